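"""Temporal-generalization decoding: chance, localization, invariances."""

import numpy as np
import pytest

from phonodyn.annotate import FeatureTable
from phonodyn.decode import (
    DecodeConfig,
    _auc_columns,
    decode_all_features,
    decode_per_sensor,
    tg_decode,
    tg_decode_subsets,
)

from conftest import make_epochs


def inject(epochs, labels, pattern, t_slice, amp=1.5):
    """Add a spatial pattern to labelled epochs over a time-index slice."""
    data = epochs.data.copy()
    for i in np.flatnonzero(labels):
        data[i, :, t_slice] += amp * pattern[:, None]
    epochs.data = data
    return epochs


@pytest.fixture
def labels200():
    rng = np.random.default_rng(42)
    return (rng.random(200) < 0.5).astype(int)


class TestAucColumns:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((100, 7))
        y = (rng.random(100) < 0.4).astype(int)
        a = _auc_columns(s, y)
        np.testing.assert_allclose(a, _auc_columns(np.exp(s), y))
        np.testing.assert_allclose(a, _auc_columns(3 * s - 7, y))

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal((80, 4))
        y = (rng.random(80) < 0.5).astype(int)
        np.testing.assert_allclose(
            _auc_columns(s, 1 - y), 1 - _auc_columns(s, y)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            _auc_columns(np.zeros((5, 1)), np.ones(5, dtype=int))


class TestTgDecode:
    def test_chance_on_independent_labels(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=16, seed=3)
        tg = tg_decode(ep, labels200, DecodeConfig(seed=0))
        assert abs(tg.values.mean() - 0.5) < 0.03

    def test_pattern_confined_to_injection_window(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=16, seed=4)
        rng = np.random.default_rng(5)
        pattern = rng.standard_normal(16)
        pattern /= np.linalg.norm(pattern)
        t_in = slice(10, 20)
        ep = inject(ep, labels200, pattern, t_in, amp=2.0)
        tg = tg_decode(ep, labels200, DecodeConfig(seed=0))
        inside = tg.values[10:20, 10:20].mean()
        outside = tg.values[30:, 30:].mean()
        assert inside > 0.85
        assert abs(outside - 0.5) < 0.05
        # cross terms (trained inside, tested outside) at chance
        assert abs(tg.values[10:20, 30:].mean() - 0.5) < 0.05

    def test_constant_pattern_generalizes_everywhere(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=16, seed=6)
        rng = np.random.default_rng(7)
        pattern = rng.standard_normal(16)
        pattern /= np.linalg.norm(pattern)
        ep = inject(ep, labels200, pattern, slice(0, 40), amp=2.0)
        tg = tg_decode(ep, labels200, DecodeConfig(seed=0))
        assert (tg.values > 0.8).mean() > 0.95

    def test_matrix_level_label_flip_symmetry(self, epochs_factory, labels200):
        # retraining on flipped labels learns the negated weights, so the
        # TG matrix is unchanged (the score-level antisymmetry lives in
        # _auc_columns, tested above)
        ep = epochs_factory(n_events=200, n_channels=8, seed=8)
        pattern = np.ones(8) / np.sqrt(8)
        ep = inject(ep, labels200, pattern, slice(5, 30), amp=1.5)
        a = tg_decode(ep, labels200, DecodeConfig(seed=0))
        b = tg_decode(ep, 1 - labels200, DecodeConfig(seed=0))
        assert np.abs(b.values - a.values).mean() < 1e-6

    def test_mean_invariant_to_fold_seed(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=8, seed=9)
        pattern = np.ones(8) / np.sqrt(8)
        ep = inject(ep, labels200, pattern, slice(5, 30), amp=1.5)
        a = tg_decode(ep, labels200, DecodeConfig(seed=0))
        b = tg_decode(ep, labels200, DecodeConfig(seed=99))
        assert abs(a.values.mean() - b.values.mean()) < 0.01

    def test_deterministic(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=8, seed=10)
        a = tg_decode(ep, labels200, DecodeConfig(seed=1))
        b = tg_decode(ep, labels200, DecodeConfig(seed=1))
        np.testing.assert_array_equal(a.values, b.values)

    def test_rare_class_rejected(self, epochs_factory):
        ep = epochs_factory(n_events=50, seed=11)
        y = np.zeros(50, dtype=int)
        y[:3] = 1  # fewer positives than folds
        with pytest.raises(ValueError, match="folds"):
            tg_decode(ep, y, DecodeConfig())

    def test_fewer_events_than_folds_rejected(self, epochs_factory):
        ep = epochs_factory(n_events=4, seed=12)
        with pytest.raises(ValueError):
            tg_decode(ep, np.array([0, 1, 0, 1]), DecodeConfig(n_folds=5))


class TestSubsets:
    def test_single_level_equals_plain_decode(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=8, seed=13)
        pattern = np.ones(8) / np.sqrt(8)
        ep = inject(ep, labels200, pattern, slice(5, 30), amp=1.5)
        plain = tg_decode(ep, labels200, DecodeConfig(seed=0))
        subs = tg_decode_subsets(
            ep, labels200, np.array(["only"] * 200), DecodeConfig(seed=0)
        )
        assert list(subs) == ["only"]
        np.testing.assert_allclose(subs["only"].values, plain.values)

    def test_signal_in_one_level_only(self, epochs_factory):
        rng = np.random.default_rng(14)
        ep = epochs_factory(n_events=300, n_channels=16, seed=14)
        labels = (rng.random(300) < 0.5).astype(int)
        level = np.where(rng.random(300) < 0.5, "A", "B")
        pattern = rng.standard_normal(16)
        pattern /= np.linalg.norm(pattern)
        # inject only into level-A epochs
        sel = (level == "A") & (labels == 1)
        data = ep.data.copy()
        data[np.flatnonzero(sel)] += 2.0 * pattern[None, :, None]
        ep.data = data
        subs = tg_decode_subsets(ep, labels, level, DecodeConfig(seed=0))
        assert subs["A"].values.mean() > 0.7
        assert abs(subs["B"].values.mean() - 0.5) < 0.05

    def test_absent_level_omitted_with_warning(self, epochs_factory, labels200):
        ep = epochs_factory(n_events=200, n_channels=8, seed=15)
        level = np.array(["common"] * 199 + ["rare"])
        with pytest.warns(UserWarning, match="rare"):
            subs = tg_decode_subsets(ep, labels200, level, DecodeConfig(seed=0))
        assert "rare" not in subs


class TestDecodeAllFeatures:
    def _table(self, n, rng):
        cols = {
            "f_good": (rng.random(n) < 0.5).astype(np.int8),
            "f_also": (rng.random(n) < 0.3).astype(np.int8),
            "f_rare": np.r_[np.ones(2, dtype=np.int8), np.zeros(n - 2, dtype=np.int8)],
        }
        return FeatureTable(np.column_stack(list(cols.values())), tuple(cols))

    def test_shapes_average_and_failing_feature_dropped(self, epochs_factory):
        rng = np.random.default_rng(16)
        ep = epochs_factory(n_events=120, n_channels=8, seed=16)
        table = self._table(120, rng)
        with pytest.warns(UserWarning, match="f_rare"):
            mats, avg = decode_all_features(ep, table, DecodeConfig(seed=0))
        assert [m.feature for m in mats] == ["f_good", "f_also"]
        np.testing.assert_allclose(
            avg.values, np.mean([m.values for m in mats], axis=0)
        )

    def test_average_of_identical_matrices_is_that_matrix(self, epochs_factory):
        rng = np.random.default_rng(17)
        ep = epochs_factory(n_events=100, n_channels=8, seed=17)
        y = (rng.random(100) < 0.5).astype(np.int8)
        table = FeatureTable(np.column_stack([y, y]), ("a", "b"))
        mats, avg = decode_all_features(ep, table, DecodeConfig(seed=0))
        np.testing.assert_allclose(avg.values, mats[0].values)


class TestPerSensor:
    def test_signal_localized_to_one_sensor(self, epochs_factory):
        rng = np.random.default_rng(18)
        ep = epochs_factory(n_events=150, n_channels=6, seed=18)
        y = (rng.random(150) < 0.5).astype(np.int8)
        data = ep.data.copy()
        data[np.flatnonzero(y), 2, :] += 1.5
        ep.data = data
        table = FeatureTable(y[:, None], ("f",))
        scores = decode_per_sensor(ep, table, DecodeConfig(seed=0))
        assert scores.shape == (6,)
        assert int(np.argmax(scores)) == 2

    def test_duplicated_sensor_scores_match(self, epochs_factory):
        rng = np.random.default_rng(19)
        ep = epochs_factory(n_events=150, n_channels=4, seed=19)
        y = (rng.random(150) < 0.5).astype(np.int8)
        data = ep.data.copy()
        data[np.flatnonzero(y), 0, :] += 1.0
        data[:, 1, :] = data[:, 0, :]
        ep.data = data
        table = FeatureTable(y[:, None], ("f",))
        scores = decode_per_sensor(ep, table, DecodeConfig(seed=0))
        assert abs(scores[0] - scores[1]) < 1e-9  # identical inputs, same folds

    def test_noise_sensors_at_chance(self, epochs_factory):
        rng = np.random.default_rng(20)
        ep = epochs_factory(n_events=200, n_channels=5, seed=20)
        y = (rng.random(200) < 0.5).astype(np.int8)
        table = FeatureTable(y[:, None], ("f",))
        scores = decode_per_sensor(ep, table, DecodeConfig(seed=0))
        assert np.abs(scores - 0.5).max() < 0.12
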