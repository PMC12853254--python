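"""Permutation tests: examples, brute-force oracles, adjacency, FDR."""

import itertools

import numpy as np
import pytest
import scipy.sparse
import scipy.stats

from phonodyn.stats import (
    MaxTResult,
    TestConfig,
    _find_clusters,
    _max_mass,
    _one_sample_t,
    behavior_correlation,
    delaunay_adjacency,
    entropy_interaction,
    max_t_sensor_test,
    one_sample_cluster_perm,
    perm_ttest_scalar,
    two_sample_cluster_perm,
)
from phonodyn.simulate import standard_montage


class TestOneSampleCluster:
    def test_all_zero_data_has_no_clusters(self):
        res = one_sample_cluster_perm(
            np.zeros((5, 12)), 0.0, TestConfig(n_permutations=50)
        )
        assert res.clusters == []

    def test_global_effect_one_cluster_covering_domain(self):
        rng = np.random.default_rng(0)
        data = 1.0 + 0.01 * rng.standard_normal((10, 20))
        res = one_sample_cluster_perm(data, 0.0, TestConfig(n_permutations=2000, seed=1))
        assert len(res.clusters) == 1
        assert len(res.clusters[0]) == 20
        assert res.p_values[0] < 0.01

    def test_sampled_p_matches_exhaustive_sign_flips(self):
        """n=8 subjects: all 2^8 sign patterns are enumerable exactly."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 5)) + 0.8
        res = one_sample_cluster_perm(X, 0.0, TestConfig(n_permutations=4000, seed=3))
        s2 = (X**2).sum(axis=0)
        null = []
        for signs in itertools.product([-1.0, 1.0], repeat=8):
            Xs = np.asarray(signs)[:, None] * X
            t = _one_sample_t(Xs.mean(axis=0), s2, 8)
            null.append(_max_mass(t, res.threshold, (5,), 4, None))
        null = np.asarray(null)
        for mass, p in zip(res.masses, res.p_values):
            p_exact = (np.sum(null >= abs(mass)) + 1) / (len(null) + 1)
            assert abs(p - p_exact) <= 0.02

    def test_nonzero_mu0(self):
        rng = np.random.default_rng(7)
        data = 0.5 + 0.01 * rng.standard_normal((10, 10))
        res = one_sample_cluster_perm(data, 0.5, TestConfig(n_permutations=100))
        assert all(len(c) < 10 for c in res.clusters) or res.clusters == []

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            one_sample_cluster_perm(np.zeros((1, 5)))

    def test_threshold_is_student_t_quantile(self):
        res = one_sample_cluster_perm(
            np.random.default_rng(1).standard_normal((12, 6)),
            cfg=TestConfig(n_permutations=20),
        )
        assert res.threshold == pytest.approx(scipy.stats.t.ppf(0.975, 11))


class TestTwoSampleCluster:
    def test_localized_difference_recovered(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((12, 30)) * 0.1
        B = rng.standard_normal((12, 30)) * 0.1
        B[:, 10:21] -= 0.2
        res = two_sample_cluster_perm(A, B, TestConfig(n_permutations=1000, seed=0))
        sig = [c for c, p in zip(res.clusters, res.p_values) if p <= 0.05]
        assert sig, "expected a significant cluster"
        covered = np.concatenate(sig)
        assert set(range(12, 19)) <= set(covered.tolist())

    def test_one_subject_per_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_cluster_perm(np.zeros((1, 5)), np.zeros((4, 5)))

    def test_exchangeable_groups_rarely_significant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for s in range(40):
            A = rng.standard_normal((8, 25))
            B = rng.standard_normal((8, 25))
            res = two_sample_cluster_perm(A, B, TestConfig(n_permutations=300, seed=s))
            hits += int(any(p <= 0.05 for p in res.p_values))
        assert hits <= 6  # ~5% FWER; binomial(40, .05) rarely exceeds 6


class TestAdjacency:
    def test_diagonally_touching_blobs_stay_separate_under_4conn(self):
        t = np.zeros((6, 6))
        t[0:2, 0:2] = 5.0
        t[2:4, 2:4] = 5.0  # touches the first blob only at a corner
        clusters, masses = _find_clusters(t.ravel(), 2.0, (6, 6), 4, None)
        assert len(clusters) == 2
        assert sorted(len(c) for c in clusters) == [4, 4]

    def test_8conn_merges_diagonal_blobs(self):
        t = np.zeros((6, 6))
        t[0:2, 0:2] = 5.0
        t[2:4, 2:4] = 5.0
        clusters, _ = _find_clusters(t.ravel(), 2.0, (6, 6), 8, None)
        assert len(clusters) == 1

    def test_positive_and_negative_clusters_separate(self):
        t = np.array([3.0, 3.0, -3.0, -3.0, 0.0])
        clusters, masses = _find_clusters(t, 2.0, (5,), 4, None)
        assert len(clusters) == 2
        assert sorted(masses.tolist()) == [-6.0, 6.0]

    def test_graph_domain_requires_matching_adjacency(self):
        adj = scipy.sparse.eye(7, format="csr")
        with pytest.raises(ValueError):
            one_sample_cluster_perm(
                np.zeros((4, 5)), cfg=TestConfig(adjacency=adj, n_permutations=10)
            )

    def test_delaunay_adjacency_sane(self):
        _, pos = standard_montage(64)
        adj = delaunay_adjacency(pos)
        assert adj.shape == (64, 64)
        assert (adj != adj.T).nnz == 0  # symmetric
        assert adj.diagonal().sum() == 0
        deg = np.asarray(adj.sum(axis=1)).ravel()
        assert deg.min() >= 2 and deg.max() <= 12


class TestAgainstMNE:
    """The cluster machinery the study itself used, as independent oracle."""

    def test_observed_clusters_match_mne(self):
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(11)
        X = rng.standard_normal((15, 40)) * 0.5
        X[:, 10:20] += 0.6
        cfg = TestConfig(n_permutations=2000, seed=0)
        res = one_sample_cluster_perm(X, 0.0, cfg)
        t_mne, clusters_mne, p_mne, _ = permutation_cluster_1samp_test(
            X,
            threshold=res.threshold,
            n_permutations=2000,
            tail=0,
            seed=42,
            out_type="indices",
            verbose="error",
        )
        np.testing.assert_allclose(res.t_obs, t_mne, atol=1e-8)
        ours = sorted(tuple(c.tolist()) for c in res.clusters)
        theirs = sorted(tuple(np.sort(c[0]).tolist()) for c in clusters_mne)
        assert ours == theirs
        # same inference for the strong cluster despite different samplers
        strongest = int(np.argmax(np.abs(res.masses)))
        assert res.p_values[strongest] <= 0.01
        assert p_mne.min() <= 0.01


class TestPermTtestScalar:
    def test_identical_multisets_give_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = perm_ttest_scalar(a, a.copy(), 2000, seed=0)
        assert t == pytest.approx(0.0)
        assert p > 0.9

    def test_disjoint_supports_extreme_p(self):
        t, p = perm_ttest_scalar(np.arange(10) + 100.0, np.arange(10), 10000, seed=0)
        assert p <= 0.001

    def test_sampled_p_matches_exhaustive_5v5(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(5) + 1.0
        b = rng.standard_normal(5)
        t_obs, p = perm_ttest_scalar(a, b, 10000, seed=1)
        z = np.concatenate([a, b])
        null = []
        for comb in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(comb)] = True
            null.append(scipy.stats.ttest_ind(z[mask], z[~mask]).statistic)
        null = np.abs(null)
        p_exact = (np.sum(null >= abs(t_obs)) + 1) / (len(null) + 1)
        assert abs(p - p_exact) <= 0.02


class TestMaxTSensor:
    def test_shifted_sensor_detected(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((20, 16))
        B = rng.standard_normal((20, 16))
        B[:, 5] -= 3.0
        res = max_t_sensor_test(A, B, TestConfig(n_permutations=1000, seed=0))
        assert res.significant[5]
        assert res.significant.sum() <= 3

    def test_identical_sensors_get_identical_p(self):
        rng = np.random.default_rng(8)
        a_col = rng.standard_normal(10)
        b_col = rng.standard_normal(10) + 1.0
        A = np.tile(a_col[:, None], (1, 6))
        B = np.tile(b_col[:, None], (1, 6))
        res = max_t_sensor_test(A, B, TestConfig(n_permutations=500, seed=0))
        assert len(set(res.p_corrected.tolist())) == 1

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(9)
        hits = 0
        for s in range(40):
            res = max_t_sensor_test(
                rng.standard_normal((10, 32)),
                rng.standard_normal((10, 32)),
                TestConfig(n_permutations=300, seed=s),
            )
            hits += int(res.significant.any())
        assert hits <= 6


class TestEntropyInteraction:
    def _times(self):
        return -0.2 + np.arange(103) / 128

    def test_constructed_interaction_found_in_window(self):
        rng = np.random.default_rng(10)
        times = self._times()
        shape = (10, 103)
        highA = rng.standard_normal(shape) * 0.05
        lowA = rng.standard_normal(shape) * 0.05
        highB = rng.standard_normal(shape) * 0.05
        lowB = rng.standard_normal(shape) * 0.05
        boost = (times >= 0.2) & (times <= 0.25)
        highA[:, boost] += 0.1
        lags, t, p_fdr, rej = entropy_interaction(highA, lowA, highB, lowB, times)
        assert rej.any()
        assert (lags[rej] >= 0.19).all() and (lags[rej] <= 0.26).all()

    def test_no_interaction_rarely_flagged(self):
        rng = np.random.default_rng(12)
        times = self._times()
        hits = 0
        for _ in range(40):
            args = [rng.standard_normal((8, 103)) * 0.05 for _ in range(4)]
            _, _, _, rej = entropy_interaction(*args, times)
            hits += int(rej.any())
        assert hits <= 6

    def test_single_lag_window_reduces_to_raw_p(self):
        rng = np.random.default_rng(13)
        times = self._times()
        args = [rng.standard_normal((8, 103)) for _ in range(4)]
        lag = float(times[60])
        lags, t, p_fdr, _ = entropy_interaction(*args, times, window=(lag, lag))
        dA = args[0] - args[1]
        dB = args[2] - args[3]
        p_raw = scipy.stats.ttest_ind(dA[:, 60], dB[:, 60]).pvalue
        assert p_fdr[0] == pytest.approx(p_raw)

    def test_window_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            entropy_interaction(
                *[np.zeros((3, 10))] * 4, np.arange(10) / 128, window=(5.0, 6.0)
            )


class TestBehaviorCorrelation:
    def test_perfect_correlation_at_matching_lag(self):
        rng = np.random.default_rng(14)
        tc = rng.standard_normal((12, 20))
        scores = tc[:, 7]
        r, p, intervals = behavior_correlation(tc, scores, np.arange(20) / 128)
        assert r[7] == pytest.approx(1.0)
        assert p[7] < 1e-6

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            behavior_correlation(np.zeros((2, 5)), np.zeros(2), np.arange(5))

    def test_null_correlations_mostly_modest(self):
        rng = np.random.default_rng(15)
        tc = rng.standard_normal((40, 60))
        scores = rng.standard_normal(40)
        r, p, _ = behavior_correlation(tc, scores, np.arange(60) / 128)
        assert (np.abs(r) < 0.32).mean() >= 0.9  # |r|<0.32 is the 95% null band

    def test_zero_variance_score_gives_nan(self):
        tc = np.random.default_rng(16).standard_normal((5, 4))
        r, p, _ = behavior_correlation(tc, np.ones(5), np.arange(4))
        assert np.isnan(r).all()
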