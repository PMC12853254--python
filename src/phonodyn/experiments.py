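"""Self-contained synthetic experiments with recoverable ground truth.

Each function builds its own stimulus and subjects, runs the decoding
pipeline and returns the quantity the experiment was designed to measure.
They are the package's verification harness: because the generator's
dynamic-coding parameters are known, every derived quantity (chance level,
generalization width, encoding duration, dynamic-vs-static delta, group
cluster, entropy interaction, test calibration) has an expected value.

Problem sizes are desk-scale by design: 6 simulated subjects per cohort,
~700–1100 phoneme events per subject (≈1–1.5 min of speech at the median
phoneme duration), one or two place features carrying signal, and a
train-time decimation of 2 for the temporal-generalization matrices.
Stimuli for the encoding-geometry experiments use the ``iid`` phonotactic
mode and a fresh stimulus per subject, so that neighbouring-phoneme
dependencies and shared-stimulus sampling noise cannot masquerade as
encoding; the entropy experiment uses the natural-like ``cv`` mode, which
is what makes cohorts informative in the first place.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .decode import DecodeConfig
from .pipeline import PipelineConfig, SessionConfig, simulate_session, subject_tg
from .simulate import SimConfig, make_ground_truth
from .stats import (
    TestConfig,
    entropy_interaction,
    one_sample_cluster_perm,
    two_sample_cluster_perm,
)
from .tgmetrics import (
    diagonal,
    dynamic_delta,
    generalization_width,
    halfmax_width,
    reorient,
)

#: signal-bearing / decoded features for the geometry experiments: place
#: features have the weakest dependence on neighbouring phonemes.
GEOMETRY_FEATURES = ("coronal", "labial")

TRAIN_WINDOW = (0.0, 0.35)


def _base_config(
    seed: int,
    n_words: int,
    features: tuple[str, ...],
    sim: SimConfig,
    phonotactics: str = "iid",
    train_stride: int = 2,
) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        session=SessionConfig(
            n_words=n_words, lexicon_words=2000, phonotactics=phonotactics
        ),
        simulate=sim,
        decode=DecodeConfig(train_stride=train_stride),
        decode_features=features,
    )


def _cohort(
    base: PipelineConfig,
    group: str,
    n_subjects: int,
    group_offset: int = 0,
    subset_column: str | None = None,
    need_overall: bool = True,
) -> list[dict]:
    """Simulate ``n_subjects`` of one group, each with a fresh stimulus."""
    truth = make_ground_truth(tuple(base.decode_features), base.simulate, seed=base.seed)
    out = []
    for si in range(n_subjects):
        cfg = replace(base, seed=base.seed + 1000 * si + group_offset)
        _, events, table = simulate_session(cfg)
        out.append(
            subject_tg(
                events, table, truth, cfg, group, si,
                subset_column=subset_column, need_overall=need_overall,
            )
        )
    return out


#: decoded features for the chance calibration: several quasi-independent
#: label vectors, because the grand-mean AUC's sampling noise is dominated
#: by per-fold label/noise alignments that average out across features.
CHANCE_FEATURES = ("coronal", "labial", "voiced", "short_vowel", "long_vowel", "velar")


def chance_auc(seed: int, n_words: int = 480) -> tuple[float, int]:
    """Grand-mean TG AUC of one zero-SNR subject (expected: 0.5).

    Uses ≥2000 phoneme events and six decoded features; any departure from
    0.5 beyond ±0.01 indicates decoder or cross-validation leakage.
    Returns (grand mean AUC, number of events).
    """
    base = _base_config(seed, n_words, CHANCE_FEATURES, SimConfig(snr=0.0),
                        train_stride=1)
    run = _cohort(base, "control", 1)[0]
    return float(run["avg"].values.mean()), int(run["epochs"].n_epochs)


def recovery_cohort(
    seed: int,
    dwell_tau_s: float = 0.08,
    encode_duration_s: float = 0.3,
    n_subjects: int = 6,
    n_words: int = 250,
    features: tuple[str, ...] = GEOMETRY_FEATURES,
    snr: float = 2.0,
) -> list[dict]:
    """Simulate and decode a cohort with known dwell/duration ground truth."""
    sim = SimConfig(
        snr=snr, dwell_tau_s=dwell_tau_s, encode_duration_s=encode_duration_s
    )
    base = _base_config(seed, n_words, features, sim)
    return _cohort(base, "control", n_subjects)


def cohort_widths(cohort: list[dict]) -> tuple[list[float], list[float]]:
    """(CI-recipe widths, half-max widths) per subject of a cohort."""
    wci, whm = [], []
    for run in cohort:
        prof = reorient(run["avg"], TRAIN_WINDOW)
        wci.append(generalization_width(prof))
        whm.append(halfmax_width(prof))
    return wci, whm


def diagonal_extent(
    cohort: list[dict], n_permutations: int = 1000, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Above-chance extent (s) of the group diagonal, via the cluster test.

    Returns (duration of the significant span, (start_s, end_s)).
    """
    diags = np.stack([diagonal(r["avg"]) for r in cohort])
    times = cohort[0]["avg"].train_times_s
    res = one_sample_cluster_perm(
        diags, 0.5, TestConfig(n_permutations=n_permutations, seed=0)
    )
    idx = np.flatnonzero(res.significant_mask(alpha))
    if idx.size == 0:
        return 0.0, (np.nan, np.nan)
    dt = float(np.mean(np.diff(times)))
    return float((idx[-1] - idx[0] + 1) * dt), (float(times[idx[0]]), float(times[idx[-1]]))


def negative_delta_clusters(
    cohort: list[dict], n_permutations: int = 1000, alpha: float = 0.05
) -> int:
    """Number of significant negative horizontal-minus-diagonal clusters.

    The delta contrast is only defined where information is decodable at
    all: outside the encoding window both curves compare chance values
    contaminated by the band-limiting filter's ringing (a slight
    anti-correlation with the pattern just outside the response support),
    which would register as spurious "dynamic" clusters.  The cluster test
    therefore runs on the contiguous span where the group-mean diagonal
    exceeds half its peak excess over chance; with no above-chance peak,
    the full axis is used.
    """
    deltas = np.stack([dynamic_delta(r["avg"]) for r in cohort])
    mean_diag = np.stack([diagonal(r["avg"]) for r in cohort]).mean(axis=0)
    peak = mean_diag.max()
    if peak > 0.55:
        above = np.flatnonzero(mean_diag >= 0.5 + 0.5 * (peak - 0.5))
        deltas = deltas[:, above[0] : above[-1] + 1]
    res = one_sample_cluster_perm(
        deltas, 0.0, TestConfig(n_permutations=n_permutations, seed=0)
    )
    return sum(1 for m, p in zip(res.masses, res.p_values) if m < 0 and p <= alpha)


APHASIA_LIKE_PROFILES = {
    "control": [(0.0, 1.0)],
    "aphasia": [(0.0, 1.0), (0.08, 0.4)],
}


def group_difference_clusters(
    seed: int,
    n_subjects: int = 6,
    n_words: int = 150,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> list[tuple[float, float, float]]:
    """Two-sample diagonal clusters under an aphasia-like late gain drop.

    Group B's response gain falls to 0.4 from 0.08 s after phoneme onset;
    returns significant clusters as (start_s, end_s, p).
    """
    sim = SimConfig(snr=2.0, group_gain_profile={k: list(v) for k, v in
                                                 APHASIA_LIKE_PROFILES.items()})
    base = _base_config(seed, n_words, ("coronal",), sim)
    diags = {}
    for offset, group in ((0, "control"), (500_000, "aphasia")):
        cohort = _cohort(base, group, n_subjects, group_offset=offset)
        diags[group] = np.stack([diagonal(r["avg"]) for r in cohort])
        times = cohort[0]["avg"].train_times_s
    res = two_sample_cluster_perm(
        diags["control"], diags["aphasia"],
        TestConfig(n_permutations=n_permutations, seed=0),
    )
    return [
        (float(times[c[0]]), float(times[c[-1]]), float(p))
        for c, p in zip(res.clusters, res.p_values)
        if p <= alpha
    ]


def entropy_interaction_lags(
    seed: int,
    n_subjects: int = 4,
    n_words: int = 150,
    bonus_s: float = 0.1,
    encode_duration_s: float = 0.2,
    window: tuple[float, float] = (0.15, 0.35),
) -> np.ndarray:
    """Lags with an FDR-significant group × entropy interaction.

    Group 'bonus' encodes high-entropy phonemes ``bonus_s`` longer; group
    'flat' does not.  The base encoding duration is chosen so the extension
    [D, D+bonus] after response onset falls inside the test window.
    """
    sim = SimConfig(
        snr=2.0,
        encode_duration_s=encode_duration_s,
        entropy_duration_bonus_s={"bonus": bonus_s, "flat": 0.0},
        group_gain_profile={"bonus": [(0.0, 1.0)], "flat": [(0.0, 1.0)]},
    )
    base = _base_config(seed, n_words, ("coronal",), sim, phonotactics="cv")
    tc: dict[str, dict[str, list]] = {g: {"low": [], "high": []} for g in ("bonus", "flat")}
    times = None
    for offset, group in ((0, "bonus"), (500_000, "flat")):
        cohort = _cohort(
            base, group, n_subjects, group_offset=offset,
            subset_column="entropy_tertile", need_overall=False,
        )
        for run in cohort:
            for lev in ("low", "high"):
                tc[group][lev].append(diagonal(run["subsets"][lev]))
            times = run["subsets"]["low"].train_times_s
    lags, _, _, reject = entropy_interaction(
        np.stack(tc["bonus"]["high"]), np.stack(tc["bonus"]["low"]),
        np.stack(tc["flat"]["high"]), np.stack(tc["flat"]["low"]),
        times, window=window,
    )
    return lags[reject]


def cluster_test_type1_error(
    seed: int,
    test: str = "one-sample",
    n_simulations: int = 500,
    n_subjects: int = 20,
    domain_length: int = 50,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> float:
    """Family-wise false-positive rate of a cluster test on pure noise."""
    rng = np.random.default_rng(seed)
    fp = 0
    for s in range(n_simulations):
        cfg = TestConfig(n_permutations=n_permutations, seed=seed + 7919 * s)
        if test == "one-sample":
            res = one_sample_cluster_perm(
                rng.standard_normal((n_subjects, domain_length)), 0.0, cfg
            )
        elif test == "two-sample":
            res = two_sample_cluster_perm(
                rng.standard_normal((n_subjects // 2, domain_length)),
                rng.standard_normal((n_subjects - n_subjects // 2, domain_length)),
                cfg,
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        fp += int(any(p <= alpha for p in res.p_values))
    return fp / n_simulations
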