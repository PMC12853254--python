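"""Permutation-based inference for decoding timecourses, TG grids and sensors.

Cluster tests follow the nonparametric max-statistic scheme: a t-value per
domain point, clusters of contiguous supra-threshold points (threshold =
two-tailed Student-t quantile at the cluster-forming alpha), cluster mass =
summed t, and a null distribution of the maximum absolute cluster mass under
per-subject sign flips (one-sample) or group-label exchange (two-sample).
Positive and negative clusters are formed separately; the test is two-sided
through the max of |mass|.  p-values use the (b + 1) / (m + 1) convention,
which is strictly positive and valid.  Domains: 1D timecourses (contiguity),
2D TG grids (4-connectivity by default), or an explicit sensor adjacency
(Delaunay neighbourhood of the montage by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.sparse
import scipy.sparse.csgraph
import scipy.spatial
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TestConfig:
    """Permutation-test settings (10,000 permutations at alpha 0.05)."""

    __test__ = False  # not a pytest class, despite the name

    n_permutations: int = 10_000
    alpha: float = 0.05
    cluster_alpha: float = 0.05  # cluster-forming threshold quantile
    connectivity: int = 4  # lattice connectivity for 2D domains (4 or 8)
    adjacency: scipy.sparse.spmatrix | None = None  # graph domains (sensors)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ClusterResult:
    """Clusters (flat index sets), masses, permutation p-values, null."""

    clusters: list[np.ndarray]
    masses: np.ndarray
    p_values: np.ndarray
    null_max_mass: np.ndarray
    threshold: float
    domain_shape: tuple
    n_permutations: int
    t_obs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean mask over the domain: union of significant clusters."""
        mask = np.zeros(int(np.prod(self.domain_shape)), dtype=bool)
        for cl, p in zip(self.clusters, self.p_values):
            if p <= alpha:
                mask[cl] = True
        return mask.reshape(self.domain_shape)


def _lattice_clusters(mask: np.ndarray, shape: tuple, connectivity: int):
    """Connected components of a boolean mask on a 1D/2D lattice."""
    m = mask.reshape(shape)
    if len(shape) == 1:
        lab, n = scipy.ndimage.label(m)
    else:
        structure = (
            np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
            if connectivity == 4
            else np.ones((3, 3), dtype=int)
        )
        lab, n = scipy.ndimage.label(m, structure=structure)
    lab = lab.ravel()
    return [np.flatnonzero(lab == k) for k in range(1, n + 1)]


def _graph_clusters(mask: np.ndarray, adjacency: scipy.sparse.spmatrix):
    """Connected components of the supra-threshold subgraph."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency.tocsr()[idx][:, idx]
    n, labels = scipy.sparse.csgraph.connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n)]


def _find_clusters(t: np.ndarray, threshold: float, shape, connectivity, adjacency):
    """Signed clusters and masses; positive and negative formed separately."""
    clusters: list[np.ndarray] = []
    for mask in (t > threshold, t < -threshold):
        if adjacency is not None:
            clusters.extend(_graph_clusters(mask, adjacency))
        else:
            clusters.extend(_lattice_clusters(mask, shape, connectivity))
    masses = np.array([t[c].sum() for c in clusters])
    return clusters, masses


def _max_mass(t: np.ndarray, threshold: float, shape, connectivity, adjacency) -> float:
    _, masses = _find_clusters(t, threshold, shape, connectivity, adjacency)
    return float(np.abs(masses).max()) if masses.size else 0.0


def _p_from_null(null: np.ndarray, observed_abs: np.ndarray) -> np.ndarray:
    m = len(null)
    return np.array([(np.sum(null >= o) + 1) / (m + 1) for o in observed_abs])


def _one_sample_t(mean: np.ndarray, s2: np.ndarray, n: int) -> np.ndarray:
    var = (s2 - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def one_sample_cluster_perm(
    data: np.ndarray, mu0: float = 0.0, cfg: TestConfig | None = None
) -> ClusterResult:
    """Sign-flip cluster permutation test of H0: mean == mu0.

    ``data`` is subjects × domain (1D, 2D, or flat with ``cfg.adjacency``).
    The null distribution is the max |cluster mass| under random per-subject
    sign flips of (data − mu0); the observed labeling is not forced into the
    null sample.
    """
    cfg = cfg or TestConfig()
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    shape = data.shape[1:]
    if cfg.adjacency is not None and (
        len(shape) != 1 or cfg.adjacency.shape[0] != shape[0]
    ):
        raise ValueError("adjacency inconsistent with domain shape")
    X = (data - mu0).reshape(n, -1)
    threshold = float(scipy.stats.t.ppf(1 - cfg.cluster_alpha / 2, df=n - 1))
    s2 = (X**2).sum(axis=0)
    t_obs = _one_sample_t(X.mean(axis=0), s2, n)
    clusters, masses = _find_clusters(
        t_obs, threshold, shape, cfg.connectivity, cfg.adjacency
    )
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_permutations)
    chunk = max(1, int(2e7 // max(1, X.shape[1])))
    done = 0
    while done < cfg.n_permutations:
        k = min(chunk, cfg.n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n))
        means = signs @ X / n  # (k, P); sum of squares is flip-invariant
        tt = _one_sample_t(means, s2[None, :], n)
        for i in range(k):
            null[done + i] = _max_mass(
                tt[i], threshold, shape, cfg.connectivity, cfg.adjacency
            )
        done += k
    p = _p_from_null(null, np.abs(masses)) if masses.size else np.array([])
    return ClusterResult(
        clusters, masses, p, null, threshold, shape, cfg.n_permutations,
        t_obs.reshape(shape),
    )


def _two_sample_t(
    sum_a, sum2_a, n1, sum_b, sum2_b, n2
) -> np.ndarray:
    ma, mb = sum_a / n1, sum_b / n2
    ssa = sum2_a - n1 * ma**2
    ssb = sum2_b - n2 * mb**2
    sp2 = np.maximum((ssa + ssb) / (n1 + n2 - 2), 1e-300)
    return (ma - mb) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def two_sample_cluster_perm(
    group_a: np.ndarray, group_b: np.ndarray, cfg: TestConfig | None = None
) -> ClusterResult:
    """Independent-samples cluster permutation test (group-label exchange)."""
    cfg = cfg or TestConfig()
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("group domains differ")
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    shape = A.shape[1:]
    if cfg.adjacency is not None and (
        len(shape) != 1 or cfg.adjacency.shape[0] != shape[0]
    ):
        raise ValueError("adjacency inconsistent with domain shape")
    Z = np.concatenate([A, B]).reshape(n1 + n2, -1)
    Z2 = Z**2
    threshold = float(scipy.stats.t.ppf(1 - cfg.cluster_alpha / 2, df=n1 + n2 - 2))
    t_obs = _two_sample_t(
        Z[:n1].sum(0), Z2[:n1].sum(0), n1, Z[n1:].sum(0), Z2[n1:].sum(0), n2
    )
    clusters, masses = _find_clusters(
        t_obs, threshold, shape, cfg.connectivity, cfg.adjacency
    )
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_permutations)
    tot, tot2 = Z.sum(0), Z2.sum(0)
    chunk = max(1, int(2e7 // max(1, Z.shape[1])))
    done = 0
    n = n1 + n2
    while done < cfg.n_permutations:
        k = min(chunk, cfg.n_permutations - done)
        # random assignment of n1 subjects to pseudo-group A
        R = np.zeros((k, n))
        order = np.argsort(rng.random((k, n)), axis=1)[:, :n1]
        np.put_along_axis(R, order, 1.0, axis=1)
        sa, s2a = R @ Z, R @ Z2
        tt = _two_sample_t(sa, s2a, n1, tot - sa, tot2 - s2a, n2)
        for i in range(k):
            null[done + i] = _max_mass(
                tt[i], threshold, shape, cfg.connectivity, cfg.adjacency
            )
        done += k
    p = _p_from_null(null, np.abs(masses)) if masses.size else np.array([])
    return ClusterResult(
        clusters, masses, p, null, threshold, shape, cfg.n_permutations,
        t_obs.reshape(shape),
    )


@dataclass
class MaxTResult:
    """Mass-univariate sensor test with max-t family-wise correction."""

    t: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray  # boolean, at cfg.alpha
    null_max_t: np.ndarray


def max_t_sensor_test(
    group_a: np.ndarray, group_b: np.ndarray, cfg: TestConfig | None = None
) -> MaxTResult:
    """Per-sensor independent t with FWER correction via the max-|t| null."""
    cfg = cfg or TestConfig()
    A, B = np.asarray(group_a, float), np.asarray(group_b, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("sensor axes differ between groups")
    n1, n2 = len(A), len(B)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    Z = np.concatenate([A, B])
    Z2 = Z**2
    t_obs = _two_sample_t(
        Z[:n1].sum(0), Z2[:n1].sum(0), n1, Z[n1:].sum(0), Z2[n1:].sum(0), n2
    )
    rng = np.random.default_rng(cfg.seed)
    tot, tot2 = Z.sum(0), Z2.sum(0)
    n = n1 + n2
    R = np.zeros((cfg.n_permutations, n))
    order = np.argsort(rng.random((cfg.n_permutations, n)), axis=1)[:, :n1]
    np.put_along_axis(R, order, 1.0, axis=1)
    sa, s2a = R @ Z, R @ Z2
    tt = _two_sample_t(sa, s2a, n1, tot - sa, tot2 - s2a, n2)
    null = np.abs(tt).max(axis=1)
    p_corr = _p_from_null(null, np.abs(t_obs))
    return MaxTResult(t_obs, p_corr, p_corr <= cfg.alpha, null)


def perm_ttest_scalar(
    a: np.ndarray, b: np.ndarray, n_permutations: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Independent-samples t with a label-exchange permutation p (two-sided)."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    t_obs = float(scipy.stats.ttest_ind(a, b).statistic)
    z = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n1 = len(a)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(z))
        null[i] = scipy.stats.ttest_ind(z[perm[:n1]], z[perm[n1:]]).statistic
    p = float((np.sum(np.abs(null) >= abs(t_obs)) + 1) / (n_permutations + 1))
    return t_obs, p


def entropy_interaction(
    high_a: np.ndarray,
    low_a: np.ndarray,
    high_b: np.ndarray,
    low_b: np.ndarray,
    times_s: np.ndarray,
    window: tuple[float, float] = (0.15, 0.35),
    alpha: float = 0.05,
):
    """Group × entropy interaction on decoding timecourses.

    Per subject, the low-entropy condition is subtracted from the
    high-entropy condition; the two groups' difference timecourses are
    compared with an independent-samples t-test at every lag inside
    ``window``, and p-values are Benjamini–Hochberg corrected across those
    lags.  Returns (window lag times, t per lag, FDR-corrected p per lag,
    significant mask at ``alpha``).
    """
    times_s = np.asarray(times_s)
    lo, hi = window
    sel = (times_s >= lo - 1e-9) & (times_s <= hi + 1e-9)
    if not sel.any():
        raise ValueError("window outside the time axis")
    d_a = np.asarray(high_a, float) - np.asarray(low_a, float)
    d_b = np.asarray(high_b, float) - np.asarray(low_b, float)
    t, p = scipy.stats.ttest_ind(d_a[:, sel], d_b[:, sel], axis=0)
    reject, p_fdr, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return times_s[sel], t, p_fdr, reject


def behavior_correlation(
    timecourses: np.ndarray, scores: np.ndarray, times_s: np.ndarray, alpha: float = 0.05
):
    """Per-lag Pearson correlation of decoding with a behavioral score.

    Uncorrected two-sided p-values (exploratory use).  Lags where either
    variable has zero variance yield NaN (logged).  Returns (r, p, list of
    (start_s, end_s) intervals of contiguous significant lags).
    """
    tc = np.asarray(timecourses, float)
    sc = np.asarray(scores, float).ravel()
    if tc.shape[0] != len(sc) or len(sc) < 3:
        raise ValueError("need at least 3 subjects with both measures")
    r = np.full(tc.shape[1], np.nan)
    p = np.full(tc.shape[1], np.nan)
    if sc.std() == 0:
        logger.warning("behavior score has zero variance; correlations undefined")
    else:
        for j in range(tc.shape[1]):
            if tc[:, j].std() == 0:
                logger.warning("zero-variance decoding at lag %d", j)
                continue
            r[j], p[j] = scipy.stats.pearsonr(tc[:, j], sc)
    sig = (p < alpha) & ~np.isnan(p)
    intervals = []
    for cl in _lattice_clusters(sig, (len(sig),), 4):
        intervals.append((float(times_s[cl[0]]), float(times_s[cl[-1]])))
    return r, p, intervals


def delaunay_adjacency(pos: np.ndarray) -> scipy.sparse.csr_matrix:
    """Sensor adjacency from a Delaunay triangulation of the montage.

    3D positions are mapped to the plane by an azimuthal-equidistant
    projection before triangulating.
    """
    pos = np.asarray(pos, float)
    xyz = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    theta = np.arccos(np.clip(xyz[:, 2], -1, 1))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    pts = np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
    tri = scipy.spatial.Delaunay(pts)
    n = len(pos)
    rows, cols = [], []
    for simplex in tri.simplices:
        for i in range(3):
            for j in range(i + 1, 3):
                rows += [simplex[i], simplex[j]]
                cols += [simplex[j], simplex[i]]
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    adj.data[:] = 1
    return adj
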