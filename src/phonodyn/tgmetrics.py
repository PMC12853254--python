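"""Summary quantities derived from temporal-generalization matrices.

* ``diagonal`` — the decoding-duration timecourse (train time == test time).
* ``reorient`` — roll each row of the TG matrix so the diagonal lands at
  lag 0, restrict to a train-time window (default 0–0.35 s), and average
  across rows: the generalization profile over test-minus-train lag.
* ``generalization_width`` — per-subject width of the profile: z-score the
  mean profile across lags, form a per-lag confidence interval, and count
  lags whose lower bound exceeds zero.  Two CI conventions are exposed (see
  below); the default follows the recipe used in the EEG decoding literature,
  where the CI half-width
  is derived from the standard deviation across the timecourse itself.
* ``halfmax_width`` — full width of the profile at half its peak AUC
  excess over chance.  For codes that hand off between patterns at fixed
  latencies the phase-averaged profile is triangular with base twice the
  dwell time, so this estimator recovers the injected dwell without the
  scale compression that affects the CI recipe when the bump occupies a
  large fraction of the lag span.
* ``dynamic_delta`` — horizontal (across-train-time average) minus diagonal
  timecourse; significantly negative values indicate dynamic (evolving)
  rather than static coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .decode import TGMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneralizationProfile:
    """Row-rolled TG matrix restricted to a train window.

    ``rows`` is (n_rows, n_lags) with NaN where a row does not cover a lag;
    ``mean_profile`` is the across-row nanmean; lag 0 is the diagonal.
    """

    lags_s: np.ndarray
    mean_profile: np.ndarray
    rows: np.ndarray
    counts: np.ndarray
    subject: str = ""

    def covered(self, min_row_fraction: float = 0.5) -> np.ndarray:
        """Mask of lags contributed to by at least that fraction of rows."""
        return self.counts >= min_row_fraction * self.rows.shape[0]


def _diag_columns(tg: TGMatrix) -> np.ndarray:
    """Test-time column index matching each train time."""
    cols = np.argmin(
        np.abs(tg.test_times_s[None, :] - tg.train_times_s[:, None]), axis=1
    )
    dt = float(np.mean(np.diff(tg.test_times_s)))
    if np.abs(tg.test_times_s[cols] - tg.train_times_s).max() > dt / 2:
        raise ValueError("train times do not lie on the test-time grid")
    return cols


def diagonal(tg: TGMatrix) -> np.ndarray:
    """Matched train/test-time decoding timecourse (the matrix diagonal).

    For a square matrix this is values[t, t]; for a train-decimated matrix,
    each row's value at the test time equal to its train time.  The
    associated time axis is ``tg.train_times_s``.
    """
    if tg.is_square:
        return np.diag(tg.values).copy()
    cols = _diag_columns(tg)
    return tg.values[np.arange(len(cols)), cols].copy()


def reorient(
    tg: TGMatrix, train_window: tuple[float, float] = (0.0, 0.35)
) -> GeneralizationProfile:
    """Roll rows so the diagonal sits at lag 0; average across the y-axis.

    Only train times within ``train_window`` contribute.  The shift is a
    pure permutation-with-padding: each row's value multiset is preserved.
    """
    t_test = tg.test_times_s
    lo, hi = train_window
    if lo < t_test[0] - 1e-9 or hi > t_test[-1] + 1e-9:
        raise ValueError("train window outside the matrix time axis")
    rows_idx = np.flatnonzero((tg.train_times_s >= lo) & (tg.train_times_s <= hi))
    if rows_idx.size == 0:
        raise ValueError("no train times inside the window")
    T = len(t_test)
    n_lags = 2 * T - 1
    dt = float(np.mean(np.diff(t_test)))
    lags = (np.arange(n_lags) - (T - 1)) * dt
    rows = np.full((rows_idx.size, n_lags), np.nan)
    for r, i in enumerate(rows_idx):
        # column index of the diagonal for this row
        ti = int(np.argmin(np.abs(t_test - tg.train_times_s[i])))
        rows[r, (T - 1) - ti : (2 * T - 1) - ti] = tg.values[i]
    counts = np.sum(~np.isnan(rows), axis=0)
    mean_profile = np.full(n_lags, np.nan)
    has = counts > 0
    mean_profile[has] = np.nanmean(rows[:, has], axis=0)
    return GeneralizationProfile(lags, mean_profile, rows, counts)


def generalization_width(
    profile: GeneralizationProfile,
    ci_level: float = 0.95,
    mode: str = "timecourse-sd",
    min_row_fraction: float = 0.5,
) -> float:
    """Width (s) of the generalization peak from per-lag confidence bounds.

    The subject's mean profile is standardized (z-scored across covered
    lags).  A lag counts toward the width when the lower bound of its CI is
    above zero:

    * ``mode='timecourse-sd'`` (default, the literature recipe): the CI
      half-width is z* times the SD across the timecourse — after
      standardization this reduces to ``z > z*``.
    * ``mode='row-sem'``: the CI half-width is z* times the SEM across the
      contributing train rows at that lag.

    Edge lags covered by fewer than ``min_row_fraction`` of rows are
    excluded to avoid edge bias.
    """
    if mode not in ("timecourse-sd", "row-sem"):
        raise ValueError(f"unknown width mode {mode!r}")
    keep = profile.covered(min_row_fraction)
    vals = profile.mean_profile[keep]
    if (profile.counts[keep] < 2).any():
        raise ValueError("need at least 2 contributing rows per counted lag")
    dt = float(np.mean(np.diff(profile.lags_s)))
    sd = vals.std()
    if sd < 1e-10:
        width = float(len(vals)) * dt if vals.mean() > 0.5 else 0.0
        logger.warning("degenerate (zero-variance) profile; width set to %.3f", width)
        return width
    z = (vals - vals.mean()) / sd
    zstar = norm.ppf(0.5 + ci_level / 2.0)
    if mode == "timecourse-sd":
        above = z - zstar > 0
    else:
        sem = np.nanstd(profile.rows, axis=0, ddof=1)[keep] / np.sqrt(
            profile.counts[keep]
        )
        above = z - zstar * (sem / sd) > 0
    return float(above.sum()) * dt


def halfmax_width(
    profile: GeneralizationProfile,
    baseline: float = 0.5,
    min_row_fraction: float = 0.5,
) -> float:
    """Full width at half maximum of the above-chance profile.

    Works on the AUC excess over chance: with pattern handoffs at fixed
    latencies, a decoder generalizes over exactly its own dwell, so the
    phase-averaged profile is triangular with base twice the dwell time and
    its half-height width equals the dwell time itself; half-height
    crossings sit on the triangle's linear flanks and are unaffected by
    symmetric filter smoothing.  Crossings are located by linear
    interpolation outward from the peak.
    """
    keep = profile.covered(min_row_fraction)
    lags = profile.lags_s[keep]
    d = profile.mean_profile[keep] - baseline
    # peak restricted to the immediate neighbourhood of lag 0
    center = int(np.argmin(np.abs(lags)))
    lo = max(0, center - 3)
    peak_idx = lo + int(np.argmax(d[lo : center + 4]))
    half = d[peak_idx] / 2.0
    if d[peak_idx] <= 0:
        return 0.0

    def cross(idx_range) -> float:
        prev = peak_idx
        for i in idx_range:
            if d[i] < half:
                # linear interpolation between i and prev
                f = (half - d[i]) / (d[prev] - d[i])
                return lags[i] + f * (lags[prev] - lags[i])
            prev = i
        return lags[idx_range[-1]] if len(idx_range) else lags[peak_idx]

    left = cross(range(peak_idx - 1, -1, -1))
    right = cross(range(peak_idx + 1, len(d)))
    return float(right - left)


def dynamic_delta(
    tg: TGMatrix,
    train_window: tuple[float, float] | None = None,
    row_fraction: float = 0.9,
) -> np.ndarray:
    """Horizontal minus diagonal timecourse on the common (test) time axis.

    The horizontal timecourse is the average across train times (the
    y-axis) of the TG matrix.  By default only rows whose diagonal
    performance reaches ``row_fraction`` of the peak excess over chance
    contribute: averaging in decoders that carried little or no information
    (outside the encoding window, or trained on the smoothed edges of the
    response) would drag the horizontal toward chance and make even a
    perfectly static code look dynamic.  Pass ``train_window`` to use a
    fixed window instead.
    Negative values mean the diagonal exceeds sustained generalization —
    the signature of dynamic coding.  The delta lives on the train-time
    axis (identical to the test-time axis for a square matrix).
    """
    diag = diagonal(tg)
    if train_window is not None:
        lo, hi = train_window
        sel = (tg.train_times_s >= lo) & (tg.train_times_s <= hi)
        if not sel.any():
            raise ValueError("train window excludes all rows")
    else:
        peak = diag.max()
        sel = diag >= 0.5 + row_fraction * (peak - 0.5)
        if sel.sum() < 3 or peak <= 0.5:
            sel = np.ones(len(diag), dtype=bool)
    horizontal = tg.values[sel].mean(axis=0)
    cols = np.arange(len(diag)) if tg.is_square else _diag_columns(tg)
    return horizontal[cols] - diag
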