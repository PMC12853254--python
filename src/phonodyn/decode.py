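"""Temporal-generalization (TG) decoding of phonetic features.

A one-versus-all L2-regularized logistic regression is trained at every
train time on the channel vector of that time slice, under stratified
5-fold cross-validation, and scored with the area under the ROC curve
(AUC) at every test time — yielding a train-time × test-time matrix whose
diagonal tracks moment-by-moment decodability and whose off-diagonal width
tracks maintenance of the underlying neural pattern.

Scoring uses the rank (Mann-Whitney) formulation of the AUC, which makes it
invariant to any strictly monotone transform of the decision scores and
insensitive to class prevalence (chance = 0.5).  AUC is computed per fold
and averaged across folds (a pooled-predictions variant is available via
``DecodeConfig.pool_folds``).

Trial-subset evaluation trains on the full training folds but scores each
subset of the test fold separately, so all subsets share the same fitted
decoders.  Per-(feature, train-time) fits are independent; execution order
does not affect results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .annotate import FeatureTable
from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class DecodeConfig:
    """Decoder settings: 5 stratified folds, L2 logistic regression, AUC."""

    n_folds: int = 5
    C: float = 1.0  # inverse L2 penalty strength
    seed: int = 0
    max_iter: int = 200
    train_stride: int = 1  # decimate train times (test times stay dense)
    pool_folds: bool = False  # pool predictions before AUC instead of averaging

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.train_stride < 1:
            raise ValueError("train_stride must be >= 1")


@dataclass
class TGMatrix:
    """Train-time × test-time AUC matrix for one feature/subject/subset."""

    values: np.ndarray
    train_times_s: np.ndarray
    test_times_s: np.ndarray
    feature: str = ""
    subject: str = ""
    subset: str = "all"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.train_times_s), len(self.test_times_s)):
            raise ValueError("values shape inconsistent with time axes")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite AUC values")

    @property
    def is_square(self) -> bool:
        return len(self.train_times_s) == len(self.test_times_s) and np.allclose(
            self.train_times_s, self.test_times_s
        )


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise ROC AUC of decision scores (n_samples × n_cols) vs binary y."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores, axis=0)
    return (ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _check_labels(labels: np.ndarray, n_folds: int) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    counts = np.bincount(labels, minlength=2)
    if len(labels) < n_folds:
        raise ValueError("fewer events than folds")
    if counts.min() < n_folds:
        raise ValueError(
            "a class has fewer events than folds; stratified splitting "
            f"impossible (class counts {counts.tolist()})"
        )
    return labels


def tg_decode(
    epochs: EpochSet,
    labels: np.ndarray,
    cfg: DecodeConfig | None = None,
    subset_labels: np.ndarray | None = None,
    feature: str = "",
    subject: str = "",
) -> TGMatrix | dict[str, TGMatrix]:
    """Temporal-generalization decoding of a binary label.

    With ``subset_labels`` (a categorical vector aligned with epochs), the
    decoders are trained on the full training folds but evaluated separately
    on each level of the test folds, returning a mapping level → TGMatrix;
    levels absent (or single-class) in all test folds are omitted with a
    warning.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or DecodeConfig()
    labels = _check_labels(labels, cfg.n_folds)
    X = epochs.data  # (n, C, T)
    n, _, T = X.shape
    train_idx_times = np.arange(0, T, cfg.train_stride)
    levels = ["all"] if subset_labels is None else sorted(
        pd.unique(pd.Series(subset_labels).dropna()).tolist()
    )
    sums = {lev: np.zeros((len(train_idx_times), T)) for lev in levels}
    counts = {lev: 0 for lev in levels}
    pooled: dict[str, list] = {lev: [] for lev in levels}

    skf = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
    clf = LogisticRegression(
        C=cfg.C, solver="lbfgs", max_iter=cfg.max_iter, tol=1e-4
    )
    for tr, te in skf.split(np.zeros(n), labels):
        y_tr, y_te = labels[tr], labels[te]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("single-class training fold; stratify labels")
        # decision scores for every (train time, test sample, test time)
        W = np.empty((len(train_idx_times), X.shape[1]))
        b = np.empty(len(train_idx_times))
        for j, ti in enumerate(train_idx_times):
            clf.fit(X[tr, :, ti], y_tr)
            W[j] = clf.coef_[0]
            b[j] = clf.intercept_[0]
        # scores[j, i, t] = W[j] . X[te_i, :, t] + b[j]
        scores = np.einsum("jc,ict->jit", W, X[te], optimize=True) + b[:, None, None]
        for lev in levels:
            if subset_labels is None:
                rows = np.arange(len(te))
            else:
                rows = np.flatnonzero(np.asarray(subset_labels)[te] == lev)
            y_lev = y_te[rows]
            if rows.size == 0 or len(np.unique(y_lev)) < 2:
                logger.info("subset %r skipped in one test fold", lev)
                continue
            if cfg.pool_folds:
                pooled[lev].append((scores[:, rows, :], y_lev))
            else:
                auc = np.stack(
                    [_auc_columns(scores[j, rows, :], y_lev) for j in range(len(W))]
                )
                sums[lev] += auc
            counts[lev] += 1

    out: dict[str, TGMatrix] = {}
    for lev in levels:
        if counts[lev] == 0:
            warnings.warn(f"subset level {lev!r} absent from all test folds; omitted")
            continue
        if cfg.pool_folds:
            sc = np.concatenate([s for s, _ in pooled[lev]], axis=1)
            yy = np.concatenate([y for _, y in pooled[lev]])
            values = np.stack(
                [_auc_columns(sc[j], yy) for j in range(sc.shape[0])]
            )
        else:
            values = sums[lev] / counts[lev]
        out[lev] = TGMatrix(
            values,
            epochs.times_s[train_idx_times],
            epochs.times_s,
            feature=feature,
            subject=subject,
            subset=lev,
        )
    if subset_labels is None:
        return out["all"]
    return out


def tg_decode_subsets(
    epochs: EpochSet,
    labels: np.ndarray,
    subset_labels: np.ndarray,
    cfg: DecodeConfig | None = None,
    **kw,
) -> dict[str, TGMatrix]:
    """Subset-wise TG decoding (train on all, test per level)."""
    out = tg_decode(epochs, labels, cfg, subset_labels=subset_labels, **kw)
    assert isinstance(out, dict)
    return out


def decode_all_features(
    epochs: EpochSet,
    table: FeatureTable,
    cfg: DecodeConfig | None = None,
    subject: str = "",
) -> tuple[list[TGMatrix], TGMatrix]:
    """One TG matrix per retained feature plus their unweighted mean.

    A feature whose decoding fails (e.g. too few events in a class for
    stratified folds) is dropped with a warning rather than aborting.
    """
    if len(table.matrix) != epochs.n_epochs:
        raise ValueError("feature table not aligned with epochs")
    cfg = cfg or DecodeConfig()
    mats: list[TGMatrix] = []
    for name in table.feature_names:
        y = table.column(name)
        logger.info("feature %s: prevalence %.3f", name, y.mean())
        try:
            tg = tg_decode(epochs, y, cfg, feature=name, subject=subject)
        except ValueError as err:
            warnings.warn(f"feature {name!r} dropped: {err}")
            continue
        assert isinstance(tg, TGMatrix)
        mats.append(tg)
    if not mats:
        raise ValueError("all features failed to decode")
    avg = replace(
        mats[0],
        values=np.mean([m.values for m in mats], axis=0),
        feature="average",
    )
    return mats, avg


def decode_per_sensor(
    epochs: EpochSet,
    table: FeatureTable,
    cfg: DecodeConfig | None = None,
) -> np.ndarray:
    """Cross-validated AUC per sensor, averaged over features.

    The decoder input for a sensor is that sensor's full epoch timecourse
    (all time samples as features); the result is a topography vector of
    length n_sensors.
    """
    cfg = cfg or DecodeConfig()
    n_sensors = epochs.data.shape[1]
    clf = LogisticRegression(
        C=cfg.C, solver="lbfgs", max_iter=cfg.max_iter, tol=1e-4
    )
    scores = np.zeros(n_sensors)
    n_used = 0
    for name in table.feature_names:
        y = table.column(name)
        try:
            y = _check_labels(y, cfg.n_folds)
        except ValueError as err:
            warnings.warn(f"feature {name!r} skipped in sensor decoding: {err}")
            continue
        skf = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
        per_sensor = np.zeros(n_sensors)
        for tr, te in skf.split(np.zeros(len(y)), y):
            for s in range(n_sensors):
                clf.fit(epochs.data[tr, s, :], y[tr])
                dec = epochs.data[te, s, :] @ clf.coef_[0] + clf.intercept_[0]
                per_sensor[s] += _auc_columns(dec[:, None], y[te])[0]
        scores += per_sensor / cfg.n_folds
        n_used += 1
    if n_used == 0:
        raise ValueError("no feature could be decoded per sensor")
    return scores / n_used
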