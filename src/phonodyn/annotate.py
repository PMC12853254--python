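"""Phoneme-level annotations: phonetic features, word positions, cohort entropy.

A multi-value phonetic feature system over five classes — voicing (2),
manner of articulation (6), place of articulation (8), roundness (2) and
front-backness (3) — yields a 21-column binary indicator table per phoneme
event.  Features active for fewer than 5% of events are pruned.  Each event
also receives its position within the word (from onset and from offset) and,
for non-word-initial phonemes, the Shannon entropy of the frequency-weighted
cohort of lexicon words compatible with the phonemes heard so far; entropy
values are split at the 33rd/66th percentiles into low/mid/high conditions.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import Lexicon

logger = logging.getLogger(__name__)

#: The 21 features, in canonical column order (class by class).
FEATURE_NAMES: tuple[str, ...] = (
    "voiced", "unvoiced",
    "nasal", "fricative", "occlusive", "approximant", "short_vowel", "long_vowel",
    "dental", "coronal", "glottal", "labial", "velar", "low", "mid", "high",
    "rounded", "unrounded",
    "front", "central", "back",
)

#: Feature-class membership, used for documentation and map validation.
FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "voicing": ("voiced", "unvoiced"),
    "manner": ("nasal", "fricative", "occlusive", "approximant",
               "short_vowel", "long_vowel"),
    "place": ("dental", "coronal", "glottal", "labial", "velar",
              "low", "mid", "high"),
    "roundness": ("rounded", "unrounded"),
    "frontback": ("front", "central", "back"),
}


def load_feature_map(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load a phoneme → feature-set map from TSV.

    The shipped default covers a Dutch (CGN-style) phone set: consonants
    carry voicing + manner + place + roundness (4 active features), vowels
    additionally carry front-backness (5).  The map is data, not algorithm —
    users may supply their own TSV with columns ``phoneme`` plus one column
    per feature class ('.' marks an inapplicable class).
    """
    if path is None:
        ref = importlib.resources.files("phonodyn") / "data" / "dutch_feature_map.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    fmap: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        phoneme = d.pop("phoneme")
        feats = frozenset(v for v in d.values() if v and v != ".")
        unknown = feats - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)} for {phoneme!r}")
        fmap[phoneme] = feats
    return fmap


@dataclass
class FeatureTable:
    """Events × features binary indicator matrix.

    ``matrix`` is int8 {0,1} of shape (n_events, n_features); ``rates`` is
    the per-feature fraction of events with the feature active.
    """

    matrix: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix shape inconsistent with feature names")

    @property
    def rates(self) -> np.ndarray:
        if len(self.matrix) == 0:
            return np.zeros(len(self.feature_names))
        return self.matrix.mean(axis=0)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.feature_names.index(name)]

    def select(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.matrix[rows], self.feature_names)


def build_feature_table(
    events: pd.DataFrame, feature_map: dict[str, frozenset[str]] | None = None
) -> FeatureTable:
    """Binary 21-column feature table for the events' phonemes.

    Raises ``KeyError`` listing any phoneme labels missing from the map.
    """
    if feature_map is None:
        feature_map = load_feature_map()
    phonemes = events["phoneme"].tolist()
    missing = sorted({p for p in phonemes if p not in feature_map})
    if missing:
        raise KeyError(f"phonemes missing from feature map: {missing}")
    col = {name: j for j, name in enumerate(FEATURE_NAMES)}
    matrix = np.zeros((len(phonemes), len(FEATURE_NAMES)), dtype=np.int8)
    for i, p in enumerate(phonemes):
        for feat in feature_map[p]:
            matrix[i, col[feat]] = 1
    return FeatureTable(matrix, FEATURE_NAMES)


def prune_rare_features(table: FeatureTable, threshold: float = 0.05) -> FeatureTable:
    """Drop features active in strictly fewer than ``threshold`` of events.

    Survivor order is preserved.  Raises if the table is empty or pruning
    would remove every feature.
    """
    if len(table.matrix) == 0:
        raise ValueError("cannot prune an empty table")
    keep = table.rates >= threshold
    if not keep.any():
        raise ValueError("pruning removed all features")
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    if dropped:
        logger.info("pruned %d rare features: %s", len(dropped), dropped)
    names = tuple(n for n, k in zip(table.feature_names, keep) if k)
    return FeatureTable(table.matrix[:, keep], names)


def assign_positions(events: pd.DataFrame, max_position: int = 5) -> pd.DataFrame:
    """Serialize phoneme positions within words (from onset and from offset).

    Requires events sorted by onset with non-decreasing ``word_index``.
    Adds ``position_from_onset`` (1..L), ``position_from_offset`` (L..1) and
    ``in_position_subset`` (both positions ≤ ``max_position``; deeper
    positions are kept but flagged out of the position-subset analyses).
    """
    ev = events.copy()
    if not ev["onset_s"].is_monotonic_increasing:
        raise ValueError("events must be sorted by onset")
    if not ev["word_index"].is_monotonic_increasing:
        raise ValueError("word_index must be non-decreasing")
    pos = ev.groupby("word_index").cumcount().to_numpy() + 1
    length = ev.groupby("word_index")["word_index"].transform("size").to_numpy()
    ev["position_from_onset"] = pos
    ev["position_from_offset"] = length - pos + 1
    ev["in_position_subset"] = (ev["position_from_onset"] <= max_position) & (
        ev["position_from_offset"] <= max_position
    )
    return ev


def cohort_entropy(
    events: pd.DataFrame,
    lexicon: Lexicon,
    frequency_weighted: bool = True,
) -> pd.DataFrame:
    """Shannon entropy (bits) of the activated cohort at each phoneme.

    The cohort at event *i* is the set of lexicon words whose pronunciation
    begins with the phonemes heard so far within the current word, inclusive
    of the current phoneme (the word being heard is itself a member).  With
    frequency weighting, p(w) = freq(w) / Σ cohort freq; otherwise uniform.

    Word-initial phonemes (position_from_onset == 1) and empty-cohort events
    receive NaN entropy.  Adds an ``entropy_bits`` column.
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    ev = events.copy()
    prons = [lexicon.pronunciation(w) for w in lexicon.words]
    freqs = np.array([lexicon.frequency(w) for w in lexicon.words], dtype=float)
    # prefix → cohort frequency vector is recomputed per unique prefix, cached
    cache: dict[tuple[str, ...], float] = {}

    def entropy_of_prefix(prefix: tuple[str, ...]) -> float:
        if prefix in cache:
            return cache[prefix]
        mask = np.fromiter(
            (len(p) >= len(prefix) and p[: len(prefix)] == prefix for p in prons),
            dtype=bool,
            count=len(prons),
        )
        if not mask.any():
            h = np.nan
        else:
            w = freqs[mask] if frequency_weighted else np.ones(mask.sum())
            p = w / w.sum()
            h = float(max(0.0, -(p * np.log2(p)).sum()))
        cache[prefix] = h
        return h

    out = np.full(len(ev), np.nan)
    n_empty = 0
    phon = ev["phoneme"].tolist()
    pos = ev["position_from_onset"].to_numpy()
    for i in range(len(ev)):
        if pos[i] == 1:
            continue  # word-initial: excluded from the cohort analysis
        prefix = tuple(phon[i - pos[i] + 1 : i + 1])
        h = entropy_of_prefix(prefix)
        if np.isnan(h):
            n_empty += 1
        out[i] = h
    if n_empty:
        logger.info("cohort undefined (empty) for %d events", n_empty)
    ev["entropy_bits"] = out
    return ev


def entropy_tertiles(events: pd.DataFrame) -> pd.DataFrame:
    """Split entropy values into thirds at the 33rd/66th percentiles.

    Percentiles use linear interpolation over all entropy-bearing events;
    values tied with a cut point fall to the lower tertile (low: h ≤ p33;
    mid: p33 < h ≤ p66; high: h > p66).  Adds an ``entropy_tertile`` column
    with values {'low','mid','high'} (NaN-entropy events get NA).
    """
    ev = events.copy()
    h = ev["entropy_bits"].to_numpy(dtype=float)
    valid = ~np.isnan(h)
    if valid.sum() < 3:
        raise ValueError("need at least 3 events with entropy to form tertiles")
    vals = h[valid]
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate entropy distribution (all values equal)")
    p33, p66 = np.percentile(vals, [100 / 3, 200 / 3], method="linear")
    lab = np.full(len(ev), None, dtype=object)
    lab[valid & (h <= p33)] = "low"
    lab[valid & (h > p33) & (h <= p66)] = "mid"
    lab[valid & (h > p66)] = "high"
    n_ties = int(np.sum(np.isclose(vals, p33)) + np.sum(np.isclose(vals, p66)))
    if n_ties:
        logger.info("%d entropy values tied with a tertile cut point", n_ties)
    ev["entropy_tertile"] = lab
    return ev


def annotate_events(
    events: pd.DataFrame,
    lexicon: Lexicon,
    feature_map: dict[str, frozenset[str]] | None = None,
    prune_threshold: float = 0.05,
) -> tuple[pd.DataFrame, FeatureTable]:
    """Full annotation chain: positions → entropy → tertiles → feature table.

    Returns the annotated events plus the pruned feature table (aligned
    row-for-row with the events).
    """
    ev = assign_positions(events)
    ev = cohort_entropy(ev, lexicon)
    ev = entropy_tertiles(ev)
    table = prune_rare_features(build_feature_table(ev, feature_map), prune_threshold)
    return ev, table
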