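"""Shared fixtures: toy lexica, event tables and epoch factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phonodyn.lexicon import Lexicon
from phonodyn.preprocess import EpochSet
from phonodyn.simulate import standard_montage


@pytest.fixture
def toy_lexicon() -> Lexicon:
    """Three /ka/-onset words with frequencies 10/30/60."""
    return Lexicon(
        {
            "kat": (("k", "a", "t"), 10),
            "kap": (("k", "a", "p"), 30),
            "kan": (("k", "a", "n"), 60),
        }
    )


def make_events(words: list[tuple[str, tuple[str, ...]]], dur: float = 0.07) -> pd.DataFrame:
    """Contiguous events from a list of (word, phoneme sequence)."""
    rows, t = [], 0.0
    for wi, (word, phones) in enumerate(words):
        for pos, ph in enumerate(phones, start=1):
            rows.append((t, dur, ph, word, wi, pos))
            t += dur
    return pd.DataFrame(
        rows,
        columns=["onset_s", "duration_s", "phoneme", "word", "word_index",
                 "position_from_onset"],
    )


@pytest.fixture
def events_factory():
    return make_events


def make_epochs(
    n_events: int = 200,
    n_channels: int = 16,
    n_times: int = 40,
    fs: float = 128.0,
    seed: int = 0,
) -> EpochSet:
    """Noise-only epochs with a plausible metadata table."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_events, n_channels, n_times))
    t0 = -8  # samples before onset
    times = (np.arange(n_times) + t0) / fs
    events = pd.DataFrame(
        {
            "onset_s": np.arange(n_events) * 0.07 + 1.0,
            "duration_s": 0.07,
            "phoneme": ["t"] * n_events,
            "word": ["w"] * n_events,
            "word_index": np.arange(n_events),
            "source_row": np.arange(n_events),
        }
    )
    names, pos = standard_montage(64)
    return EpochSet(data, times, fs, events, names[:n_channels], pos[:n_channels])


@pytest.fixture
def epochs_factory():
    return make_epochs
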