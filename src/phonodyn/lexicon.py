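"""Pronunciation lexicon with word frequencies, and phoneme-sequence sampling.

The lexicon plays the role of the SUBTLEX-style frequency database plus a
pronunciation dictionary: every entry maps a word label to a phoneme sequence
and a positive occurrence count.  It drives two things downstream:

* utterance sampling for the synthetic-EEG generator (words drawn with
  probability proportional to frequency), and
* the cohort model — the set of words compatible with a phoneme prefix —
  whose Shannon entropy quantifies lexical uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default phoneme inventory for synthetic lexica: the common subset of the
#: shipped Dutch (CGN-style) phone set.  Rare loan phones (dental fricatives)
#: are deliberately excluded so their features stay rare, as in natural Dutch.
DEFAULT_INVENTORY: tuple[str, ...] = (
    "p", "b", "t", "d", "k", "f", "v", "s", "z", "x", "G", "h",
    "m", "n", "N", "l", "r", "w", "j",
    "I", "E", "A", "O", "@", "i", "e", "o", "a", "u", "Ei", "Au",
)

#: Phoneme-duration model of the stimulus narrative: (median_s, min_s, max_s).
DEFAULT_DURATION_MODEL: tuple[float, float, float] = (0.070, 0.029, 0.359)


@dataclass
class Lexicon:
    """Map from word label to (phoneme sequence, frequency).

    Invariants: all frequencies strictly positive, all pronunciations
    non-empty.  ``entries`` preserves insertion order (rank order for
    generated lexica).
    """

    entries: dict[str, tuple[tuple[str, ...], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for word, (phones, freq) in self.entries.items():
            if freq <= 0:
                raise ValueError(f"non-positive frequency for word {word!r}")
            if len(phones) == 0:
                raise ValueError(f"empty pronunciation for word {word!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def words(self) -> list[str]:
        return list(self.entries)

    def pronunciation(self, word: str) -> tuple[str, ...]:
        return self.entries[word][0]

    def frequency(self, word: str) -> int:
        return self.entries[word][1]

    def phoneme_inventory(self) -> set[str]:
        inv: set[str] = set()
        for phones, _ in self.entries.values():
            inv.update(phones)
        return inv

    # -- TSV round trip (word, space-separated pronunciation, frequency) --

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "word": list(self.entries),
                "pronunciation": [" ".join(p) for p, _ in self.entries.values()],
                "frequency": [f for _, f in self.entries.values()],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        df = pd.read_csv(path, sep="\t", dtype={"word": str, "pronunciation": str})
        entries = {
            str(r.word): (tuple(str(r.pronunciation).split()), int(r.frequency))
            for r in df.itertuples()
        }
        return cls(entries)


def generate_lexicon(
    n_words: int,
    phoneme_inventory: tuple[str, ...] = DEFAULT_INVENTORY,
    length_range: tuple[int, int] = (2, 7),
    zipf_exponent: float = 1.0,
    seed: int = 0,
    base_count: int = 100_000,
    phonotactics: str = "cv",
) -> Lexicon:
    """Generate a lexicon of unique random words with Zipf frequencies.

    Word *r* (1-based rank) receives frequency ``round(base_count / r**s)``
    (floored at 1), so the rank-1/rank-2 ratio is ``2**s`` up to rounding.

    ``phonotactics`` controls the word template:

    * ``'cv'`` (default): consonant/vowel alternation with Zipf-skewed
      within-class phoneme probabilities — natural-like prefix sharing, so
      cohort entropy is graded; but features of neighbouring phonemes are
      statistically dependent (a co-articulation-like confound).
    * ``'iid'``: every slot drawn uniformly from the full inventory — a
      controlled stimulus in which neighbouring phonemes carry no
      information about each other, isolating the current phoneme's
      encoding geometry.

    Raises
    ------
    ValueError
        If ``n_words < 2`` or the inventory/length range cannot yield
        ``n_words`` distinct sequences.
    """
    if n_words < 2:
        raise ValueError("a lexicon needs at least 2 words")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    n_possible = sum(len(phoneme_inventory) ** L for L in range(lo, hi + 1))
    if n_possible < n_words:
        raise ValueError(
            f"inventory of {len(phoneme_inventory)} phonemes with lengths "
            f"{lo}-{hi} admits only {n_possible} distinct words; "
            f"{n_words} requested"
        )
    if phonotactics not in ("cv", "iid"):
        raise ValueError(f"unknown phonotactics {phonotactics!r}")
    rng = np.random.default_rng(seed)
    inv = list(phoneme_inventory)
    # Phonotactic structure: words alternate consonant/vowel slots, and
    # phonemes are drawn with Zipf-skewed within-class probabilities.  Both
    # choices emulate natural lexica, where shared onsets make cohorts large
    # and lexical entropy graded rather than degenerate.
    vowel_set = {"I", "E", "A", "O", "Y", "@", "i", "y", "u", "e", "2", "o",
                 "a", "Ei", "9y", "Au"}
    cons = [p for p in inv if p not in vowel_set] or inv
    vows = [p for p in inv if p in vowel_set] or inv

    def class_probs(k: int) -> np.ndarray:
        w = 1.0 / np.arange(1, k + 1) ** 0.8
        return w / w.sum()

    p_cons, p_vows = class_probs(len(cons)), class_probs(len(vows))
    seen: set[tuple[str, ...]] = set()
    pronunciations: list[tuple[str, ...]] = []
    max_tries = 200 * n_words
    tries = 0
    while len(pronunciations) < n_words:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "inventory too small to produce the requested number of "
                "unique words under the phonotactic template"
            )
        L = int(rng.integers(lo, hi + 1))
        if phonotactics == "iid":
            phones = tuple(inv[i] for i in rng.integers(0, len(inv), size=L))
        else:
            start_vowel = bool(rng.random() < 0.4)
            phones = []
            for j in range(L):
                if (j % 2 == 0) != start_vowel:
                    phones.append(cons[rng.choice(len(cons), p=p_cons)])
                else:
                    phones.append(vows[rng.choice(len(vows), p=p_vows)])
            phones = tuple(phones)
        if phones not in seen:
            seen.add(phones)
            pronunciations.append(phones)
    entries = {}
    for rank, phones in enumerate(pronunciations, start=1):
        freq = max(1, round(base_count / rank**zipf_exponent))
        entries[f"w{rank:04d}"] = (phones, freq)
    return Lexicon(entries)


def sample_utterance(
    lexicon: Lexicon,
    n_words: int,
    phoneme_duration_model: tuple[float, float, float] = DEFAULT_DURATION_MODEL,
    seed: int = 0,
    start_s: float = 0.0,
    sigma_log: float = 0.45,
) -> pd.DataFrame:
    """Sample a contiguous stream of phoneme events from the lexicon.

    Words are drawn i.i.d. with probability proportional to frequency.
    Phoneme durations are log-normal with the stated median, clipped to
    ``[min_s, max_s]``; because both clip bounds straddle the median, the
    clip leaves the median untouched.

    Returns a DataFrame with columns ``onset_s, duration_s, phoneme, word,
    word_index, position_from_onset`` sorted by onset; events are contiguous
    (each onset equals the previous onset plus duration).
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    median_s, min_s, max_s = phoneme_duration_model
    if not (min_s <= median_s <= max_s):
        raise ValueError("duration model must satisfy min <= median <= max")
    rng = np.random.default_rng(seed)
    words = lexicon.words
    freqs = np.array([lexicon.frequency(w) for w in words], dtype=float)
    p = freqs / freqs.sum()
    choice = rng.choice(len(words), size=n_words, p=p)

    rows: list[tuple] = []
    t = float(start_s)
    for wi, idx in enumerate(choice):
        word = words[idx]
        phones = lexicon.pronunciation(word)
        durs = np.clip(
            np.exp(np.log(median_s) + sigma_log * rng.standard_normal(len(phones))),
            min_s,
            max_s,
        )
        for pos, (ph, d) in enumerate(zip(phones, durs), start=1):
            rows.append((t, float(d), ph, word, wi, pos))
            t += float(d)
    return pd.DataFrame(
        rows,
        columns=[
            "onset_s", "duration_s", "phoneme", "word", "word_index",
            "position_from_onset",
        ],
    )
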