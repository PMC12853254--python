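"""Synthetic continuous EEG with a known dynamic-coding ground truth.

The forward model realizes the hierarchical-dynamic-coding scheme: each
phonetic feature of each phoneme evokes a response that lives in a sequence
of mutually orthogonal spatial patterns.  The active pattern is handed off
every ``dwell_tau_s`` seconds (constant amplitude within a dwell,
instantaneous handoff smoothed downstream by the low-pass filter), for a
total encoding duration ``encode_duration_s`` starting ``response_onset_s``
after phoneme onset.  A per-group gain profile
— a step function of time since phoneme onset — scales the response, which
lets a clinical-like group lose encoding strength after an initial shared
window.  Responses of successive phonemes overlap, as in natural listening.
High-entropy phonemes may receive an extended encoding duration
(``entropy_duration_bonus_s``), emulating uncertainty-contingent encoding.

Noise is an equal-power pink (1/f) + white mixture, i.i.d. across channels,
scaled so that ``snr`` equals the response-vector norm over the per-channel
noise standard deviation.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import FeatureTable

logger = logging.getLogger(__name__)

#: gain profile: list of (start_s_since_onset, gain) steps, first start at 0.
GainProfile = list[tuple[float, float]]

DEFAULT_GAIN_PROFILES: dict[str, GainProfile] = {
    "control": [(0.0, 1.0)],
    "aphasia": [(0.0, 1.0), (0.08, 0.4)],
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the recording setup (64 channels, 128 Hz after
    preprocessing) and the dynamic-coding parameters (pattern dwell 0.08 s,
    encoding duration 0.3 s).  ``snr`` is the response amplitude (pattern
    norm) divided by the per-channel noise standard deviation.
    """

    n_channels: int = 64
    sampling_rate_hz: float = 128.0
    n_subjects_per_group: int = 6
    duration_s: float | None = None  # derived from events when None
    dwell_tau_s: float = 0.08
    encode_duration_s: float = 0.3
    response_onset_s: float = 0.05
    snr: float = 2.0
    group_gain_profile: dict[str, GainProfile] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GAIN_PROFILES.items()}
    )
    entropy_duration_bonus_s: float | dict[str, float] = 0.0
    signal_features: tuple[str, ...] | None = None  # None → all table features
    pink_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_tau_s > self.encode_duration_s:
            raise ValueError("dwell_tau_s must not exceed encode_duration_s")
        for group, profile in self.group_gain_profile.items():
            for _, g in profile:
                if not (0.0 <= g <= 1.0):
                    raise ValueError(f"gain out of [0,1] in profile for {group!r}")

    def bonus_for(self, group: str) -> float:
        if isinstance(self.entropy_duration_bonus_s, dict):
            return float(self.entropy_duration_bonus_s.get(group, 0.0))
        return float(self.entropy_duration_bonus_s)

    def max_bonus(self) -> float:
        if isinstance(self.entropy_duration_bonus_s, dict):
            return max([0.0, *self.entropy_duration_bonus_s.values()])
        return float(self.entropy_duration_bonus_s)


@dataclass
class GroundTruth:
    """Injected spatial code: per-feature pattern sequences plus timing.

    ``patterns[f]`` has shape (n_patterns, n_channels) with unit-norm rows;
    consecutive rows are orthogonal by construction.  ``realized_duration_s``
    is filled per event by :func:`simulate_subject`.
    """

    patterns: dict[str, np.ndarray]
    dwell_tau_s: float
    encode_duration_s: float
    group_gain_profile: dict[str, GainProfile]
    realized_duration_s: np.ndarray | None = None


@dataclass
class ContinuousEEG:
    """Channels × samples array with labels and 3D sensor positions."""

    data: np.ndarray
    sampling_rate_hz: float
    ch_names: list[str]
    ch_pos: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel labels do not match data")
        if self.ch_pos.shape != (self.data.shape[0], 3):
            raise ValueError("channel positions do not match data")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples in EEG data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, sampling_rate_hz: float | None = None):
        return ContinuousEEG(
            data,
            sampling_rate_hz or self.sampling_rate_hz,
            list(self.ch_names),
            self.ch_pos.copy(),
        )


def standard_montage(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Channel labels and 3D positions of the standard 64-channel montage.

    Uses the BioSemi 64-electrode layout; for other channel counts a
    Fibonacci arrangement on the upper hemisphere is generated.
    """
    if n_channels == 64:
        from mne.channels import make_standard_montage

        m = make_standard_montage("biosemi64")
        pos = m.get_positions()["ch_pos"]
        names = list(m.ch_names)
        return names, np.array([pos[ch] for ch in names])
    # generic fallback: points on the upper half of a 9.5 cm sphere
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = 0.05 + 0.95 * (i + 0.5) / n_channels
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    xyz = 0.095 * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return [f"CH{k + 1:02d}" for k in i], xyz


def gain_at(profile: GainProfile, t_since_onset: np.ndarray) -> np.ndarray:
    """Evaluate a step gain profile at times since phoneme onset."""
    steps = sorted(profile)
    out = np.full_like(np.asarray(t_since_onset, dtype=float), steps[0][1])
    for start, g in steps:
        out[t_since_onset >= start] = g
    return out


def make_ground_truth(
    features: tuple[str, ...], cfg: SimConfig, seed: int | None = None
) -> GroundTruth:
    """Draw the per-feature pattern sequences.

    ``ceil(encode_duration_s / dwell_tau_s)`` patterns per feature (plus
    extra patterns covering any entropy duration bonus).  Each pattern is a
    unit-norm random vector orthogonalized against its predecessor, so
    consecutive patterns have exactly zero cosine.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    d_max = cfg.encode_duration_s + cfg.max_bonus()
    n_patterns = math.ceil(round(d_max / cfg.dwell_tau_s, 9))
    patterns: dict[str, np.ndarray] = {}
    for f in features:
        mats = np.empty((n_patterns, cfg.n_channels))
        prev = None
        for k in range(n_patterns):
            v = rng.standard_normal(cfg.n_channels)
            if prev is not None:
                v -= (v @ prev) * prev
            v /= np.linalg.norm(v)
            mats[k] = v
            prev = v
        patterns[f] = mats
    return GroundTruth(
        patterns,
        cfg.dwell_tau_s,
        cfg.encode_duration_s,
        {k: list(v) for k, v in cfg.group_gain_profile.items()},
    )


def _response_kernel(
    patterns: np.ndarray,
    duration_s: float,
    cfg: SimConfig,
    profile: GainProfile,
) -> np.ndarray:
    """Channels × samples response to one phoneme for one feature.

    Pattern k is active at constant amplitude on dwell interval
    [kτ, (k+1)τ) after response onset and hands off to pattern k+1 at the
    boundary; the response stops at ``duration_s``.  Transitions are
    instantaneous in the forward model — the pipeline's low-pass filter
    supplies the physiological smoothing — so a decoder trained inside one
    dwell generalizes over exactly that dwell, making the injected dwell
    time exactly recoverable.  The group gain profile multiplies in as a
    function of time since phoneme onset.
    """
    fs = cfg.sampling_rate_hz
    tau = cfg.dwell_tau_s
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs  # since response onset
    k = np.minimum(np.floor(t / tau).astype(int), patterns.shape[0] - 1)
    kern = patterns[k].T.copy()  # (C, n)
    kern[:, t > duration_s] = 0.0
    g = gain_at(profile, t + cfg.response_onset_s)
    return kern * g


def _pink_white_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, pink_fraction: float
) -> np.ndarray:
    """Unit-variance per-channel mixture of 1/f and white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    if pink_fraction <= 0:
        return white
    spec = np.fft.rfft(rng.standard_normal((n_channels, n_samples)), axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    mix = np.sqrt(pink_fraction) * pink + np.sqrt(1 - pink_fraction) * white
    return mix / mix.std(axis=1, keepdims=True)


def simulate_subject(
    events: pd.DataFrame,
    features: FeatureTable,
    truth: GroundTruth,
    cfg: SimConfig,
    group: str = "control",
    seed: int = 0,
) -> tuple[ContinuousEEG, GroundTruth]:
    """Render one subject's continuous EEG from events + ground truth.

    EEG = Σ over events, Σ over that event's active features, of the gained
    pattern-sequence response, plus pink/white noise; deterministic given
    ``seed``.  Events whose response would extend past the end of the signal
    are truncated (with a warning).  Returns the EEG and a ground-truth copy
    carrying the per-event realized encoding durations.
    """
    if len(events) != len(features.matrix):
        raise ValueError("feature table rows must match event count")
    if group not in cfg.group_gain_profile:
        raise ValueError(f"no gain profile for group {group!r}")
    fs = cfg.sampling_rate_hz
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    duration_s = cfg.duration_s
    if duration_s is None:
        last = events["onset_s"].iloc[-1] + events["duration_s"].iloc[-1]
        duration_s = float(last) + 1.0
    n_samples = int(round(duration_s * fs))
    n_ch = cfg.n_channels
    signal = np.zeros((n_ch, n_samples))

    sig_features = [f for f in features.feature_names if f in truth.patterns]
    profile = cfg.group_gain_profile[group]
    bonus = cfg.bonus_for(group)

    # realized encoding duration per event
    base = truth.encode_duration_s
    realized = np.full(len(events), base)
    if bonus > 0:
        if "entropy_tertile" not in events.columns:
            raise ValueError("entropy bonus requires entropy_tertile annotations")
        high = (events["entropy_tertile"] == "high").to_numpy()
        realized[high] = base + bonus

    # kernels cached per (feature, realized duration)
    kernels: dict[tuple[str, float], np.ndarray] = {}
    onset_samples = np.round(events["onset_s"].to_numpy() * fs).astype(int)
    start_samples = onset_samples + int(round(cfg.response_onset_s * fs))
    n_truncated = 0
    if cfg.snr > 0:
        col = {f: features.feature_names.index(f) for f in sig_features}
        for i in range(len(events)):
            d = realized[i]
            for f in sig_features:
                if not features.matrix[i, col[f]]:
                    continue
                key = (f, d)
                if key not in kernels:
                    kernels[key] = _response_kernel(truth.patterns[f], d, cfg, profile)
                kern = kernels[key]
                s0 = start_samples[i]
                s1 = s0 + kern.shape[1]
                if s0 >= n_samples:
                    n_truncated += 1
                    continue
                if s1 > n_samples:
                    n_truncated += 1
                    kern = kern[:, : n_samples - s0]
                    s1 = n_samples
                signal[:, s0:s1] += kern
    if n_truncated:
        warnings.warn(
            f"{n_truncated} event responses truncated at end of signal",
            stacklevel=2,
        )
    noise = _pink_white_noise(rng, n_ch, n_samples, cfg.pink_fraction)
    data = cfg.snr * signal + noise
    names, pos = standard_montage(n_ch)
    eeg = ContinuousEEG(data, fs, names, pos)
    return eeg, replace(truth, realized_duration_s=realized)


def subject_seed(master_seed: int, group: str, subject_index: int) -> int:
    """Stable per-subject seed derived from (master seed, group, index)."""
    group_key = zlib.crc32(group.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), group_key, int(subject_index)])
    return int(ss.generate_state(1)[0] % (2**31))
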