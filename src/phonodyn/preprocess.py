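"""EEG conditioning chain and phoneme-locked epoching.

Fixed stage order, mirroring the acquisition pipeline of the study design:
common-average reference → least-squares FIR band-limiting (high-pass
0.45→0.5 Hz, low-pass 25→27.5 Hz) → downsampling to 128 Hz → per-channel
z-normalization over the whole recording → epoching from −0.2 to 0.6 s
around phoneme onsets.  No baseline correction and no post-epoch
normalization are applied.

Filters are linear-phase least-squares FIRs applied forward-backward, so
the net phase is zero (epoch latencies are untouched) and the effective
attenuation is the squared design response.  The nominal order 2000 refers
to a 512 Hz rate; by default the order scales with the sampling rate so the
impulse-response duration is rate-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .simulate import ContinuousEEG

logger = logging.getLogger(__name__)

#: (passband_hz, stopband_hz, order at 512 Hz)
DEFAULT_HIGHPASS = (0.5, 0.45, 2000)
DEFAULT_LOWPASS = (25.0, 27.5, 2000)
DEFAULT_WINDOW = (-0.2, 0.6)


@dataclass
class EpochSet:
    """Events × channels × time array locked to phoneme onsets.

    ``times_s`` is uniform at 1/sampling_rate_hz; ``events`` carries the
    (annotated) metadata row-aligned with ``data``.
    """

    data: np.ndarray
    times_s: np.ndarray
    sampling_rate_hz: float
    events: pd.DataFrame
    ch_names: list[str]
    ch_pos: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be events x channels x time")
        if self.data.shape[2] != len(self.times_s):
            raise ValueError("time axis mismatch")
        if len(self.events) != self.data.shape[0]:
            raise ValueError("metadata rows must match epochs")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in epochs")
        dt = np.diff(self.times_s)
        if not np.allclose(dt, 1.0 / self.sampling_rate_hz):
            raise ValueError("times_s must be uniform at 1/sampling_rate_hz")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, rows: np.ndarray) -> "EpochSet":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return EpochSet(
            self.data[rows],
            self.times_s,
            self.sampling_rate_hz,
            self.events.iloc[rows].reset_index(drop=True),
            self.ch_names,
            self.ch_pos,
        )


def rereference_common_average(eeg: ContinuousEEG) -> ContinuousEEG:
    """Subtract the instantaneous across-channel mean from every channel."""
    if eeg.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return eeg.copy_with(eeg.data - eeg.data.mean(axis=0, keepdims=True))


def design_fir(
    sampling_rate_hz: float,
    passband_hz: float,
    stopband_hz: float,
    order: int,
) -> np.ndarray:
    """Least-squares FIR design (high-pass if stopband < passband).

    ``order`` taps + 1 coefficients; the order is forced even so the filter
    has integer group delay (type-I linear phase).
    """
    order = int(order)
    if order % 2:
        order += 1
    nyq = sampling_rate_hz / 2.0
    if stopband_hz < passband_hz:  # high-pass
        bands = [0.0, stopband_hz, passband_hz, nyq]
        desired = [0.0, 0.0, 1.0, 1.0]
    else:  # low-pass
        bands = [0.0, passband_hz, stopband_hz, nyq]
        desired = [1.0, 1.0, 0.0, 0.0]
    return scipy.signal.firls(order + 1, bands, desired, fs=sampling_rate_hz)


def _apply_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR application (zero phase, attenuation squared).

    The signal is reflect-padded by the filter length on both sides so the
    output has the same length and no edge roll-in.
    """
    L = len(taps) - 1
    padded = np.pad(data, [(0, 0), (L, L)], mode="reflect")
    out = scipy.signal.oaconvolve(padded, taps[None, :], mode="full", axes=1)
    out = scipy.signal.oaconvolve(out, taps[None, ::-1], mode="full", axes=1)
    return out[:, 2 * L : 2 * L + data.shape[1]]


def fir_bandlimit(
    eeg: ContinuousEEG,
    highpass: tuple[float, float, int] | None = DEFAULT_HIGHPASS,
    lowpass: tuple[float, float, int] | None = DEFAULT_LOWPASS,
    scale_order_with_rate: bool = True,
) -> ContinuousEEG:
    """Band-limit with least-squares FIR high-pass and low-pass filters.

    Orders are interpreted at the 512 Hz design rate and scaled to the data's
    sampling rate when ``scale_order_with_rate`` (keeps the filter's
    time-domain support constant).  Raises if a filter is longer than the
    recording.
    """
    fs = eeg.sampling_rate_hz
    if lowpass is not None and fs <= 2 * lowpass[1]:
        raise ValueError("sampling rate must exceed twice the low-pass stopband")
    data = eeg.data
    for spec in (highpass, lowpass):
        if spec is None:
            continue
        pass_hz, stop_hz, order = spec
        if scale_order_with_rate:
            order = max(16, int(round(order * fs / 512.0)))
        if order >= data.shape[1]:
            raise ValueError(
                f"filter order {order} is not below signal length {data.shape[1]}"
            )
        taps = design_fir(fs, pass_hz, stop_hz, order)
        data = _apply_zero_phase(data, taps)
    return eeg.copy_with(data)


def resample(eeg: ContinuousEEG, target_hz: float = 128.0) -> ContinuousEEG:
    """Anti-aliased polyphase downsampling; onsets stay in seconds."""
    if target_hz > eeg.sampling_rate_hz:
        raise ValueError("upsampling is not supported")
    if target_hz == eeg.sampling_rate_hz:
        return eeg.copy_with(eeg.data.copy())
    frac = Fraction(target_hz / eeg.sampling_rate_hz).limit_denominator(1000)
    data = scipy.signal.resample_poly(eeg.data, frac.numerator, frac.denominator, axis=1)
    return eeg.copy_with(data, sampling_rate_hz=target_hz)


def normalize(eeg: ContinuousEEG) -> ContinuousEEG:
    """Per-channel z-score over the full recording."""
    mean = eeg.data.mean(axis=1, keepdims=True)
    std = eeg.data.std(axis=1, keepdims=True)
    flat = np.flatnonzero(std.ravel() == 0)
    if flat.size:
        names = [eeg.ch_names[i] for i in flat]
        raise ValueError(f"flat channel(s) cannot be normalized: {names}")
    return eeg.copy_with((eeg.data - mean) / std)


def epoch(
    eeg: ContinuousEEG,
    events: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> EpochSet:
    """Slice fixed-length windows around phoneme onsets.

    Onsets are rounded to the nearest sample; the epoch length is
    ``round((w1 - w0) * fs) + 1`` samples (103 at 128 Hz for −0.2..0.6 s).
    Events whose window exceeds the recording are dropped and counted in the
    log.  No baseline correction.
    """
    fs = eeg.sampling_rate_hz
    w0, w1 = window
    start_off = int(round(w0 * fs))
    n_times = int(round((w1 - w0) * fs)) + 1
    times = (np.arange(n_times) + start_off) / fs
    onset_samples = np.round(events["onset_s"].to_numpy() * fs).astype(int)
    starts = onset_samples + start_off
    ok = (starts >= 0) & (starts + n_times <= eeg.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d events outside the recording bounds", n_dropped)
    if not ok.any():
        raise ValueError("no events survive epoching")
    starts = starts[ok]
    idx = starts[:, None] + np.arange(n_times)[None, :]
    data = eeg.data[:, idx].transpose(1, 0, 2)  # events x channels x time
    ev_out = events.loc[ok].copy()
    ev_out["source_row"] = np.flatnonzero(ok)  # row into the pre-epoch table
    return EpochSet(
        np.ascontiguousarray(data),
        times,
        fs,
        ev_out.reset_index(drop=True),
        list(eeg.ch_names),
        eeg.ch_pos.copy(),
    )


def evoked_average(epochs: EpochSet) -> np.ndarray:
    """Mean over events: the channels × time auditory evoked response."""
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    return epochs.data.mean(axis=0)


def preprocess_chain(
    eeg: ContinuousEEG,
    events: pd.DataFrame,
    target_hz: float = 128.0,
    highpass: tuple[float, float, int] | None = DEFAULT_HIGHPASS,
    lowpass: tuple[float, float, int] | None = DEFAULT_LOWPASS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> EpochSet:
    """Full chain: reference → filter → resample → normalize → epoch."""
    logger.info(
        "preprocess chain: reference -> filter -> resample(%g Hz) -> normalize -> epoch",
        target_hz,
    )
    out = rereference_common_average(eeg)
    out = fir_bandlimit(out, highpass, lowpass)
    out = resample(out, target_hz)
    out = normalize(out)
    return epoch(out, events, window)
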