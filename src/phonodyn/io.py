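"""File formats: events/lexicon TSV, array containers with JSON sidecars.

Arrays are stored as ``.npy`` with a ``.json`` sidecar describing channels,
sampling rate and montage; events and lexica are plain TSV.  Real raw EEG
(BDF/FIF) is ingested through MNE's readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .simulate import ContinuousEEG

EVENT_COLUMNS = ["onset_s", "duration_s", "phoneme", "word", "word_index"]


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"phoneme": str, "word": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing columns: {missing}")
    return df


def write_eeg(eeg: ContinuousEEG, stem: str | Path) -> None:
    """Write ``<stem>.npy`` + ``<stem>.json`` (channels, rate, positions)."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), eeg.data)
    sidecar = {
        "sampling_rate_hz": eeg.sampling_rate_hz,
        "ch_names": eeg.ch_names,
        "ch_pos": eeg.ch_pos.tolist(),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def read_eeg(stem: str | Path) -> ContinuousEEG:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ContinuousEEG(
        data, meta["sampling_rate_hz"], meta["ch_names"], np.array(meta["ch_pos"])
    )


def read_raw_eeg(path: str | Path) -> ContinuousEEG:
    """Read a standard raw-EEG file (BDF/FIF/...) via MNE."""
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    raw.pick("eeg")
    montage = raw.get_montage()
    if montage is not None:
        pos_map = montage.get_positions()["ch_pos"]
        pos = np.array([pos_map.get(ch, [np.nan] * 3) for ch in raw.ch_names])
    else:
        pos = np.zeros((len(raw.ch_names), 3))
    return ContinuousEEG(raw.get_data(), raw.info["sfreq"], list(raw.ch_names), pos)


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialize a GroundTruth (patterns, timing, gains, realized durations)."""
    payload = {
        "dwell_tau_s": truth.dwell_tau_s,
        "encode_duration_s": truth.encode_duration_s,
        "group_gain_profile": truth.group_gain_profile,
        "patterns": {f: m.tolist() for f, m in truth.patterns.items()},
        "realized_duration_s": (
            None
            if truth.realized_duration_s is None
            else np.asarray(truth.realized_duration_s).tolist()
        ),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth

    d = json.loads(Path(path).read_text())
    return GroundTruth(
        {f: np.array(m) for f, m in d["patterns"].items()},
        d["dwell_tau_s"],
        d["encode_duration_s"],
        {g: [tuple(s) for s in p] for g, p in d["group_gain_profile"].items()},
        None if d["realized_duration_s"] is None else np.array(d["realized_duration_s"]),
    )


def write_epochs(epochs: EpochSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "epochs.npy", epochs.data)
    (d / "epochs.json").write_text(
        json.dumps(
            {
                "times_s": epochs.times_s.tolist(),
                "sampling_rate_hz": epochs.sampling_rate_hz,
                "ch_names": epochs.ch_names,
                "ch_pos": epochs.ch_pos.tolist(),
            }
        )
    )
    epochs.events.to_csv(d / "events.tsv", sep="\t", index=False)


def read_epochs(directory: str | Path) -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / "epochs.json").read_text())
    return EpochSet(
        np.load(d / "epochs.npy"),
        np.array(meta["times_s"]),
        meta["sampling_rate_hz"],
        pd.read_csv(d / "events.tsv", sep="\t", dtype={"phoneme": str, "word": str}),
        meta["ch_names"],
        np.array(meta["ch_pos"]),
    )
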