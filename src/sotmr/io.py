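"""Readers and writers for recordings, hypnograms, event tables and configs.

Recordings persist as NPZ (arrays) with TSV sidecars for the hypnogram
(onset, duration, stage) and cue events; configs round-trip through YAML.
EDF and BrainVision recordings are read through MNE when available on disk;
all in-repo data stays in plain-text/NPZ form.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .closed_loop import CueEvent
from .synthetic import SleepRecording

EVENT_COLUMNS = ["onset", "condition", "sound_type", "item", "block", "detected_trough_time"]


def save_recording(recording: SleepRecording, path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        data=recording.data,
        channel_labels=np.array(recording.channel_labels),
        sampling_rate=recording.sampling_rate,
        hypnogram=np.array(recording.hypnogram),
        arousals=np.array(recording.arousals, dtype=float).reshape(-1, 2),
    )


def load_recording(path) -> SleepRecording:
    with np.load(Path(path), allow_pickle=False) as f:
        return SleepRecording(
            data=f["data"],
            channel_labels=tuple(str(c) for c in f["channel_labels"]),
            sampling_rate=float(f["sampling_rate"]),
            hypnogram=tuple(str(s) for s in f["hypnogram"]),
            arousals=tuple((float(a), float(b)) for a, b in f["arousals"]),
        )


def read_raw_recording(path, hypnogram: tuple[str, ...] | None = None) -> SleepRecording:
    """Read an EDF or BrainVision (.vhdr) recording via MNE into µV arrays.

    EEG file formats carry no sleep staging; pass the hypnogram separately
    (default: all-N3, long enough to cover the recording).
    """
    import math

    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> µV
    duration = data.shape[1] / raw.info["sfreq"]
    if hypnogram is None:
        hypnogram = tuple(["N3"] * math.ceil(duration / SleepRecording.EPOCH_LEN))
    return SleepRecording(data=data, channel_labels=tuple(raw.ch_names),
                          sampling_rate=float(raw.info["sfreq"]), hypnogram=hypnogram)


def write_hypnogram_tsv(recording: SleepRecording, path) -> None:
    rows = [{"onset": i * SleepRecording.EPOCH_LEN, "duration": SleepRecording.EPOCH_LEN,
             "stage": s} for i, s in enumerate(recording.hypnogram)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path) -> tuple[str, ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(df.sort_values("onset")["stage"].astype(str))


def write_events_tsv(events: list[CueEvent], path) -> None:
    rows = [{c: getattr(ev, c) for c in EVENT_COLUMNS} for ev in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[CueEvent]:
    df = pd.read_csv(path, sep="\t")
    return [CueEvent(onset=float(r.onset), condition=str(r.condition),
                     sound_type=str(r.sound_type), item=str(r.item),
                     block=int(r.block), detected_trough_time=float(r.detected_trough_time))
            for r in df.itertuples()]


def save_config(config, path) -> None:
    """Serialise a dataclass config to YAML (tuples become lists)."""
    payload = dataclasses.asdict(config)
    payload["__type__"] = type(config).__name__
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(payload, default=_jsonable)), fh, sort_keys=False)


def load_config(path, cls):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload.pop("__type__", None)
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in field_types:
            raise KeyError(f"unknown field {key!r} for {cls.__name__}")
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
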