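"""Offline EEG preprocessing, epoching, ERPs, and Morlet time-frequency power.

Offline band limits are zero-phase cascaded Butterworth high- and low-pass
filters (order 4 per pass, two passes).
Cue-locked epochs span -1 to 3 s around sound onset; time-frequency power is
computed with Morlet wavelets from 4 to 20 Hz in 0.5 Hz steps, sampled from
-1 to 2.4 s in 50 ms steps (the 2.4 s cap keeps the 4-cycle wavelet at 4 Hz
inside the 3 s epoch tail), and normalised as relative change from the
-1 to 0 s pre-cue baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .montage import MASTOID_LABELS, channel_positions
from .synthetic import SleepRecording

logger = logging.getLogger(__name__)


def _two_pass_bandpass(data: np.ndarray, band: tuple[float, float], fs: float,
                       order: int = 4) -> np.ndarray:
    """Zero-phase band limit as cascaded high-pass + low-pass (Butterworth
    ``order`` per pass, two passes), matching separate low/high-pass steps."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, Nyquist={fs/2}) Hz")
    hp = sps.butter(order, low, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(lp, sps.sosfiltfilt(hp, data, axis=-1), axis=-1)


def preprocess(recording: SleepRecording, band: tuple[float, float] = (0.5, 30.0),
               bad_channels: list[str] | None = None) -> SleepRecording:
    """Band-pass 0.5-30 Hz (zero-phase), linked-mastoid re-reference when
    mastoid channels exist, and neighbour-average interpolation of a
    user-provided bad-channel list."""
    out = recording.copy()
    labels = list(out.channel_labels)
    bad = list(bad_channels or [])
    unknown = [b for b in bad if b not in labels]
    if unknown:
        raise KeyError(f"bad channels not in recording: {unknown}")
    if len(bad) == len(labels):
        raise ValueError("all channels marked bad; nothing to interpolate from")

    if bad:
        pos = channel_positions(tuple(labels))
        good_idx = [i for i, ch in enumerate(labels) if ch not in bad]
        for ch in bad:
            i = labels.index(ch)
            d = cdist(pos[i:i + 1], pos[good_idx])[0]
            neighbours = [good_idx[k] for k in np.argsort(d)[:4]]
            out.data[i] = out.data[neighbours].mean(axis=0)
        logger.info("interpolated %d bad channels by neighbour average: %s", len(bad), bad)

    out.data = _two_pass_bandpass(out.data, band, out.sampling_rate)

    mastoids = [ch for ch in MASTOID_LABELS if ch in labels]
    if mastoids:
        ref = out.data[[labels.index(ch) for ch in mastoids]].mean(axis=0)
        out.data = out.data - ref[None, :]
        logger.info("re-referenced to linked mastoids (%s)", mastoids)
    else:
        logger.warning("no mastoid channels present; keeping the original reference")
    return out


@dataclass
class EpochSet:
    """Cue-locked epochs (epochs x channels x samples, µV) with metadata."""

    data: np.ndarray
    times: np.ndarray                 # seconds relative to cue onset
    sampling_rate: float
    channel_labels: tuple[str, ...]
    metadata: pd.DataFrame            # one row per epoch (condition, sound_type, item, block)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata rows must match epoch count")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("epoch window must cover cue onset (time 0)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, **criteria) -> "EpochSet":
        mask = np.ones(self.n_epochs, dtype=bool)
        for key, value in criteria.items():
            mask &= (self.metadata[key] == value).to_numpy()
        return EpochSet(self.data[mask], self.times, self.sampling_rate,
                        self.channel_labels, self.metadata[mask].reset_index(drop=True))


def epoch(recording: SleepRecording, events, window: tuple[float, float] = (-1.0, 3.0)) -> EpochSet:
    """Cut one epoch per event; events with partial coverage are dropped (logged)."""
    events = list(events)
    if not events:
        raise ValueError("no events to epoch")
    fs = recording.sampling_rate
    n0 = int(round(window[0] * fs))
    n1 = int(round(window[1] * fs))
    rows, chunks, dropped = [], [], 0
    for ev in events:
        onset = getattr(ev, "onset", ev)
        i = int(round(onset * fs))
        if i + n0 < 0 or i + n1 > recording.n_samples:
            dropped += 1
            continue
        chunks.append(recording.data[:, i + n0:i + n1])
        rows.append({
            "onset": onset,
            "condition": getattr(ev, "condition", None),
            "sound_type": getattr(ev, "sound_type", None),
            "item": getattr(ev, "item", None),
            "block": getattr(ev, "block", None),
        })
    if dropped:
        logger.info("dropped %d events with partial epoch coverage", dropped)
    if not chunks:
        raise ValueError("every event fell outside the recording")
    times = (np.arange(n0, n1)) / fs
    return EpochSet(np.stack(chunks), times, fs, tuple(recording.channel_labels),
                    pd.DataFrame(rows))


@dataclass
class ERP:
    mean: np.ndarray   # channels x samples
    sem: np.ndarray
    n: int


def compute_erp(epochs: EpochSet, group_by: tuple[str, ...] = ("condition", "sound_type")) -> dict:
    """Per-cell mean +/- SEM over epochs; empty cells are absent (logged)."""
    cells = {}
    meta = epochs.metadata
    observed = meta.groupby(list(group_by), dropna=False).indices
    for key, idx in observed.items():
        key = key if isinstance(key, tuple) else (key,)
        sub = epochs.data[idx]
        n = sub.shape[0]
        sem = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(sub[0])
        cells[key] = ERP(mean=sub.mean(axis=0), sem=sem, n=n)
    if not cells:
        logger.warning("no epochs in any requested cell")
    return cells


@dataclass
class TFR:
    """Time-frequency power: (epochs x) channels x frequencies x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    baseline_mode: str = "raw"
    edge_mask: np.ndarray = field(default=None)   # freqs x times, True where wavelet support incomplete

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.baseline_mode == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")

    @property
    def per_epoch(self) -> bool:
        return self.power.ndim == 4

    def average(self) -> "TFR":
        if not self.per_epoch:
            return self
        return replace(self, power=self.power.mean(axis=0))


def morlet_tfr(epochs: EpochSet, freqs: np.ndarray | None = None,
               tmin: float = -1.0, tmax: float = 2.4, tstep: float = 0.05,
               min_cycles: float = 4.0) -> TFR:
    """Morlet-wavelet power per epoch, channel, frequency and time bin.

    Wavelet width is at least ``min_cycles`` cycles, growing with frequency
    (``max(min_cycles, f/2)`` cycles) so temporal smoothing stays bounded.
    Bins whose wavelet half-width extends beyond the epoch are flagged in
    ``edge_mask``, not removed.
    """
    from mne.time_frequency import tfr_array_morlet

    fs = epochs.sampling_rate
    if freqs is None:
        freqs = np.arange(4.0, 20.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() > fs / 2:
        raise ValueError(f"requested frequency {freqs.max()} Hz above Nyquist ({fs/2} Hz)")
    n_cycles = np.maximum(min_cycles, freqs / 2.0)
    half_width = n_cycles / (2.0 * freqs)
    if epochs.times[0] > tmin or epochs.times[-1] < tmax:
        raise ValueError("epoch window does not cover the requested TFR times")

    decim = max(int(round(tstep * fs)), 1)
    power = tfr_array_morlet(epochs.data, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
                             output="power", decim=decim, zero_mean=True)
    times = epochs.times[::decim]
    keep = (times >= tmin - 1e-9) & (times <= tmax + 1e-9)
    power = power[..., keep]
    times = times[keep]
    edge = ((times[None, :] - epochs.times[0] < half_width[:, None])
            | (epochs.times[-1] - times[None, :] < half_width[:, None]))
    return TFR(power=power, freqs=freqs, times=times,
               channel_labels=epochs.channel_labels, edge_mask=edge)


def baseline_normalize(tfr: TFR, baseline: tuple[float, float] = (-1.0, 0.0)) -> TFR:
    """Relative change from the pre-cue baseline: (P - mean_bl) / mean_bl,
    per channel and frequency (and epoch when present)."""
    if tfr.baseline_mode != "raw":
        raise ValueError("TFR is already baseline-normalised")
    mask = (tfr.times >= baseline[0] - 1e-9) & (tfr.times <= baseline[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window {baseline} outside TFR times")
    # per-frequency baseline over bins with full wavelet support (edge bins
    # under-estimate power and would bias the whole map upward)
    if tfr.edge_mask is not None:
        valid = mask[None, :] & ~tfr.edge_mask           # freqs x times
        empty = ~valid.any(axis=1)
        valid[empty] = mask[None, :]
        w = valid / valid.sum(axis=1, keepdims=True)
        bl = np.einsum("...ft,ft->...f", tfr.power, w)[..., None]
    else:
        bl = tfr.power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(bl <= 0):
        raise ValueError("baseline power is zero in some bins; cannot normalise")
    return replace(tfr, power=(tfr.power - bl) / bl, baseline_mode="relative_change")
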