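"""Scalp channel layout helpers.

A fixed 60-channel 10-20/10-10 label set is used throughout: the simulator
mixes its sources onto it, the detector picks F3 from it, and the cluster
statistics derive channel adjacency from its electrode positions.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Default 60-channel scalp layout (no mastoids/EOG/EMG).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

MASTOID_LABELS = ("M1", "M2", "A1", "A2", "TP9", "TP10")


@lru_cache(maxsize=4)
def channel_positions(channels: tuple[str, ...] = DEFAULT_CHANNELS) -> np.ndarray:
    """3-D electrode positions (metres) for ``channels``, from the standard
    10-20 extended montage.  Shape ``(n_channels, 3)``."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channels if ch not in pos]
    if missing:
        raise KeyError(f"channels without montage coordinates: {missing}")
    return np.array([pos[ch] for ch in channels])


def frontal_weights(channels: tuple[str, ...] = DEFAULT_CHANNELS, sigma: float = 0.07) -> np.ndarray:
    """Frontal-maximal mixing vector for a single midline-frontal source.

    Gaussian fall-off (length scale ``sigma`` metres) from the F3/Fz/F4
    centroid, normalised so that F3 — the online detection channel — has
    weight exactly 1.
    """
    pos = channel_positions(channels)
    idx = {ch: i for i, ch in enumerate(channels)}
    for required in ("F3", "Fz", "F4"):
        if required not in idx:
            raise KeyError(f"frontal weighting requires channel {required}")
    centre = pos[[idx["F3"], idx["Fz"], idx["F4"]]].mean(axis=0)
    d2 = ((pos - centre) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * sigma**2))
    return w / w[idx["F3"]]
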