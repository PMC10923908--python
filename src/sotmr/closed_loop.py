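"""Replay simulation of the online slow-oscillation phase-targeted cueing system.

The engine processes the detection channel strictly causally: a causal
band-pass (0.5-4 Hz) of the F3 signal is tracked until it crosses the -80 µV
threshold, the negative half-wave peak (trough) is confirmed once the
filtered derivative has been positive for a short confirmation window, and
the cue is scheduled a fixed 500 ms after the trough — which lands it on the
SO positive peak (up-phase).  Down-phase targeting runs the identical
detector on the polarity-inverted signal, so its cues land on the trough.
Cues are gated by sleep stage (N3 only), arousal intervals, and a minimum
inter-trial pause measured from sound offset to next onset.

Because any causal filter distorts timing inside the SO band (a steady 1 Hz
oscillation is detected ~44 ms early, an isolated SO transient ~10 ms late),
the trough time is refined as the minimum of the *raw* detection channel in
a short window around the filtered minimum — the same filtered-detect /
raw-refine scheme real closed-loop rigs use.  The refinement lookahead is
well below the 500 ms cue delay, so the engine stays causal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import SleepRecording

ITEMS = ("A", "B", "C", "D", "E", "F")
SET_TYPES = (("Up", "Experimental"), ("Up", "Novel"), ("Down", "Experimental"), ("Down", "Novel"))


@dataclass
class DetectorConfig:
    """Online SO-trough detector parameters.

    ``threshold`` is applied to the causally band-passed detection channel
    (after polarity inversion for Down targeting); ``delay_ms`` runs from the
    detected trough to cue onset; ``min_iti`` is the pause between sounds,
    measured offset-to-onset when ``iti_mode='offset'`` (so consecutive
    onsets are at least ``min_iti`` + sound duration apart) or
    onset-to-onset when ``iti_mode='onset'``.
    """

    detection_channel: str = "F3"
    band_low: float = 0.5
    band_high: float = 4.0
    threshold: float = -80.0
    delay_ms: float = 500.0
    min_iti: float = 4.0
    polarity: int = +1                      # +1 detects troughs (Up), -1 peaks (Down)
    allowed_stages: tuple[str, ...] = ("N3",)
    confirm_window_ms: float = 20.0
    iti_mode: str = "offset"                # "offset" or "onset"
    filter_order: int = 2                   # transfer-function order of the causal IIR
    refine_window_ms: float = 100.0         # raw-signal trough refinement half-window (0 = off)

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError("threshold must be negative (µV)")
        if self.delay_ms <= 0 or self.min_iti <= 0:
            raise ValueError("delay_ms and min_iti must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.iti_mode not in ("offset", "onset"):
            raise ValueError("iti_mode must be 'offset' or 'onset'")

    def sos(self, fs: float):
        if self.band_high >= fs / 2:
            raise ValueError(f"band_high={self.band_high} Hz not below Nyquist ({fs/2} Hz)")
        return sps.butter(self.filter_order // 2, [self.band_low, self.band_high],
                          btype="bandpass", fs=fs, output="sos")



@dataclass(frozen=True)
class SoundSet:
    condition: str        # Up / Down
    sound_type: str       # Experimental / Novel
    items: tuple[str, ...] = ITEMS


@dataclass
class TMRSchedule:
    """Night plan: blocks of the four sound sets, each set = items A..F in order."""

    blocks: list[list[SoundSet]]
    sound_duration: float = 0.2

    def __post_init__(self) -> None:
        for b, block in enumerate(self.blocks):
            kinds = {(s.condition, s.sound_type) for s in block}
            if len(block) != 4 or kinds != set(SET_TYPES):
                raise ValueError(f"block {b} must contain each of the 4 sound sets exactly once")
            for s in block:
                if tuple(s.items) != ITEMS:
                    raise ValueError("within-set order must be A..F")

    @property
    def n_planned(self) -> int:
        return sum(len(s.items) for block in self.blocks for s in block)

    def flatten(self) -> list[tuple[int, SoundSet, str]]:
        return [(b, s, item) for b, block in enumerate(self.blocks) for s in block for item in s.items]


@dataclass(frozen=True)
class CueEvent:
    onset: float
    condition: str
    sound_type: str
    item: str
    block: int
    detected_trough_time: float


@dataclass
class ClosedLoopResult:
    events: list[CueEvent]
    pending: list[tuple[int, SoundSet, str]] = field(default_factory=list)


def make_tmr_schedule(n_blocks: int, rng: np.random.Generator | int = 0) -> TMRSchedule:
    """Randomised, counterbalanced block schedule of the four sound sets.

    Set order within a block is drawn without replacement from the 24
    possible orders, reshuffled whenever exhausted, so orders are balanced
    across blocks.  Planned cue count = n_blocks x 4 sets x 6 items.
    """
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    all_orders = list(itertools.permutations(range(4)))
    pool: list[tuple[int, ...]] = []
    blocks = []
    for _ in range(n_blocks):
        if not pool:
            pool = [all_orders[i] for i in rng.permutation(len(all_orders))]
        order = pool.pop()
        blocks.append([SoundSet(*SET_TYPES[i]) for i in order])
    return TMRSchedule(blocks=blocks)


def detect_so_troughs(recording: SleepRecording, config: DetectorConfig | None = None) -> np.ndarray:
    """All confirmed SO trough times (seconds) with the online detector, ungated.

    Runs the same causal threshold-track-confirm-refine machine as
    :func:`run_closed_loop` at a fixed polarity (``config.polarity``; -1
    detects positive peaks), without schedule, stage or ITI gating.
    """
    cfg = config or DetectorConfig()
    fs = recording.sampling_rate
    x = recording.channel(cfg.detection_channel)
    s = cfg.polarity * sps.sosfilt(cfg.sos(fs), x)
    xs = cfg.polarity * x
    refine_n = int(round(cfg.refine_window_ms / 1000.0 * fs))
    confirm_n = max(int(round(cfg.confirm_window_ms / 1000.0 * fs)), 1)
    n = s.size
    troughs = []
    tracking = False
    refractory = False
    min_idx = 0
    rise_count = 0
    for i in range(1, n):
        if refractory:
            # hysteresis: re-arm only once the signal has recovered above threshold
            if s[i] >= cfg.threshold:
                refractory = False
        elif not tracking:
            if s[i] < cfg.threshold:
                tracking, min_idx, rise_count = True, i, 0
        else:
            if s[i] < s[min_idx]:
                min_idx, rise_count = i, 0
            elif s[i] > s[i - 1]:
                rise_count += 1
                if rise_count >= confirm_n:
                    idx = min_idx
                    if refine_n > 0:
                        a = max(min_idx - refine_n, 0)
                        b = min(min_idx + refine_n + 1, n)
                        idx = a + int(np.argmin(xs[a:b]))
                    troughs.append(idx / fs)
                    tracking, rise_count = False, 0
                    refractory = True
            else:
                rise_count = 0
    return np.asarray(troughs)


def run_closed_loop(recording: SleepRecording, schedule: TMRSchedule,
                    config: DetectorConfig | dict[str, DetectorConfig] | None = None) -> ClosedLoopResult:
    """Replay the night: detect SO troughs causally and deliver scheduled cues.

    The polarity used by the detector at any moment follows the condition of
    the next pending sound (Up: trough of the signal; Down: trough of the
    inverted signal, i.e. the positive peak).  A confirmed trough triggers a
    cue at trough + delay iff the stage gate is open at cue time, the sound
    would not overlap an arousal, and the inter-trial pause is respected;
    otherwise the trough is skipped.  Sounds are delivered strictly in
    schedule order; the undelivered tail is returned as ``pending``.
    """
    if config is None:
        config = DetectorConfig()
    configs = config if isinstance(config, dict) else {"Up": config, "Down": config}
    base = configs["Up"]
    fs = recording.sampling_rate
    x = recording.channel(base.detection_channel)
    filt = sps.sosfilt(base.sos(fs), x)
    refine_n = int(round(base.refine_window_ms / 1000.0 * fs))
    confirm_n = max(int(round(base.confirm_window_ms / 1000.0 * fs)), 1)
    delay = base.delay_ms / 1000.0
    duration = recording.duration

    pending = schedule.flatten()
    events: list[CueEvent] = []
    last_onset = -np.inf

    def gate_open(onset: float, cfg: DetectorConfig) -> bool:
        sound_end = onset + schedule.sound_duration
        if sound_end > duration:
            return False
        if recording.stage_at(onset) not in cfg.allowed_stages:
            return False
        if recording.in_arousal(onset) or recording.in_arousal(sound_end):
            return False
        ref = last_onset + (schedule.sound_duration if cfg.iti_mode == "offset" else 0.0)
        return onset - ref >= cfg.min_iti

    i = 1
    n = filt.size
    tracking = False
    refractory = False
    min_idx = 0
    rise_count = 0
    current_polarity = 0

    while i < n and pending:
        cond = pending[0][1].condition
        cfg = configs[cond]
        pol = cfg.polarity if cond == "Up" else -abs(cfg.polarity)
        if pol != current_polarity:
            # polarity switched between sets: restart the state machine
            tracking = False
            refractory = False
            rise_count = 0
            current_polarity = pol
        s_i = pol * filt[i]
        s_prev = pol * filt[i - 1]
        if refractory:
            if s_i >= cfg.threshold:
                refractory = False
        elif not tracking:
            if s_i < cfg.threshold:
                tracking = True
                min_idx = i
                rise_count = 0
        else:
            if s_i < pol * filt[min_idx]:
                min_idx = i
                rise_count = 0
            elif s_i > s_prev:
                rise_count += 1
                if rise_count >= confirm_n:
                    trough_idx = min_idx
                    if refine_n > 0:
                        a = max(min_idx - refine_n, 0)
                        b = min(min_idx + refine_n + 1, n)
                        trough_idx = a + int(np.argmin(pol * x[a:b]))
                    trough_t = trough_idx / fs
                    onset = trough_t + delay
                    if onset <= duration and gate_open(onset, cfg):
                        block, sset, item = pending.pop(0)
                        events.append(CueEvent(onset=onset, condition=sset.condition,
                                               sound_type=sset.sound_type, item=item,
                                               block=block, detected_trough_time=trough_t))
                        last_onset = onset
                    tracking = False
                    rise_count = 0
                    refractory = True
            else:
                rise_count = 0
        i += 1

    return ClosedLoopResult(events=events, pending=pending)


def summarize_delivery(events: list[CueEvent]) -> dict:
    """Delivery bookkeeping: cue counts per condition x sound type, ITI stats."""
    counts = {st: 0 for st in SET_TYPES}
    for ev in events:
        counts[(ev.condition, ev.sound_type)] += 1
    onsets = np.array([ev.onset for ev in events])
    gaps = np.diff(onsets) if onsets.size > 1 else np.empty(0)
    return {
        "counts": counts,
        "n_delivered": len(events),
        "min_onset_gap": float(gaps.min()) if gaps.size else None,
        "mean_onset_gap": float(gaps.mean()) if gaps.size else None,
    }
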