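"""Synthetic slow-wave-sleep EEG and behavioural data with known ground truth.

The generator produces the signal class the whole pipeline assumes: N3 sleep
containing high-amplitude slow oscillations (SOs, 0.5-1.5 Hz, frontally
dominant), spindle bursts (9-16 Hz) coupled to the SO up-phase, 1/f
background noise, a hypnogram, and arousal intervals.  Every planted event is
reported back as ground truth so that detector, phase, ERP/TFR, cluster and
decoding stages can all be tested against exact oracles.

SO waveform: one period of a raised-cosine biphasic template — a negative
(trough) half-wave followed by a positive (peak) half-wave — so trough and
peak times are analytically known.  Channel topography is a fixed
frontal-maximal mixing vector applied to a single source; no forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .montage import DEFAULT_CHANNELS, frontal_weights

STAGES = ("W", "N1", "N2", "N3", "REM")

_CORE_CHANNELS = ("F3", "Fz", "F4", "Cz")


def select_channels(n_channels: int) -> tuple[str, ...]:
    """First ``n_channels`` scalp labels, always retaining F3/Fz/F4/Cz.

    The online detector reads F3 and the frontal mixing vector is anchored
    at F3/Fz/F4, so reduced-channel simulations keep those labels first.
    """
    if n_channels < len(_CORE_CHANNELS):
        raise ValueError(f"n_channels must be >= {len(_CORE_CHANNELS)} (core: {_CORE_CHANNELS})")
    rest = [c for c in DEFAULT_CHANNELS if c not in _CORE_CHANNELS]
    chosen = set(_CORE_CHANNELS) | set(rest[: n_channels - len(_CORE_CHANNELS)])
    return tuple(c for c in DEFAULT_CHANNELS if c in chosen)


# ---------------------------------------------------------------------------
# configuration / containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the sleep-EEG simulator.

    Amplitudes are µV, durations seconds, rates events/minute (SOs) or
    events/hour (arousals).  ``stage_plan`` is a list of ``(stage, seconds)``
    segments; ``None`` means one all-N3 segment of ``duration``.
    """

    sampling_rate: float = 500.0
    n_channels: int = 60
    duration: float = 300.0
    so_rate: float = 8.0              # SO events per minute of N3
    so_freq_low: float = 0.5
    so_freq_high: float = 1.5
    so_trough_amp_mean: float = -130.0
    so_trough_amp_sd: float = 20.0
    so_peak_ratio: float = 0.65       # positive peak amplitude / |trough|
    so_updown_asymmetry: float = 1.0  # peak half-wave duration / trough half-wave duration
    spindle_freq_low: float = 9.0
    spindle_freq_high: float = 16.0
    spindle_prob_per_so: float = 0.5
    spindle_amp: float = 20.0
    spindle_duration: float = 0.8
    noise_exponent: float = 1.0       # 1/f^exponent power slope
    noise_scale: float = 15.0         # background RMS, µV
    stage_plan: list[tuple[str, float]] | None = None
    arousal_rate: float = 2.0         # per hour
    arousal_duration: float = 5.0
    seed: int = 0

    def resolved_stage_plan(self) -> list[tuple[str, float]]:
        return list(self.stage_plan) if self.stage_plan is not None else [("N3", self.duration)]

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.so_freq_low < self.so_freq_high:
            raise ValueError("so_freq_low must be below so_freq_high")
        if not 4 <= self.n_channels <= len(DEFAULT_CHANNELS):
            raise ValueError(f"n_channels must be in 4..{len(DEFAULT_CHANNELS)}")
        plan = self.resolved_stage_plan()
        for stage, dur in plan:
            if stage not in STAGES:
                raise ValueError(f"unknown sleep stage {stage!r}")
            if dur < 0:
                raise ValueError("stage durations must be non-negative")
        total = sum(d for _, d in plan)
        if not math.isclose(total, self.duration, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"stage_plan durations sum to {total}, expected duration={self.duration}")
        if self.so_rate > 0:
            if not any(s == "N3" and d > 0 for s, d in plan):
                raise ValueError("so_rate > 0 requires at least one N3 segment in stage_plan")
            if self.so_trough_amp_mean > -75.0:
                raise ValueError(
                    "so_trough_amp_mean must be below -75 µV so the -80 µV online threshold is reachable"
                )


@dataclass
class SleepRecording:
    """Continuous multichannel EEG (µV) with hypnogram and arousal intervals."""

    data: np.ndarray                      # (n_channels, n_samples)
    channel_labels: tuple[str, ...]
    sampling_rate: float
    hypnogram: tuple[str, ...]            # stage per 30-s epoch
    arousals: tuple[tuple[float, float], ...] = ()

    EPOCH_LEN = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples) matching channel_labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        n_epochs = math.ceil(self.duration / self.EPOCH_LEN)
        if len(self.hypnogram) != n_epochs:
            raise ValueError(f"hypnogram has {len(self.hypnogram)} epochs, expected {n_epochs}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def stage_at(self, t: float) -> str:
        i = int(t // self.EPOCH_LEN)
        if not 0 <= i < len(self.hypnogram):
            raise IndexError(f"time {t} s outside recording")
        return self.hypnogram[i]

    def in_arousal(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.arousals)

    def copy(self) -> "SleepRecording":
        return SleepRecording(self.data.copy(), tuple(self.channel_labels),
                              self.sampling_rate, tuple(self.hypnogram), tuple(self.arousals))


@dataclass
class GroundTruth:
    """Exact event times planted by the generator (oracle for downstream tests)."""

    so_trough_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    so_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spindle_intervals: tuple[tuple[float, float], ...] = ()
    planted_effect_windows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.so_trough_times = np.asarray(self.so_trough_times, dtype=float)
        self.so_peak_times = np.asarray(self.so_peak_times, dtype=float)
        for name, t in (("trough", self.so_trough_times), ("peak", self.so_peak_times)):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"SO {name} times must be strictly increasing")


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      exponent: float, rms: float, fs: float) -> np.ndarray:
    """Independent 1/f^exponent noise per channel, scaled to a target RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f[0] = f[1] if n_samples > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def _raised_cosine_half(n: int) -> np.ndarray:
    """Half-wave 0 -> 1 -> 0 with zero-derivative endpoints (n samples)."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _n3_intervals(plan: list[tuple[str, float]]) -> list[tuple[float, float]]:
    out, t = [], 0.0
    for stage, dur in plan:
        if stage == "N3" and dur > 0:
            out.append((t, t + dur))
        t += dur
    return out


def _hypnogram_from_plan(plan: list[tuple[str, float]], duration: float) -> tuple[str, ...]:
    n_epochs = math.ceil(duration / SleepRecording.EPOCH_LEN)
    edges, t = [], 0.0
    for stage, dur in plan:
        edges.append((t, t + dur, stage))
        t += dur
    stages = []
    for i in range(n_epochs):
        mid = min((i + 0.5) * SleepRecording.EPOCH_LEN, duration - 1e-9)
        stage = next(s for a, b, s in edges if a <= mid < b or (b == t and mid >= a))
        stages.append(stage)
    return tuple(stages)


def generate_sleep_eeg(config: SimConfig) -> tuple[SleepRecording, GroundTruth]:
    """Simulate an N3-rich sleep recording plus exact ground-truth annotations.

    SOs are placed only inside N3 segments of the stage plan, as a renewal
    process whose mean spacing matches ``so_rate`` (hard-core gap of one SO
    duration so templates never overlap).  Each SO is a biphasic
    raised-cosine wave at a frequency drawn uniformly from the configured SO
    band; spindle bursts are Gaussian-windowed sinusoids centred on the SO
    positive peak with probability ``spindle_prob_per_so``.  Identical seeds
    reproduce the output bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    channels = select_channels(config.n_channels)

    data = _one_over_f_noise(rng, len(channels), n_samples,
                             config.noise_exponent, config.noise_scale, fs)
    weights = frontal_weights(channels)

    trough_times: list[float] = []
    peak_times: list[float] = []
    spindles: list[tuple[float, float]] = []

    if config.so_rate > 0:
        mean_spacing = 60.0 / config.so_rate
        max_so_dur = (1.0 + config.so_updown_asymmetry) / (2.0 * config.so_freq_low)
        min_gap = max_so_dur + 0.2
        if mean_spacing <= min_gap:
            raise ValueError(
                f"so_rate={config.so_rate}/min too dense for SOs of up to {max_so_dur:.2f} s"
            )
        for seg_start, seg_end in _n3_intervals(config.resolved_stage_plan()):
            t = seg_start + rng.uniform(0.0, mean_spacing)
            while True:
                f_so = rng.uniform(config.so_freq_low, config.so_freq_high)
                d_down = 0.5 / f_so
                d_up = config.so_updown_asymmetry * d_down
                if t + d_down + d_up > seg_end:
                    break
                amp = -rng.normal(abs(config.so_trough_amp_mean), config.so_trough_amp_sd)
                amp = min(amp, -10.0)
                i0 = int(round(t * fs))
                n_down = max(int(round(d_down * fs)), 3)
                n_up = max(int(round(d_up * fs)), 3)
                wave = np.concatenate([
                    amp * _raised_cosine_half(n_down),
                    -amp * config.so_peak_ratio * _raised_cosine_half(n_up),
                ])
                wave = wave[: n_samples - i0]
                data[:, i0:i0 + wave.size] += weights[:, None] * wave[None, :]
                t_trough = (i0 + (n_down - 1) / 2.0) / fs
                t_peak = (i0 + n_down + (n_up - 1) / 2.0) / fs
                trough_times.append(t_trough)
                peak_times.append(t_peak)

                if rng.uniform() < config.spindle_prob_per_so:
                    f_sp = rng.uniform(config.spindle_freq_low, config.spindle_freq_high)
                    half = config.spindle_duration / 2.0
                    s0 = max(int(round((t_peak - half) * fs)), 0)
                    s1 = min(int(round((t_peak + half) * fs)), n_samples)
                    if s1 > s0:
                        tt = np.arange(s0, s1) / fs
                        env = np.exp(-0.5 * ((tt - t_peak) / (config.spindle_duration / 6.0)) ** 2)
                        burst = config.spindle_amp * env * np.sin(2 * np.pi * f_sp * (tt - t_peak))
                        data[:, s0:s1] += weights[:, None] * burst[None, :]
                        spindles.append((s0 / fs, s1 / fs))

                t += min_gap + rng.exponential(mean_spacing - min_gap)

    arousals: list[tuple[float, float]] = []
    n_arousals = rng.poisson(config.arousal_rate * config.duration / 3600.0)
    for start in np.sort(rng.uniform(0.0, config.duration, size=n_arousals)):
        arousals.append((float(start), float(min(start + config.arousal_duration, config.duration))))

    recording = SleepRecording(
        data=data,
        channel_labels=channels,
        sampling_rate=fs,
        hypnogram=_hypnogram_from_plan(config.resolved_stage_plan(), config.duration),
        arousals=tuple(arousals),
    )
    truth = GroundTruth(
        so_trough_times=np.array(trough_times),
        so_peak_times=np.array(peak_times),
        spindle_intervals=tuple(spindles),
    )
    return recording, truth


def periodic_so_recording(duration: float, period: float = 1.5, so_freq: float = 1.0,
                          trough_amp: float = -130.0, peak_ratio: float = 0.65,
                          n_channels: int = 4, sampling_rate: float = 500.0,
                          noise_scale: float = 2.0,
                          seed: int = 0) -> tuple[SleepRecording, GroundTruth]:
    """Deterministic all-N3 SO train: one biphasic SO every ``period`` seconds.

    Convenience oracle for detector tests — trough/peak times are exact and
    the spacing is regular, unlike the stochastic :func:`generate_sleep_eeg`.
    """
    if period < 1.0 / so_freq:
        raise ValueError("period shorter than one SO cycle")
    fs = sampling_rate
    n_samples = int(round(duration * fs))
    channels = select_channels(n_channels)
    rng = np.random.default_rng(seed)
    data = _one_over_f_noise(rng, len(channels), n_samples, 1.0, noise_scale, fs)
    weights = frontal_weights(channels)

    d_half = 0.5 / so_freq
    n_half = int(round(d_half * fs))
    wave = np.concatenate([
        trough_amp * _raised_cosine_half(n_half),
        -trough_amp * peak_ratio * _raised_cosine_half(n_half),
    ])
    troughs, peaks = [], []
    t = 0.25 * period
    while t + 2 * d_half < duration:
        i0 = int(round(t * fs))
        seg = wave[: n_samples - i0]
        data[:, i0:i0 + seg.size] += weights[:, None] * seg[None, :]
        troughs.append((i0 + (n_half - 1) / 2.0) / fs)
        peaks.append((i0 + n_half + (n_half - 1) / 2.0) / fs)
        t += period

    n_epochs = math.ceil(duration / SleepRecording.EPOCH_LEN)
    rec = SleepRecording(data, channels, fs, tuple(["N3"] * n_epochs))
    return rec, GroundTruth(np.array(troughs), np.array(peaks))


def sinusoid_recording(duration: float, freq: float = 1.0, amplitude: float = 100.0,
                       n_channels: int = 4, sampling_rate: float = 500.0) -> SleepRecording:
    """Pure cosine on every channel (closed-form oracle for detector/phase tests).

    ``x(t) = -A cos(2π f t)`` so troughs sit at integer multiples of the period.
    """
    fs = sampling_rate
    t = np.arange(int(round(duration * fs))) / fs
    x = -amplitude * np.cos(2 * np.pi * freq * t)
    channels = select_channels(n_channels)
    data = np.tile(x, (len(channels), 1))
    n_epochs = math.ceil(duration / SleepRecording.EPOCH_LEN)
    return SleepRecording(data, channels, fs, tuple(["N3"] * n_epochs))


# ---------------------------------------------------------------------------
# condition effects
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Additive cue-locked effect distinguishing Experimental from Novel cues.

    ``amplitude`` µV of a Hann-windowed multivariate deflection added in
    ``window`` (seconds relative to cue onset) to every matching event;
    ``theta_amp`` / ``sigma_amp`` add oscillatory bursts (6 / 13 Hz) over the
    same window for time-frequency effects.  ``topography`` is a per-channel
    weight vector, or "frontal" for the standard frontal-maximal map.
    """

    amplitude: float = 0.0
    window: tuple[float, float] = (1.2, 1.3)
    topography: object = "frontal"
    sound_type: str = "Experimental"
    condition: str | None = None
    theta_amp: float = 0.0
    theta_freq: float = 6.0
    sigma_amp: float = 0.0
    sigma_freq: float = 13.0


def inject_condition_effects(recording: SleepRecording, events,
                             effect_spec: EffectSpec | list[EffectSpec]) -> SleepRecording:
    """Add condition-specific evoked/oscillatory structure at cue events.

    Purely additive, so the generator's ground truth remains recoverable.
    Returns a new recording; the input is untouched.
    """
    specs = effect_spec if isinstance(effect_spec, list) else [effect_spec]
    out = recording.copy()
    fs = recording.sampling_rate
    n = recording.n_samples

    for spec in specs:
        w0, w1 = spec.window
        if not w1 > w0:
            raise ValueError("effect window must have positive length")
        if isinstance(spec.topography, str):
            if spec.topography != "frontal":
                raise ValueError(f"unknown topography {spec.topography!r}")
            topo = frontal_weights(tuple(recording.channel_labels))
        else:
            topo = np.asarray(spec.topography, dtype=float)
            if topo.shape != (len(recording.channel_labels),):
                raise ValueError("topography length must match channel count")

        n_win = int(round((w1 - w0) * fs))
        hann = np.hanning(n_win)
        tt = np.arange(n_win) / fs
        burst = (spec.theta_amp * np.sin(2 * np.pi * spec.theta_freq * tt)
                 + spec.sigma_amp * np.sin(2 * np.pi * spec.sigma_freq * tt)) * hann
        deflection = spec.amplitude * hann + burst

        for k, ev in enumerate(events):
            onset = getattr(ev, "onset", ev)
            if not 0 <= onset <= recording.duration:
                raise ValueError(f"event {k} at {onset} s lies outside the recording")
            if getattr(ev, "sound_type", spec.sound_type) != spec.sound_type:
                continue
            if spec.condition is not None and getattr(ev, "condition", None) != spec.condition:
                continue
            i0 = int(round((onset + w0) * fs))
            if i0 < 0 or i0 + n_win > n:
                raise ValueError(f"effect window for event {k} exceeds the recording")
            out.data[:, i0:i0 + n_win] += topo[:, None] * deflection[None, :]
    return out


# ---------------------------------------------------------------------------
# behavioural generator
# ---------------------------------------------------------------------------

CONDITIONS = ("Up", "Down", "Control")
SESSIONS = (1, 2, 3)
PAIR_CLASSES = ("premise", "deg1", "deg2", "anchor")


def default_true_accuracy() -> dict[tuple[str, int, str], float]:
    """Per-cell response probabilities emulating the study design.

    Premise accuracy in session 1 uses the reported immediate-test means
    (Down 0.747, Control 0.792, Up 0.796); session 2 keeps premise knowledge
    flat overnight and session 3 shows the two-week decline.  Inference pairs
    exist only from session 2: the Up condition is boosted most at the
    2nd-degree pair, the Down condition sits below chance at session 2
    (0.464) recovering by session 3 (0.586), and anchor pairs are easy in
    every condition.
    """
    acc: dict[tuple[str, int, str], float] = {}
    premise = {
        ("Down", 1): 0.747, ("Control", 1): 0.792, ("Up", 1): 0.796,
        ("Down", 2): 0.75, ("Control", 2): 0.79, ("Up", 2): 0.80,
        ("Down", 3): 0.65, ("Control", 3): 0.68, ("Up", 3): 0.68,
    }
    for (cond, sess), p in premise.items():
        acc[(cond, sess, "premise")] = p
    inference = {
        ("Up", 2, "deg1"): 0.68, ("Up", 2, "deg2"): 0.72,
        ("Control", 2, "deg1"): 0.62, ("Control", 2, "deg2"): 0.55,
        ("Down", 2, "deg1"): 0.50, ("Down", 2, "deg2"): 0.464,
        ("Up", 3, "deg1"): 0.66, ("Up", 3, "deg2"): 0.66,
        ("Control", 3, "deg1"): 0.62, ("Control", 3, "deg2"): 0.60,
        ("Down", 3, "deg1"): 0.59, ("Down", 3, "deg2"): 0.586,
    }
    acc.update(inference)
    for cond in CONDITIONS:
        for sess in (2, 3):
            acc[(cond, sess, "anchor")] = 0.90
    return acc


@dataclass
class BehaviourSimConfig:
    """Behavioural simulator: Bernoulli responses with subject random effects.

    ``true_accuracy`` maps ``(condition, session, pair_class)`` to the
    population response probability; each subject adds a Normal(0,
    ``subject_effect_sd``) shift on the logit scale shared across cells.
    """

    n_subjects: int = 20
    true_accuracy: dict[tuple[str, int, str], float] = field(default_factory=default_true_accuracy)
    subject_effect_sd: float = 0.3
    trials_per_cell: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if not self.true_accuracy:
            raise ValueError("true_accuracy map is empty")
        for key, p in self.true_accuracy.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability for cell {key} must lie in (0, 1)")


def generate_behaviour(config: BehaviourSimConfig) -> pd.DataFrame:
    """Simulate the behavioural table: one row per trial, ``correct`` in {0,1}.

    Columns: subject, condition, session, pair_class, trial, correct.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = sorted(config.true_accuracy.items())
    rows = []
    for subj in range(config.n_subjects):
        u = rng.normal(0.0, config.subject_effect_sd)
        for (cond, sess, pclass), p in cells:
            p_subj = expit(logit(p) + u)
            correct = rng.uniform(size=config.trials_per_cell) < p_subj
            for t, c in enumerate(correct):
                rows.append((subj, cond, sess, pclass, t, int(c)))
    return pd.DataFrame(rows, columns=["subject", "condition", "session", "pair_class", "trial", "correct"])
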