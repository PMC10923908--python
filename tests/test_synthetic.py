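"""Generator tests: event placement, amplitudes, determinism, behaviour model."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from sotmr import synthetic as syn
from sotmr.closed_loop import CueEvent


def make_events(onsets, sound_type="Experimental", condition="Up"):
    return [CueEvent(onset=t, condition=condition, sound_type=sound_type, item="A",
                     block=0, detected_trough_time=0.0) for t in onsets]


class TestGenerateSleepEEG:
    def test_no_events_when_rate_zero(self):
        rec, truth = syn.generate_sleep_eeg(syn.SimConfig(duration=60, n_channels=4,
                                                          so_rate=0, seed=0))
        assert truth.so_trough_times.size == 0
        assert truth.so_peak_times.size == 0
        # noise only: RMS close to the configured background scale
        assert rec.data.std() == pytest.approx(15.0, rel=0.15)

    def test_so_count_matches_rate(self):
        config = syn.SimConfig(duration=600, n_channels=4, so_rate=8, seed=4)
        _, truth = syn.generate_sleep_eeg(config)
        expected = 8 * 10
        assert abs(truth.so_trough_times.size - expected) <= 3 * np.sqrt(expected)

    def test_planted_troughs_cross_detector_threshold(self):
        """Offline filter-and-check oracle: the slow-wave-band F3 trace dips
        below -80 µV around the planted troughs."""
        config = syn.SimConfig(duration=300, n_channels=4, so_rate=6,
                               so_trough_amp_mean=-130, seed=1)
        rec, truth = syn.generate_sleep_eeg(config)
        sos = sps.butter(2, [0.5, 4], btype="bandpass", fs=rec.sampling_rate, output="sos")
        f3 = sps.sosfiltfilt(sos, rec.channel("F3"))
        idx = (truth.so_trough_times * rec.sampling_rate).astype(int)
        local_min = np.array([f3[max(i - 100, 0):i + 100].min() for i in idx])
        assert (local_min < -80).mean() > 0.7
        assert local_min.min() < -80

    def test_determinism(self):
        config = syn.SimConfig(duration=90, n_channels=4, seed=7)
        rec1, t1 = syn.generate_sleep_eeg(config)
        rec2, t2 = syn.generate_sleep_eeg(config)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        np.testing.assert_array_equal(t1.so_trough_times, t2.so_trough_times)
        assert rec1.hypnogram == rec2.hypnogram
        assert rec1.arousals == rec2.arousals

    def test_so_placement_respects_hypnogram(self):
        plan = [("N2", 120.0), ("N3", 180.0), ("W", 60.0)]
        config = syn.SimConfig(duration=360, n_channels=4, stage_plan=plan, seed=2)
        rec, truth = syn.generate_sleep_eeg(config)
        assert truth.so_trough_times.size > 0
        assert np.all(truth.so_trough_times >= 120.0)
        assert np.all(truth.so_trough_times <= 300.0)
        assert rec.hypnogram[0] == "N2" and rec.hypnogram[-1] == "W"

    def test_spindles_overlap_so_up_phase(self):
        config = syn.SimConfig(duration=300, n_channels=4, spindle_prob_per_so=1.0, seed=3)
        _, truth = syn.generate_sleep_eeg(config)
        assert truth.spindle_intervals
        for start, end in truth.spindle_intervals:
            assert np.any((truth.so_peak_times >= start) & (truth.so_peak_times <= end))

    @pytest.mark.parametrize("bad_config", [
        dict(duration=0.0),
        dict(duration=-5.0),
        dict(stage_plan=[("N2", 60.0)], duration=60.0),            # no N3 but so_rate > 0
        dict(stage_plan=[("N3", 30.0)], duration=60.0),            # durations do not sum
        dict(so_trough_amp_mean=-50.0),                            # threshold unreachable
        dict(so_freq_low=2.0, so_freq_high=1.0),
    ])
    def test_invalid_configs_rejected(self, bad_config):
        with pytest.raises(ValueError):
            syn.generate_sleep_eeg(syn.SimConfig(n_channels=4, **bad_config))

    def test_trough_times_strictly_increasing(self, night):
        _, truth = night
        assert np.all(np.diff(truth.so_trough_times) > 0)
        assert np.all(np.diff(truth.so_peak_times) > 0)


class TestInjectConditionEffects:
    def test_zero_amplitude_is_identity(self):
        rec, _ = syn.generate_sleep_eeg(syn.SimConfig(duration=60, n_channels=4,
                                                      so_rate=0, seed=5))
        events = make_events([10.0, 20.0])
        out = syn.inject_condition_effects(rec, events, syn.EffectSpec(amplitude=0.0))
        np.testing.assert_array_equal(out.data, rec.data)

    def test_frontal_topography_maximal_at_frontal_channels(self):
        config = syn.SimConfig(duration=400, n_channels=20, so_rate=0, seed=6)
        rec, _ = syn.generate_sleep_eeg(config)
        exp = make_events(np.arange(5, 190, 5.0), "Experimental")
        nov = make_events(np.arange(192.5, 380, 5.0), "Novel")
        out = syn.inject_condition_effects(rec, exp + nov,
                                           syn.EffectSpec(amplitude=40.0, window=(1.2, 1.3)))
        fs = rec.sampling_rate
        win = slice(int(1.2 * fs), int(1.3 * fs))

        def erp(events):
            return np.mean([out.data[:, int(e.onset * fs) + win.start:
                                     int(e.onset * fs) + win.stop] for e in events], axis=0)

        diff = np.abs(erp(exp) - erp(nov)).mean(axis=1)
        frontal = [out.channel_labels.index(c) for c in ("F3", "Fz", "F4")]
        others = [i for i in range(len(out.channel_labels)) if i not in frontal]
        assert diff[frontal].min() > np.median(diff[others])

    def test_effect_is_additive_and_recoverable(self):
        rec, _ = syn.generate_sleep_eeg(syn.SimConfig(duration=60, n_channels=4,
                                                      so_rate=0, seed=7))
        events = make_events([10.0])
        out = syn.inject_condition_effects(rec, events,
                                           syn.EffectSpec(amplitude=25.0, window=(0.5, 0.7)))
        delta = out.data - rec.data
        fs = rec.sampling_rate
        assert np.abs(delta[:, : int(10.5 * fs)]).max() == 0
        assert np.abs(delta).max() > 0

    def test_event_outside_recording_names_index(self):
        rec, _ = syn.generate_sleep_eeg(syn.SimConfig(duration=30, n_channels=4,
                                                      so_rate=0, seed=8))
        events = make_events([5.0, 99.0])
        with pytest.raises(ValueError, match="event 1"):
            syn.inject_condition_effects(rec, events, syn.EffectSpec(amplitude=1.0))


class TestGenerateBehaviour:
    def test_chance_generator_stays_at_chance(self):
        acc = {("Up", 2, "deg2"): 0.5}
        config = syn.BehaviourSimConfig(n_subjects=50, true_accuracy=acc,
                                        subject_effect_sd=0.0, trials_per_cell=100, seed=0)
        table = syn.generate_behaviour(config)
        mean = table["correct"].mean()
        se = np.sqrt(0.25 / len(table))
        assert abs(mean - 0.5) < 3 * se

    def test_cell_difference_recovery(self):
        acc = {("Up", 2, "deg2"): 0.8, ("Control", 2, "deg2"): 0.55}
        config = syn.BehaviourSimConfig(n_subjects=40, true_accuracy=acc,
                                        subject_effect_sd=0.2, trials_per_cell=30, seed=1)
        table = syn.generate_behaviour(config)
        means = table.groupby("condition")["correct"].mean()
        assert means["Up"] - means["Control"] == pytest.approx(0.25, abs=0.05)

    def test_determinism(self):
        config = syn.BehaviourSimConfig(n_subjects=5, trials_per_cell=4, seed=9)
        pd.testing.assert_frame_equal(syn.generate_behaviour(config),
                                      syn.generate_behaviour(config))

    @pytest.mark.parametrize("kwargs", [
        dict(trials_per_cell=0),
        dict(true_accuracy={}),
        dict(true_accuracy={("Up", 2, "deg2"): 1.5}),
        dict(n_subjects=0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.generate_behaviour(syn.BehaviourSimConfig(**kwargs))
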