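"""EMG chain: filters, RMS, MVC reference, baseline threshold, detection."""

import numpy as np
import pytest

from solereflex import emg
from solereflex.emg import (
    BaselineStats,
    EmgRecording,
    MvcReference,
    ProcessingError,
    baseline_stats,
    cyclic_rms_ratio,
    detect_reflex,
    flag_noisy_trials,
    mvc_reference,
    preprocess,
    reflex_occurrence,
    rms,
    single_pulse_rms,
)
from solereflex.stimulus import StimulusEvent, cyclic_protocol
from conftest import rectified_recording

FS = 1200.0


def _raw(values):
    values = np.asarray(values, float)
    return EmgRecording(
        times=np.arange(len(values)) / FS,
        channels={"TA": values, "SOL": values.copy()},
        state="raw",
    )


class TestPreprocess:
    def test_mains_frequency_notched_out(self):
        t = np.arange(int(10 * FS)) / FS
        out = preprocess(_raw(np.sin(2 * np.pi * 50 * t)))
        attenuation = rms(out.channels["TA"][1200:-1200]) / rms(np.abs(np.sin(2 * np.pi * 50 * t)))
        assert attenuation < 0.1  # >= 20 dB

    def test_slow_drift_removed_by_band_pass(self):
        t = np.arange(int(10 * FS)) / FS
        out = preprocess(_raw(np.sin(2 * np.pi * 2 * t)))
        attenuation = rms(out.channels["TA"][1200:-1200]) / (1 / np.sqrt(2))
        assert attenuation < 0.1

    def test_passband_tone_survives(self):
        t = np.arange(int(10 * FS)) / FS
        out = preprocess(_raw(np.sin(2 * np.pi * 100 * t)))
        assert rms(out.channels["TA"][1200:-1200]) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_zero_signal_stays_zero(self):
        out = preprocess(_raw(np.zeros(6000)))
        assert not out.channels["TA"].any()
        assert out.state == "rectified"

    def test_output_is_nonnegative(self):
        rng = np.random.default_rng(1)
        out = preprocess(_raw(rng.normal(0, 10, 6000)))
        assert (out.channels["TA"] >= 0).all()

    def test_double_preprocess_rejected(self):
        out = preprocess(_raw(np.zeros(6000)))
        with pytest.raises(ProcessingError):
            preprocess(out)

    def test_insufficient_sample_rate_rejected(self):
        rec = EmgRecording(
            times=np.arange(1000) / 800.0,
            channels={"TA": np.zeros(1000), "SOL": np.zeros(1000)},
            state="raw",
        )
        with pytest.raises(ProcessingError, match="sample rate"):
            preprocess(rec)


class TestRms:
    def test_constant_window(self):
        assert rms(np.full(100, -3.0)) == 3.0

    def test_unit_sine_full_cycles(self):
        t = np.arange(1200) / FS
        assert rms(np.abs(np.sin(2 * np.pi * 10 * t))) == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_hand_arithmetic(self):
        assert rms([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            rms(np.array([]))


class TestMvcReference:
    def _trial(self, level):
        x = np.full(int(2 * FS), 1.0)
        x[700:1700] = level  # plateau wider than the reference window
        x[1200] = level * 1.0001  # pin the maximal sample at the center
        return rectified_recording(x)

    def test_maximum_over_repetitions(self):
        trials = [self._trial(v) for v in (100.0, 180.0, 150.0)]
        ref = mvc_reference(trials, "TA")
        assert ref.mvc_rms == pytest.approx(180.0)
        assert ref.n_repetitions == 3

    def test_identical_trials(self):
        trials = [self._trial(120.0)] * 3
        assert mvc_reference(trials, "TA").mvc_rms == pytest.approx(120.0)

    def test_window_truncated_at_edge(self):
        x = np.full(int(0.4 * FS), 50.0)  # shorter than the 0.5 s window
        ref = mvc_reference([rectified_recording(x)], "TA")
        assert ref.mvc_rms == pytest.approx(50.0)

    def test_requires_preprocessed_trials(self):
        with pytest.raises(ProcessingError):
            mvc_reference([_raw(np.zeros(2400))], "TA")


class TestBaselineStats:
    def test_zero_baseline_zero_threshold(self):
        rec = rectified_recording(np.zeros(2400))
        stats = baseline_stats(rec, "TA", onset=1.0)
        assert stats.threshold == 0.0

    def test_hand_arithmetic_sample_sd(self):
        # four samples at 5 Hz fill a 0.8 s window
        rec = rectified_recording([1.0, 1.0, 1.0, 3.0, 0.0], sample_rate=5.0)
        stats = baseline_stats(rec, "TA", onset=0.8)
        assert stats.mean == pytest.approx(1.5)
        assert stats.sd == pytest.approx(1.0)
        assert stats.threshold == pytest.approx(2.5)

    def test_folded_gaussian_matches_closed_form(self):
        """Rectified Gaussian noise: mean ~ sigma*sqrt(2/pi), SD from folded-normal."""
        sigma = 1.58
        rng = np.random.default_rng(42)
        x = np.abs(rng.normal(0, sigma, int(100 * FS)))
        rec = rectified_recording(x)
        stats = baseline_stats(rec, "TA", onset=rec.times[-1], pre_window=99.0)
        mean_expected = sigma * np.sqrt(2 / np.pi)
        sd_expected = sigma * np.sqrt(1 - 2 / np.pi)
        assert stats.mean == pytest.approx(mean_expected, rel=0.02)
        assert stats.sd == pytest.approx(sd_expected, rel=0.02)

    def test_insufficient_pre_stimulus_data(self):
        rec = rectified_recording(np.zeros(600))
        with pytest.raises(ValueError):
            baseline_stats(rec, "TA", onset=0.4)


EVENT = StimulusEvent(2.0, 0.8, "heel", 3.5, "slow")


def _with_burst(level, start_s, dur_s, base=0.0):
    """Rectified-domain recording with a constant supra-threshold burst."""
    x = np.full(int(4 * FS), base)
    i0 = int(start_s * FS)
    x[i0 : i0 + int(dur_s * FS)] = level
    return rectified_recording(x)


class TestDetectReflex:
    BASE = BaselineStats(muscle="TA", mean=1.0, sd=0.5)

    def test_thirty_ms_burst_detected_with_latency(self):
        rec = _with_burst(7.5, 2.06, 0.03)  # 5x threshold, 60 ms latency
        res = detect_reflex(rec, "TA", EVENT, self.BASE)
        assert res.occurred
        assert res.onset_latency == pytest.approx(0.06, abs=2 / FS)
        assert res.peak_amplitude == pytest.approx(7.5)

    def test_five_ms_blip_rejected(self):
        rec = _with_burst(7.5, 2.06, 0.005)
        assert not detect_reflex(rec, "TA", EVENT, self.BASE).occurred

    def test_exact_threshold_is_not_above(self):
        rec = _with_burst(self.BASE.threshold, 2.06, 0.1)
        assert not detect_reflex(rec, "TA", EVENT, self.BASE).occurred

    def test_burst_must_fall_inside_window(self):
        rec = _with_burst(7.5, 3.0, 0.03)  # 1.0 s after onset, outside 0.8 s
        assert not detect_reflex(rec, "TA", EVENT, self.BASE).occurred

    def test_exact_duration_boundary(self):
        """Exactly 12 samples above threshold at 1200 Hz qualify; 11 do not."""
        for n_samples, expect in [(12, True), (11, False)]:
            x = np.zeros(int(4 * FS))
            i0 = int(2.1 * FS)
            x[i0 : i0 + n_samples] = 7.5
            rec = rectified_recording(x)
            assert detect_reflex(rec, "TA", EVENT, self.BASE).occurred is expect

    def test_double_burst_requires_gap(self):
        x = np.zeros(int(4 * FS))
        i0 = int(2.1 * FS)
        x[i0 : i0 + 24] = 7.5
        x[i0 + 24 + 24 : i0 + 24 + 24 + 24] = 7.5  # 20 ms gap
        res = detect_reflex(rectified_recording(x), "TA", EVENT, self.BASE)
        assert res.occurred and res.double_burst
        y = np.zeros(int(4 * FS))
        y[i0 : i0 + 24] = 7.5
        y[i0 + 24 + 6 : i0 + 24 + 6 + 24] = 7.5  # 5 ms gap: one burst
        res2 = detect_reflex(rectified_recording(y), "TA", EVENT, self.BASE)
        assert res2.occurred and not res2.double_burst

    def test_peak_normalized_by_mvc(self):
        rec = _with_burst(90.0, 2.06, 0.03)
        mvc = MvcReference("TA", mvc_rms=180.0)
        res = detect_reflex(rec, "TA", EVENT, self.BASE, mvc=mvc)
        assert res.peak_amplitude == pytest.approx(50.0)


class TestOccurrenceScoring:
    def _events(self, flags):
        return [
            emg.ReflexEvent(trial=i, muscle="TA", occurred=f) for i, f in enumerate(flags)
        ]

    @pytest.mark.parametrize(
        "flags,expected",
        [([True, False, False, False], 25.0),
         ([True] * 4, 100.0),
         ([False] * 4, 0.0)],
    )
    def test_quarter_resolution(self, flags, expected):
        assert reflex_occurrence(self._events(flags)) == expected

    def test_occurrence_times_trials_is_integer(self):
        for k in range(5):
            flags = [True] * k + [False] * (4 - k)
            pct = reflex_occurrence(self._events(flags))
            assert (pct * 4 / 100) == pytest.approx(round(pct * 4 / 100))

    def test_excluded_trials_dropped_from_denominator(self):
        events = self._events([True, False, False, False])
        events[1] = emg.ReflexEvent(trial=1, muscle="TA", occurred=False, excluded=True)
        assert reflex_occurrence(events) == pytest.approx(100 / 3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            reflex_occurrence([])


class TestSinglePulseRms:
    def test_normalization_identity(self):
        rec = rectified_recording(np.full(int(4 * FS), 55.0))
        mvc = MvcReference("TA", mvc_rms=55.0)
        assert single_pulse_rms(rec, "TA", EVENT, mvc) == pytest.approx(100.0)

    def test_zero_signal(self):
        rec = rectified_recording(np.zeros(int(4 * FS)))
        mvc = MvcReference("TA", mvc_rms=55.0)
        assert single_pulse_rms(rec, "TA", EVENT, mvc) == 0.0

    def test_gain_invariance_of_normalized_value(self):
        """%MVC is invariant to a common gain on signal and reference."""
        x = np.abs(np.sin(np.arange(int(4 * FS)) / 40.0)) * 30.0
        a = single_pulse_rms(rectified_recording(x), "TA", EVENT, MvcReference("TA", 80.0))
        b = single_pulse_rms(
            rectified_recording(x * 7.3), "TA", EVENT, MvcReference("TA", 80.0 * 7.3)
        )
        assert a == pytest.approx(b)

    def test_truncated_event_rejected(self):
        rec = rectified_recording(np.zeros(int(2.5 * FS)))
        mvc = MvcReference("TA", mvc_rms=55.0)
        with pytest.raises(ValueError):
            single_pulse_rms(rec, "TA", EVENT, mvc)


class TestCyclicRmsRatio:
    def test_rest_like_stimulation_gives_unity(self):
        sched = cyclic_protocol(5.0, 3.5, n_cycles=2, lead_in_rest=5.0)
        rng = np.random.default_rng(3)
        x = np.abs(rng.normal(0, 1.3, int(16 * FS)))
        assert cyclic_rms_ratio(rectified_recording(x), "TA", sched) == pytest.approx(1.0, abs=0.05)

    def test_constructed_threefold_increase(self):
        sched = cyclic_protocol(5.0, 3.5, n_cycles=2, lead_in_rest=5.0)
        x = np.full(int(16 * FS), 2.0)
        for e in sched.events_at("heel") + sched.events_at("forefoot"):
            x[int(e.onset * FS) : int(e.offset * FS)] = 6.0
        assert cyclic_rms_ratio(rectified_recording(x), "TA", sched) == pytest.approx(3.0, rel=0.01)

    def test_requires_cyclic_schedule(self):
        from solereflex.stimulus import ProtocolSchedule

        sched = ProtocolSchedule(events=[EVENT], kind="single_pulse")
        with pytest.raises(ValueError, match="cyclic"):
            cyclic_rms_ratio(rectified_recording(np.ones(int(4 * FS))), "TA", sched)

    def test_missing_rest_period_rejected(self):
        sched = cyclic_protocol(5.0, 3.5, n_cycles=1, lead_in_rest=1.0)
        with pytest.raises(ValueError, match="rest"):
            cyclic_rms_ratio(rectified_recording(np.ones(int(8 * FS))), "TA", sched)


class TestNoiseFlagging:
    def test_high_sd_trials_flagged(self):
        baselines = [BaselineStats("TA", 1.0, sd) for sd in [0.5, 0.6, 0.55, 5.0, 0.45]]
        flags = flag_noisy_trials(baselines)
        assert flags == [False, False, False, True, False]
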