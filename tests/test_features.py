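import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import get_window, periodogram

from tuglab import features, segment, synth
from tuglab.features import (
    count_steps,
    dominant_frequency,
    extract_all,
    psd_peak_measures,
    regularity,
    step_stride_timing,
    step_symmetry,
    total_duration,
    transition_measures,
    turn_measures,
)
from tuglab.segment import Segment, SegmentedTask

from conftest import truth_bounds

FS = 100.0


def _periodic_gait(duration_s=10.0, step_hz=2.0, asymmetry=1.0, cv=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s * step_hz))
    sig, peaks = synth.gait_waveform(
        n_steps, 1.0 / step_hz, FS, rng, cv=cv, asymmetry=asymmetry, amp_jitter=0.0
    )
    return sig, peaks


def _dummy_recording(n=1200, fs=FS):
    zeros = np.zeros(n)
    return synth.SensorRecording(
        fs=fs,
        acc_v=zeros.copy(),
        acc_ml=zeros.copy(),
        acc_ap=zeros.copy(),
        gyr_yaw=zeros.copy(),
        gyr_pitch=zeros.copy(),
        gyr_roll=zeros.copy(),
        task="TUG",
        trial_index=1,
        participant_id="dummy",
    )


class TestTotalDuration:
    def test_six_two_second_segments(self):
        rec = _dummy_recording(1200)
        segs = [Segment(lbl, i * 200, (i + 1) * 200) for i, lbl in enumerate(segment.TUG_LABELS)]
        st = SegmentedTask(rec, segs, "TUG")
        assert total_duration(st) == pytest.approx(12.0)

    def test_equals_span_for_contiguous_cover(self, tug_segmented):
        st = tug_segmented
        span = (st.segments[-1].end_idx - st.segments[0].start_idx) / st.fs
        assert total_duration(st) == pytest.approx(span)


class TestCountSteps:
    def test_pure_two_hz_oscillation(self):
        t = np.arange(0, 5.0, 1 / FS)
        assert count_steps(np.sin(2 * np.pi * 2.0 * t), FS) == 10

    def test_flat_signal(self):
        assert count_steps(np.zeros(500), FS) == 0

    def test_jittered_walk_matches_generator_truth(self):
        sig, peaks = _periodic_gait(duration_s=8.0, cv=0.05, seed=3)
        assert abs(count_steps(sig, FS) - len(peaks)) <= 1


class TestStepStrideTiming:
    def test_exact_two_hz(self):
        t = np.arange(0, 5.0, 1 / FS)
        step, stride = step_stride_timing(np.sin(2 * np.pi * 2.0 * t), FS)
        assert step == pytest.approx(0.5, abs=0.01)
        assert stride == pytest.approx(1.0, abs=0.02)

    def test_stride_is_twice_step_for_regular_gait(self):
        sig, _ = _periodic_gait()
        step, stride = step_stride_timing(sig, FS)
        assert stride == pytest.approx(2 * step, rel=0.02)

    def test_too_few_peaks_undefined(self):
        step, stride = step_stride_timing(np.zeros(500), FS)
        assert math.isnan(step) and math.isnan(stride)

    def test_jittered_gait_matches_truth_intervals(self):
        sig, peaks = _periodic_gait(duration_s=12.0, cv=0.06, seed=9)
        step, _ = step_stride_timing(sig, FS)
        true_step = np.mean(np.diff(peaks)) / FS
        assert step == pytest.approx(true_step, rel=0.05)


class TestRegularity:
    def test_noiseless_periodic_gait(self):
        sig, _ = _periodic_gait()
        step_reg, stride_reg = regularity(sig, FS)
        assert stride_reg == pytest.approx(1.0, abs=0.01)
        assert step_reg == pytest.approx(1.0, abs=0.01)

    def test_white_noise_near_zero(self, rng):
        x = rng.standard_normal(1000)  # 10 s
        step_reg, stride_reg = regularity(x, FS)
        for v in (step_reg, stride_reg):
            assert math.isnan(v) or abs(v) < 0.2

    def test_asymmetric_gait_step_below_stride(self):
        sig, _ = _periodic_gait(asymmetry=0.5)
        step_reg, stride_reg = regularity(sig, FS)
        assert step_reg < stride_reg
        # closed-form two-amplitude comb: corr at one-step lag ~ 2r/(1+r^2)
        r = 0.5
        assert step_reg == pytest.approx(2 * r / (1 + r * r), abs=0.08)

    def test_bounds_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(80, 400)
            x = rng.standard_normal(n) * rng.uniform(0.1, 5.0)
            s, t = regularity(x, FS)
            for v in (s, t):
                assert math.isnan(v) or -1.0 <= v <= 1.0
            sym = step_symmetry(s, t)
            assert math.isnan(sym) or 0.0 < sym <= 1.0


class TestStepSymmetry:
    @pytest.mark.parametrize(
        "s,t,expected", [(0.8, 0.8, 1.0), (0.5, 1.0, 0.5), (1.0, 0.5, 0.5)]
    )
    def test_examples(self, s, t, expected):
        assert step_symmetry(s, t) == pytest.approx(expected)

    def test_nonpositive_stride_undefined(self):
        assert math.isnan(step_symmetry(0.5, 0.0))
        assert math.isnan(step_symmetry(0.5, -0.2))


class TestDominantFrequency:
    def test_pure_tone(self):
        t = np.arange(0, 10.0, 1 / FS)
        assert dominant_frequency(np.sin(2 * np.pi * 1.8 * t), FS) == pytest.approx(1.8, abs=0.1)

    def test_larger_amplitude_wins(self):
        t = np.arange(0, 10.0, 1 / FS)
        x = 1.0 * np.sin(2 * np.pi * 1.0 * t) + 2.0 * np.sin(2 * np.pi * 3.0 * t)
        assert dominant_frequency(x, FS) == pytest.approx(3.0, abs=0.1)

    def test_turn_pulse_matches_analytic_spectrum(self, noiseless_control):
        # the raised-cosine yaw pulse has its single non-DC component at 1/T
        rec = synth.simulate_recording(noiseless_control, "TUG", 1, seed=4)
        ts, te = truth_bounds(rec)["turn1"]
        yaw = rec.gyr_yaw[ts:te]
        expected = 1.0 / ((te - ts) / rec.fs)
        bin_width = rec.fs / len(yaw)
        assert dominant_frequency(yaw, rec.fs) == pytest.approx(expected, abs=bin_width)


class TestPsdPeakMeasures:
    def test_pure_tone_width_within_two_bins(self):
        t = np.arange(0, 20.0, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t)
        amp, width, slope = psd_peak_measures(x, FS)
        bin_hz = FS / 256
        assert width <= 2 * bin_hz
        assert slope < 0

    def test_broadband_wider_than_tone(self, rng):
        t = np.arange(0, 20.0, 1 / FS)
        tone = np.sin(2 * np.pi * 2.0 * t)
        noise = rng.standard_normal(len(t))
        _, w_tone, _ = psd_peak_measures(tone, FS)
        _, w_noise, _ = psd_peak_measures(noise, FS)
        assert w_noise > w_tone

    def test_amplitude_matches_periodogram_oracle(self, rng):
        t = np.arange(0, 40.0, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t) + 0.05 * rng.standard_normal(len(t))
        amp, _, _ = psd_peak_measures(x, FS)
        # independent single-segment Hann periodogram at the Welch resolution
        f, p = periodogram(x[:256], fs=FS, window=get_window("hann", 256))
        assert amp == pytest.approx(p.max(), rel=0.10)


class TestTransitionMeasures:
    def test_constant_signal_degenerate(self):
        tm = transition_measures(np.full(200, 3.7), FS)
        assert tm["range"] == 0.0
        assert tm["jerk"] == 0.0
        assert tm["sd"] == 0.0
        assert tm["median"] == pytest.approx(3.7)

    def test_linear_ramp_jerk_equals_slope(self):
        a = 0.8  # g/s
        t = np.arange(0, 2.0, 1 / FS)
        tm = transition_measures(a * t, FS)
        assert tm["jerk"] == pytest.approx(a, rel=0.01)

    def test_synthetic_pulse_range_matches_generator(self, noiseless_control):
        rec = synth.simulate_recording(noiseless_control, "TUG", 1, seed=6)
        ts, te = truth_bounds(rec)["sit_to_stand"]
        tm = transition_measures(rec.acc_ap[ts:te], FS)
        assert tm["range"] == pytest.approx(rec.truth["transition_amp_ap"], rel=0.05)

    def test_median_is_offset_sensitive(self):
        x = np.linspace(0, 1, 100)
        assert transition_measures(x + 5.0, FS)["median"] == pytest.approx(
            transition_measures(x, FS)["median"] + 5.0
        )


class TestTurnMeasures:
    def test_simulated_turn_amplitude(self, noiseless_control):
        rec = synth.simulate_recording(noiseless_control, "TUG", 1, seed=1)
        st = segment.segment_tug(rec)
        tm = turn_measures(rec, st["turn1"])
        assert tm["amplitude_yaw_deg"] == pytest.approx(180.0, abs=10.0)

    def test_zero_rotation(self):
        rec = _dummy_recording()
        tm = turn_measures(rec, Segment("turn", 100, 300))
        assert tm["amplitude_yaw_deg"] == 0.0

    def test_in_turn_step_count_matches_truth(self, noiseless_control):
        rec = synth.simulate_recording(noiseless_control, "TUG", 1, seed=1)
        ts, te = truth_bounds(rec)["turn1"]
        true_steps = len(rec.truth["step_peaks"]["turn1"])
        tm = turn_measures(rec, Segment("turn", ts, te))
        assert abs(tm["step_count"] - true_steps) <= 1


class TestExtractAll:
    def test_tug_schema_complete_and_unique(self, tug_segmented):
        df = extract_all(tug_segmented)
        assert df["measure"].is_unique
        # 1 total + 6 durations + 2 walks x 2 axes x 9 + 2 transitions x 2 axes x 4 + 2 turns x 3
        assert len(df) == 1 + 6 + 36 + 16 + 6

    def test_16ft_walk_measures_twice_turn_once(self, walk32_recording):
        a, _ = segment.split_32ft(walk32_recording)
        df = extract_all(a)
        walk_measures = df[df.measure.str.startswith(("walk1_", "walk2_"))]
        assert len(walk_measures) == 2 + 2 * 2 * 9
        assert (df.measure.str.startswith("turn_")).sum() == 1 + 3

    def test_flat_signal_durations_present_gait_undefined(self):
        rec = _dummy_recording(1800)
        segs = [Segment(lbl, i * 300, (i + 1) * 300) for i, lbl in enumerate(segment.TUG_LABELS)]
        df = extract_all(SegmentedTask(rec, segs, "TUG", 1)).set_index("measure")["value"]
        assert df["total_duration"] == pytest.approx(18.0)
        assert np.isfinite(df[[f"{l}_duration" for l in segment.TUG_LABELS]]).all()
        assert math.isnan(df["walk1_v_step_regularity"])
        assert df["walk1_v_step_count"] == 0

    def test_offset_invariance_except_median(self, tug_recording, tug_segmented):
        base = extract_all(tug_segmented).set_index("measure")["value"]
        shifted_rec = synth.SensorRecording(
            fs=tug_recording.fs,
            acc_v=tug_recording.acc_v + 0.5,
            acc_ml=tug_recording.acc_ml + 0.5,
            acc_ap=tug_recording.acc_ap + 0.5,
            gyr_yaw=tug_recording.gyr_yaw,
            gyr_pitch=tug_recording.gyr_pitch,
            gyr_roll=tug_recording.gyr_roll,
            task=tug_recording.task,
            trial_index=tug_recording.trial_index,
            participant_id=tug_recording.participant_id,
        )
        st = SegmentedTask(shifted_rec, tug_segmented.segments, "TUG", 1)
        shifted = extract_all(st).set_index("measure")["value"]
        for name in base.index:
            if name.endswith("_median"):
                assert shifted[name] == pytest.approx(base[name] + 0.5, abs=1e-9)
            elif math.isnan(base[name]):
                assert math.isnan(shifted[name])
            else:
                assert shifted[name] == pytest.approx(base[name], abs=1e-9), name

    def test_sampling_rate_invariance(self, noiseless_control):
        vals = {}
        for fs in (100.0, 200.0):
            rec = synth.simulate_recording(noiseless_control, "TUG", 1, seed=8, fs=fs)
            # ground-truth segmentation so only the measures themselves vary
            segs = [Segment(lbl, s, e) for lbl, s, e in rec.truth["segments"]]
            st = SegmentedTask(rec, segs, "TUG", 1)
            vals[fs] = extract_all(st).set_index("measure")["value"]
        for name in vals[100.0].index:
            a, b = vals[100.0][name], vals[200.0][name]
            if math.isnan(a) or math.isnan(b):
                continue
            # 0.005 absolute floor: below the 1 mg sensor resolution scale,
            # where grid discreteness dominates the relative error
            assert b == pytest.approx(a, rel=0.02, abs=5e-3), name
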