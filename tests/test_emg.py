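"""EMG features: segment RMS vs a direct-sum oracle, the normalization
identity, calibration, activity segmentation and motion-group assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rehabsig import emg, synth
from rehabsig.errors import (
    InsufficientDataError,
    InvalidCalibrationError,
    InvalidInputError,
    NoActivityError,
)
from rehabsig.types import MotionGroup, SampledSignal


def _sig(x, fs=1000.0, channel="FCR"):
    return SampledSignal(np.asarray(x, dtype=float), fs=fs, channel=channel)


class TestRectify:
    def test_mixed_signs(self):
        out = emg.rectify(_sig([-1.0, 2.0, -3.0]))
        np.testing.assert_array_equal(out.samples, [1.0, 2.0, 3.0])

    def test_nonnegative_input_unchanged(self, rng):
        x = np.abs(rng.normal(size=100))
        np.testing.assert_array_equal(emg.rectify(_sig(x)).samples, x)

    def test_idempotent(self, rng):
        x = rng.normal(size=100)
        once = emg.rectify(_sig(x))
        np.testing.assert_array_equal(emg.rectify(once).samples, once.samples)


class TestRmsSegments:
    def test_constant_signal(self):
        s = emg.rms_segments(_sig(np.full(600, 2.0)), n=200)
        np.testing.assert_allclose(s.rms, [2.0, 2.0, 2.0])

    def test_alternating_unit_signal(self):
        x = np.tile([1.0, -1.0], 200)
        s = emg.rms_segments(_sig(x), n=200)
        np.testing.assert_allclose(s.rms, [1.0, 1.0])

    def test_matches_direct_sum_oracle(self, rng):
        x = rng.normal(size=1000)
        s = emg.rms_segments(_sig(x), n=200)
        for i in range(5):
            seg = x[i * 200 : (i + 1) * 200]
            expected = np.sqrt(sum(v * v for v in seg) / 200.0)
            assert abs(s.rms[i] - expected) <= 1e-12 * expected

    def test_trailing_remainder_dropped(self, rng):
        s = emg.rms_segments(_sig(rng.normal(size=599)), n=200)
        assert len(s) == 2

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            emg.rms_segments(_sig(np.zeros(100)), n=200)

    @given(
        arrays(np.float64, 400, elements=st.floats(-10, 10)),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_equivariance(self, x, a):
        base = emg.rms_segments(_sig(x), n=200).rms
        scaled = emg.rms_segments(_sig(a * x), n=200).rms
        np.testing.assert_allclose(scaled, a * base, rtol=1e-12, atol=1e-300)


class TestCalibration:
    def test_mean_of_three_trial_maxima(self):
        trials = [
            _sig(np.full(200, 2.0)),
            _sig(np.full(200, 2.2)),
            _sig(np.full(200, 1.8)),
        ]
        cal = emg.calibrate_rms_max(trials)
        np.testing.assert_allclose(cal.trial_rms, [2.0, 2.2, 1.8])
        assert cal.rms_m == pytest.approx(2.0)

    def test_identical_trials(self):
        trials = [_sig(np.full(400, 1.5))] * 3
        cal = emg.calibrate_rms_max(trials)
        assert cal.rms_m == pytest.approx(1.5)

    def test_generator_trials_recover_configured_maximum(self):
        target = 2.0
        trials = [
            synth.gen_emg(
                [("finger_flexion", 500.0, 2000.0)], seed=30 + i, dominant_rms=target
            )[0]
            for i in range(3)
        ]
        cal = emg.calibrate_rms_max(trials)
        assert cal.rms_m == pytest.approx(target, rel=0.10)

    def test_empty_trial_list_rejected(self):
        with pytest.raises(InvalidInputError):
            emg.calibrate_rms_max([])

    def test_mixed_channels_rejected(self):
        with pytest.raises(InvalidInputError):
            emg.calibrate_rms_max([_sig(np.ones(200), channel="FCR"),
                                   _sig(np.ones(200), channel="ECRL")])


class TestNormalize:
    def _cal(self, rms_m, channel="FCR"):
        return emg.CalibrationRecord(channel=channel, trial_rms=[rms_m], rms_m=rms_m)

    def test_rms_equal_to_benchmark_maps_to_one(self):
        s = emg.rms_segments(_sig(np.full(200, 1.3)), n=200)
        out = emg.normalize(s, self._cal(1.3))
        np.testing.assert_allclose(out.rms_normalized, [1.0])

    def test_zero_rms_maps_to_zero(self):
        s = emg.rms_segments(_sig(np.zeros(200)), n=200)
        out = emg.normalize(s, self._cal(2.0))
        np.testing.assert_array_equal(out.rms_normalized, [0.0])

    @given(arrays(np.float64, 600, elements=st.floats(-5, 5)),
           st.floats(min_value=1e-3, max_value=100))
    def test_round_trip_identity(self, x, rms_m):
        s = emg.rms_segments(_sig(x), n=200)
        out = emg.normalize(s, self._cal(rms_m))
        np.testing.assert_allclose(out.rms_normalized * rms_m, s.rms, rtol=1e-12, atol=1e-300)

    def test_invalid_benchmark_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            emg.CalibrationRecord(channel="FCR", trial_rms=[0.0], rms_m=0.0)

    def test_channel_mismatch_rejected(self):
        s = emg.rms_segments(_sig(np.ones(200), channel="ECRL"), n=200)
        with pytest.raises(InvalidInputError):
            emg.normalize(s, self._cal(1.0, channel="FCR"))


def _normalized_pair(motions, seed, rms_m=2.0, **kwargs):
    fcr, ecrl, truth = synth.gen_emg(motions, seed=seed, **kwargs)
    out = []
    for sig in (fcr, ecrl):
        s = emg.rms_segments(sig, n=200)
        cal = emg.CalibrationRecord(channel=sig.channel, trial_rms=[rms_m], rms_m=rms_m)
        out.append(emg.normalize(s, cal))
    return out[0], out[1], truth


class TestSegmentation:
    def test_pure_baseline_has_no_events(self):
        nf, ne, _ = _normalized_pair([], seed=1)
        assert emg.segment_activity(nf) == []
        assert emg.segment_activity(ne) == []

    def test_single_burst_overlaps_truth_window(self):
        nf, ne, truth = _normalized_pair([("finger_flexion", 3000.0, 2500.0)], seed=2)
        events = emg.segment_activity(nf)
        assert len(events) == 1
        (onset, offset), w = events[0], truth.motion_windows[0]
        overlap = min(offset, w.offset_ms) - max(onset, w.onset_ms)
        assert overlap >= 0.8 * (w.offset_ms - w.onset_ms)

    def test_two_separated_bursts_in_order(self):
        nf, _, _ = _normalized_pair(
            [("finger_flexion", 2000.0, 2000.0), ("forearm_pronation", 9000.0, 2000.0)], seed=3
        )
        events = emg.segment_activity(nf)
        assert len(events) == 2
        assert events[0][1] <= events[1][0]

    def test_unnormalized_input_rejected(self):
        s = emg.rms_segments(_sig(np.ones(1000)), n=200)
        with pytest.raises(InvalidInputError):
            emg.segment_activity(s)


class TestClassifyMotion:
    def test_fcr_dominant(self):
        assert emg.classify_motion(1.5, 0.8) is MotionGroup.FCR_DOMINANT

    def test_ecrl_dominant(self):
        assert emg.classify_motion(0.8, 1.5) is MotionGroup.ECRL_DOMINANT

    def test_exact_tie_is_indeterminate(self):
        assert emg.classify_motion(1.0, 1.0) is MotionGroup.INDETERMINATE

    def test_no_activity_rejected(self):
        with pytest.raises(NoActivityError):
            emg.classify_motion(0.05, 0.1)


class TestMotionEvents:
    @pytest.mark.parametrize("seed", range(5))
    def test_every_truth_window_yields_one_correct_event(self, seed):
        rng = np.random.default_rng(seed)
        labels = list(rng.permutation(list(synth.MOTION_LABELS)))
        motions = [(lab, 1500.0 + 5000.0 * i, 2000.0) for i, lab in enumerate(labels)]
        nf, ne, truth = _normalized_pair(motions, seed=100 + seed)
        events = emg.detect_motion_events(nf, ne)
        assert len(events) == len(truth.motion_windows)
        for e, w in zip(events, truth.motion_windows):
            assert e.motion_group is w.group
            assert abs(e.onset_ms - w.onset_ms) < 1000.0

    def test_weak_activity_monotone_in_envelope_amplitude(self):
        peaks = []
        for amp in (0.6, 0.9, 1.2, 1.5):
            nf, ne, _ = _normalized_pair(
                [("finger_flexion", 2000.0, 2000.0)], seed=7,
                dominant_rms=amp, nondominant_rms=0.5 * amp,
            )
            (e,) = emg.detect_motion_events(nf, ne)
            peaks.append(e.peak_rms_n_fcr)
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_saturation_annotation(self):
        nf, ne, _ = _normalized_pair(
            [("finger_flexion", 2000.0, 2000.0)], seed=8, rms_m=1.0, dominant_rms=1.3
        )
        (e,) = emg.detect_motion_events(nf, ne)
        assert e.possibly_saturated
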