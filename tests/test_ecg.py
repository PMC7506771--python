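"""ECG conditioning and feature extraction, checked against independent
oracles: sinusoid fits for filter gains, brute-force window medians, and
direct recomputation of HRV statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rehabsig import ecg, synth
from rehabsig.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from rehabsig.types import NoiseSpec, RPeakSeries, SampledSignal


def _sine(freq_hz, fs=500.0, duration_s=5.0, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return SampledSignal(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)


def _fit_amplitude(samples, freq_hz, fs):
    """Least-squares sinusoid amplitude at a known frequency."""
    t = np.arange(samples.size) / fs
    design = np.column_stack([np.sin(2 * np.pi * freq_hz * t), np.cos(2 * np.pi * freq_hz * t)])
    coef, *_ = np.linalg.lstsq(design, samples, rcond=None)
    return float(np.hypot(*coef))


class TestLowpass:
    def test_dc_gain_is_unity(self):
        sig = SampledSignal(np.full(2000, 3.7), fs=500.0)
        out = ecg.lowpass_filter(sig)
        assert np.max(np.abs(out.samples - 3.7)) < 1e-9

    def test_passband_5hz_attenuation_below_2pct(self):
        out = ecg.lowpass_filter(_sine(5.0))
        amp = _fit_amplitude(out.samples[500:-500], 5.0, 500.0)
        assert abs(amp - 1.0) < 0.02

    def test_stopband_80hz_attenuated_over_90pct(self):
        out = ecg.lowpass_filter(_sine(80.0))
        amp = _fit_amplitude(out.samples[500:-500], 80.0, 500.0)
        assert amp < 0.10

    def test_cutoff_gain_is_minus_3db(self):
        out = ecg.lowpass_filter(_sine(40.0))
        amp = _fit_amplitude(out.samples[500:-500], 40.0, 500.0)
        assert 0.64 < amp < 0.78  # 1/sqrt(2) +/- 10%

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            ecg.lowpass_filter(_sine(5.0), cutoff=250.0)


class TestBaselineRemoval:
    def test_constant_maps_to_zero(self):
        sig = SampledSignal(np.full(1000, 2.5), fs=500.0)
        out = ecg.remove_baseline_median(sig)
        assert np.max(np.abs(out.samples)) < 1e-12

    def test_slow_ramp_maps_to_near_zero_interior(self):
        sig = SampledSignal(np.linspace(0, 1, 5000), fs=500.0)
        out = ecg.remove_baseline_median(sig)
        interior = out.samples[400:-400]
        assert np.max(np.abs(interior)) < 1e-9

    def test_wander_reduced_at_least_80pct(self):
        rr = synth.gen_rr_series("excited", 12, 800, seed=3)
        spec = NoiseSpec(baseline_wander_amp=0.3, baseline_wander_freq=0.3)
        noisy, _ = synth.gen_ecg(rr, fs=500.0, noise=spec, seed=3)
        out = ecg.remove_baseline_median(noisy)
        amp = _fit_amplitude(out.samples[500:-500], 0.3, 500.0)
        assert amp < 0.2 * 0.3

    def test_matches_brute_force_median(self, rng):
        x = rng.normal(size=400)
        sig = SampledSignal(x, fs=500.0)
        out = ecg.remove_baseline_median(sig, window_ms=50.0)
        w = 25  # 50 ms at 500 Hz, forced odd
        padded = np.pad(x, w // 2, mode="symmetric")
        expected = np.array([x[i] - np.median(padded[i : i + w]) for i in range(x.size)])
        np.testing.assert_allclose(out.samples, expected, atol=1e-12)

    def test_idempotent_on_constant(self):
        sig = SampledSignal(np.full(1000, 1.0), fs=500.0)
        once = ecg.remove_baseline_median(sig)
        twice = ecg.remove_baseline_median(once)
        assert np.max(np.abs(twice.samples - once.samples)) < 1e-9

    def test_window_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            ecg.remove_baseline_median(SampledSignal(np.zeros(100), fs=500.0), window_ms=2.0)


class TestArtifactSuppression:
    def test_clean_ecg_passes_unchanged(self, clean_ecg):
        sig, _ = clean_ecg
        cond = ecg.remove_baseline_median(ecg.lowpass_filter(sig))
        out = ecg.suppress_artifacts(cond)
        np.testing.assert_array_equal(out.samples, cond.samples)

    def test_injected_spike_removed_neighbors_kept(self, clean_ecg):
        sig, _ = clean_ecg
        cond = ecg.remove_baseline_median(ecg.lowpass_filter(sig))
        x = cond.samples.copy()
        x[700] += 10.0  # 10 V artifact, far above any R wave
        out = ecg.suppress_artifacts(cond.copy_with(x))
        assert abs(out.samples[700]) < 1.0
        np.testing.assert_array_equal(out.samples[:650], x[:650])
        np.testing.assert_array_equal(out.samples[750:], x[750:])

    def test_constant_signal_passes_through(self):
        sig = SampledSignal(np.full(1000, 0.5), fs=500.0)
        out = ecg.suppress_artifacts(sig)
        np.testing.assert_array_equal(out.samples, sig.samples)

    def test_suppression_never_hurts_detection_f1(self):
        rr = synth.gen_rr_series("excited", 80, 800, seed=4)
        spec = NoiseSpec(motion_artifact_rate=6.0, motion_artifact_amp=2.0, white_noise_sd=0.02)
        noisy, truth = synth.gen_ecg(rr, fs=500.0, noise=spec, seed=4)
        base = ecg.remove_baseline_median(ecg.lowpass_filter(noisy))

        def f1(signal):
            pk = ecg.detect_r_peaks(signal)
            m, nt, nd = ecg.match_peak_times(truth.r_peak_times, pk.peak_times, tol_ms=20.0)
            return 2 * m / (nt + nd)

        assert f1(ecg.suppress_artifacts(base)) >= f1(base)


class TestDetectRPeaks:
    def test_clean_three_interval_ecg(self, clean_ecg):
        sig, truth = clean_ecg
        pk = ecg.detect_r_peaks(ecg.condition(sig))
        assert len(pk) == 4
        np.testing.assert_allclose(pk.peak_times, truth.r_peak_times, atol=1000.0 / sig.fs)

    def test_flat_signal_yields_no_peaks(self):
        sig = SampledSignal(np.zeros(2000), fs=500.0)
        assert len(ecg.detect_r_peaks(sig)) == 0

    def test_short_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            ecg.detect_r_peaks(SampledSignal(np.zeros(100), fs=500.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_output_respects_refractory_invariant(self, seed):
        sig, _ = synth.gen_ecg_at_bpm(
            bpm=70 + 10 * seed, duration_min=0.5, noise=NoiseSpec.ambulatory(), seed=seed
        )
        pk = ecg.detect_r_peaks(ecg.condition(sig))
        gaps = np.diff(pk.peak_times)
        assert np.all(gaps >= pk.min_rr_ms - 1e-9)


class TestAnnotateWaves:
    def test_wave_ordering_around_r(self, clean_ecg):
        sig, _ = clean_ecg
        cond = ecg.condition(sig)
        pk = ecg.detect_r_peaks(cond)
        beats = ecg.annotate_waves(cond, pk)
        for b in beats[1:-1]:  # interior beats have all five waves
            assert b["P"] < b["Q"] < b["R"] < b["S"] < b["T"]


class TestComputeRR:
    def test_uniform_peaks(self):
        pk = RPeakSeries(
            peak_times=[0.0, 1000.0, 2000.0, 3000.0],
            peak_indices=[0, 500, 1000, 1500],
            peak_amplitudes=[1.0] * 4,
        )
        np.testing.assert_array_equal(ecg.compute_rr(pk).intervals, [1000.0, 1000.0, 1000.0])

    def test_mixed_intervals(self):
        pk = RPeakSeries([0.0, 800.0, 1900.0], [0, 400, 950], [1.0] * 3)
        np.testing.assert_array_equal(ecg.compute_rr(pk).intervals, [800.0, 1100.0])

    def test_fewer_than_two_peaks_rejected(self):
        pk = RPeakSeries([500.0], [250], [1.0])
        with pytest.raises(InsufficientDataError):
            ecg.compute_rr(pk)

    @given(
        st.lists(st.floats(min_value=300, max_value=2000), min_size=2, max_size=50)
    )
    def test_interval_sum_telescopes_to_span(self, gaps):
        times = 1000.0 + np.cumsum(np.concatenate(([0.0], gaps)))
        pk = RPeakSeries(times, np.arange(times.size), np.ones(times.size))
        rr = ecg.compute_rr(pk)
        assert math.fsum(rr.intervals) == pytest.approx(times[-1] - times[0], rel=1e-12)


class TestHrvWindows:
    def test_three_interval_variation(self):
        rr = ecg.compute_rr(
            RPeakSeries(np.cumsum([0.0, 101.0, 80.0, 113.0]) + 300.0, [0, 1, 2, 3], [1.0] * 4)
        )
        stats = ecg.hrv_windows(rr, k=3)
        assert len(stats) == 1
        assert stats[0].variation == pytest.approx(33.0)

    def test_identical_intervals_have_zero_spread(self):
        from rehabsig.types import RRSeries

        rr = RRSeries(np.full(10, 900.0), np.cumsum(np.full(10, 900.0)))
        (s,) = ecg.hrv_windows(rr, k=10)
        assert s.variation == 0 and s.sdnn == 0 and s.rmssd == 0
        assert s.mean_rr == pytest.approx(900.0)

    def test_matches_brute_force_recomputation(self, rng):
        from rehabsig.types import RRSeries

        x = rng.uniform(600, 1000, size=40)
        rr = RRSeries(x, np.cumsum(x))
        stats = ecg.hrv_windows(rr, k=10)
        assert len(stats) == 40 - 10 + 1
        for s in stats:
            w = x[s.start_index : s.start_index + 10]
            assert s.variation == pytest.approx(w.max() - w.min())
            assert s.mean_rr == pytest.approx(w.mean())
            assert s.sdnn == pytest.approx(np.std(w, ddof=1))
            assert s.rmssd == pytest.approx(np.sqrt(np.mean(np.diff(w) ** 2)))

    def test_too_few_intervals_rejected(self):
        from rehabsig.types import RRSeries

        rr = RRSeries(np.full(5, 900.0), np.cumsum(np.full(5, 900.0)))
        with pytest.raises(InsufficientDataError):
            ecg.hrv_windows(rr, k=10)
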