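"""ECG conditioning, R-peak detection and windowed HRV statistics.

Processing chain (applied in this order by :func:`condition`):

1. 40 Hz zero-phase low-pass (4th-order Butterworth, forward-backward) to
   strip high-frequency interference while preserving QRS timing.
2. Sliding-window median subtraction (600 ms default) to remove baseline
   wander without distorting the beat morphology.
3. Adaptive-threshold artifact suppression: samples deviating from a running
   median by more than ``k_mad`` running MADs are replaced by linear
   interpolation. Because an ECG is a sparse, spiky signal, a raw MAD badly
   underestimates its legitimate dynamic range, so the threshold is floored
   at a multiple of the robust (99.5th-percentile) deviation; this keeps the
   QRS complexes of a clean trace untouched while still catching
   motion-artifact bumps that dwarf the R wave.

R-peak detection follows the differential-threshold scheme: local maxima are
located by a sign change of the first-order difference, candidates below
half of the maximum candidate amplitude are discarded, and remaining
candidates closer together than a minimum R-R interval (300 ms) are pruned
keeping the larger one ("singularity removal"). The half-max threshold is
evaluated per 10 s chunk to bound the effect of slow amplitude drift.
"""

from __future__ import annotations

import bisect

import numpy as np
import scipy.ndimage
import scipy.signal

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .types import HRVWindowStat, RPeakSeries, RRSeries, SampledSignal

__all__ = [
    "lowpass_filter",
    "remove_baseline_median",
    "suppress_artifacts",
    "condition",
    "detect_r_peaks",
    "annotate_waves",
    "compute_rr",
    "hrv_windows",
    "match_peak_times",
]


def lowpass_filter(signal: SampledSignal, cutoff: float = 40.0, order: int = 4) -> SampledSignal:
    """Zero-phase Butterworth low-pass.

    The filter is applied forward-backward, which squares the single-pass
    magnitude response; the design cutoff is pre-warped so the *combined*
    response is -3 dB at ``cutoff`` and the passband (<= cutoff/2) stays
    within a fraction of a percent of unity. DC gain is exactly 1.
    """
    if not (0 < cutoff < signal.fs / 2):
        raise InvalidParameterError(
            f"cutoff must lie in (0, Nyquist={signal.fs / 2} Hz), got {cutoff}"
        )
    # Per-pass |H|^2 = 1/(1+(f/fc)^(2n)); solve for fc so that the two-pass
    # response is 1/2 at the nominal cutoff.
    fc = cutoff / (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
    fc = min(fc, 0.99 * signal.fs / 2)
    sos = scipy.signal.butter(order, fc, btype="lowpass", fs=signal.fs, output="sos")
    return signal.copy_with(scipy.signal.sosfiltfilt(sos, signal.samples))


def _window_samples(signal: SampledSignal, window_ms: float, minimum: int = 3) -> int:
    w = int(round(window_ms * signal.fs / 1000.0))
    if w < minimum:
        raise InvalidParameterError(
            f"window of {window_ms} ms spans only {w} samples at fs={signal.fs} Hz "
            f"(need >= {minimum})"
        )
    return w | 1  # odd length so the median is centered


def remove_baseline_median(signal: SampledSignal, window_ms: float = 600.0) -> SampledSignal:
    """Subtract a sliding-window median (reflect-padded at the edges).

    A window of 600 ms is longer than any QRS complex but much shorter than
    a respiration-rate wander period, so the median tracks the drifting
    baseline and leaves the beats intact. A pure slow ramp maps to ~0 away
    from the edges; a constant maps to exactly 0.
    """
    w = _window_samples(signal, window_ms)
    baseline = scipy.ndimage.median_filter(signal.samples, size=w, mode="reflect")
    return signal.copy_with(signal.samples - baseline)


def suppress_artifacts(
    signal: SampledSignal,
    k_mad: float = 8.0,
    window_ms: float = 2000.0,
    floor_quantile: float = 0.995,
    floor_factor: float = 1.5,
    dilate_ms: float = 30.0,
) -> SampledSignal:
    """Replace motion-artifact samples by linear interpolation of neighbors.

    A sample is flagged when its absolute deviation from the running median
    exceeds ``max(k_mad * running MAD, floor_factor * q)``, where *q* is the
    ``floor_quantile`` quantile of all absolute deviations. The floor keeps
    the largest legitimate deflections (the R waves) below threshold on a
    clean trace. Flagged regions are dilated by ``dilate_ms`` so artifact
    shoulders are removed together with their cores. A constant signal (MAD
    identically zero, all deviations zero) passes through unchanged.
    """
    if len(signal) < 3:
        return signal.copy_with(signal.samples.copy())
    x = signal.samples
    w = _window_samples(signal, window_ms)
    run_med = scipy.ndimage.median_filter(x, size=w, mode="reflect")
    dev = np.abs(x - run_med)
    run_mad = scipy.ndimage.median_filter(dev, size=w, mode="reflect")
    floor = floor_factor * float(np.quantile(dev, floor_quantile))
    thresh = np.maximum(k_mad * run_mad, floor)
    bad = dev > thresh
    if not np.any(bad):
        return signal.copy_with(x.copy())
    n_dilate = int(round(dilate_ms * signal.fs / 1000.0))
    if n_dilate > 0:
        bad = scipy.ndimage.binary_dilation(bad, iterations=n_dilate)
    good = ~bad
    if not np.any(good):  # pathological: everything flagged
        return signal.copy_with(x.copy())
    out = x.copy()
    idx = np.arange(x.size)
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return signal.copy_with(out)


def condition(
    signal: SampledSignal,
    cutoff: float = 40.0,
    baseline_window_ms: float = 600.0,
    artifact_filter: bool = True,
    k_mad: float = 8.0,
) -> SampledSignal:
    """Full conditioning chain: low-pass, baseline removal, artifact filter."""
    out = lowpass_filter(signal, cutoff=cutoff)
    out = remove_baseline_median(out, window_ms=baseline_window_ms)
    if artifact_filter:
        out = suppress_artifacts(out, k_mad=k_mad)
    return out


def detect_r_peaks(
    signal: SampledSignal,
    min_rr_ms: float = 300.0,
    chunk_s: float = 10.0,
    global_floor_frac: float = 0.25,
) -> RPeakSeries:
    """Detect R peaks on a conditioned ECG by the differential-threshold method.

    Candidate peaks are local maxima found where the first-order difference
    changes sign from positive to negative. Within each ``chunk_s``-second
    chunk, candidates below half of the chunk's maximum candidate amplitude
    are discarded (and below ``global_floor_frac`` of the global maximum, so
    beat-free noise chunks contribute nothing). Candidates closer than
    ``min_rr_ms`` are resolved in favor of the larger amplitude.

    Expects at least 2 s of signal.
    """
    if signal.duration_ms < 2000.0:
        raise InvalidInputError("need at least 2 s of ECG to detect R peaks")
    x = signal.samples
    d = np.diff(x)
    # sign change + -> - means x[i] is a local max (plateaus break rightward)
    cand = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    if cand.size == 0:
        return RPeakSeries(np.array([]), np.array([]), np.array([]), min_rr_ms=min_rr_ms)
    amps = x[cand]
    pos = amps > 0
    cand, amps = cand[pos], amps[pos]
    if cand.size == 0:
        return RPeakSeries(np.array([]), np.array([]), np.array([]), min_rr_ms=min_rr_ms)

    chunk_len = max(1, int(round(chunk_s * signal.fs)))
    chunk_of = cand // chunk_len
    global_max = float(amps.max())
    keep = np.zeros(cand.size, dtype=bool)
    for c in np.unique(chunk_of):
        m = chunk_of == c
        thr = max(0.5 * float(amps[m].max()), global_floor_frac * global_max)
        keep[m] = amps[m] >= thr
    cand, amps = cand[keep], amps[keep]

    # Singularity removal: enforce the refractory period, largest first.
    order = np.argsort(-amps, kind="stable")
    min_gap = min_rr_ms * signal.fs / 1000.0
    taken = np.zeros(cand.size, dtype=bool)
    sorted_accept: list[int] = []
    for j in order:
        i = cand[j]
        k = bisect.bisect_left(sorted_accept, i)
        ok = True
        if k > 0 and i - sorted_accept[k - 1] < min_gap:
            ok = False
        if k < len(sorted_accept) and sorted_accept[k] - i < min_gap:
            ok = False
        if ok:
            bisect.insort(sorted_accept, i)
            taken[j] = True
    idx = np.sort(cand[taken])
    times = signal.t0 + idx * (1000.0 / signal.fs)
    return RPeakSeries(
        peak_times=times, peak_indices=idx, peak_amplitudes=x[idx], min_rr_ms=min_rr_ms
    )


def annotate_waves(
    signal: SampledSignal,
    peaks: RPeakSeries,
    qs_search_ms: float = 80.0,
    p_search_ms: float = 200.0,
    t_search_ms: float = 400.0,
) -> list[dict]:
    """Mark P/Q/S/T wave times relative to each detected R peak.

    Q and S are the nearest local minima before/after R within a short
    window; P and T are the largest local maxima in fixed flanking search
    windows. Purely annotational — nothing downstream consumes this.
    """
    x = signal.samples
    fs = signal.fs
    out = []
    for i in peaks.peak_indices:
        beat = {"R": signal.t0 + i * 1000.0 / fs}
        n_qs = int(qs_search_ms * fs / 1000.0)
        lo = max(0, i - n_qs)
        if i > lo:
            beat["Q"] = signal.t0 + (lo + int(np.argmin(x[lo:i]))) * 1000.0 / fs
        hi = min(x.size, i + n_qs)
        if hi > i + 1:
            beat["S"] = signal.t0 + (i + 1 + int(np.argmin(x[i + 1 : hi]))) * 1000.0 / fs
        n_p = int(p_search_ms * fs / 1000.0)
        plo = max(0, i - n_p)
        q_idx = int((beat.get("Q", beat["R"]) - signal.t0) * fs / 1000.0)
        if q_idx > plo:
            beat["P"] = signal.t0 + (plo + int(np.argmax(x[plo:q_idx]))) * 1000.0 / fs
        n_t = int(t_search_ms * fs / 1000.0)
        s_idx = int((beat.get("S", beat["R"]) - signal.t0) * fs / 1000.0) + 1
        thi = min(x.size, i + n_t)
        if thi > s_idx:
            beat["T"] = signal.t0 + (s_idx + int(np.argmax(x[s_idx:thi]))) * 1000.0 / fs
        out.append(beat)
    return out


def compute_rr(peaks: RPeakSeries) -> RRSeries:
    """Successive R-R intervals; interval *i* is anchored at the later peak.

    The sum of the intervals telescopes to last-minus-first peak time.
    """
    if len(peaks) < 2:
        raise InsufficientDataError(f"need >= 2 peaks to form intervals, got {len(peaks)}")
    intervals = np.diff(peaks.peak_times)
    return RRSeries(intervals=intervals, anchor_times=peaks.peak_times[1:])


def hrv_windows(rr: RRSeries, k: int = 10) -> list[HRVWindowStat]:
    """Sliding-window (stride 1) HRV statistics over k consecutive intervals.

    ``variation`` is max - min within the window — the quantity the 10-beat
    fatigue rule thresholds at 5 ms; ``sdnn`` and ``rmssd`` are the standard
    time-domain measures.
    """
    if k < 2:
        raise InvalidParameterError(f"window size k must be >= 2, got {k}")
    x = rr.intervals
    if x.size < k:
        raise InsufficientDataError(f"need >= {k} intervals, got {x.size}")
    w = np.lib.stride_tricks.sliding_window_view(x, k)
    variation = w.max(axis=1) - w.min(axis=1)
    mean = w.mean(axis=1)
    sdnn = w.std(axis=1, ddof=1)
    rmssd = np.sqrt(np.mean(np.diff(w, axis=1) ** 2, axis=1))
    return [
        HRVWindowStat(
            window_size=k,
            start_index=i,
            anchor_time_ms=float(rr.anchor_times[i + k - 1]),
            variation=float(variation[i]),
            mean_rr=float(mean[i]),
            sdnn=float(sdnn[i]),
            rmssd=float(rmssd[i]),
        )
        for i in range(w.shape[0])
    ]


def match_peak_times(
    truth_times, detected_times, tol_ms: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true peak times.

    Returns ``(n_matched, n_truth, n_detected)``; recall = matched/truth,
    precision = matched/detected.
    """
    truth = np.asarray(truth_times, dtype=float)
    det = np.asarray(detected_times, dtype=float)
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in truth:
        lo = np.searchsorted(det, t - tol_ms)
        hi = np.searchsorted(det, t + tol_ms, side="right")
        best, best_d = -1, np.inf
        for j in range(lo, hi):
            if not used[j] and abs(det[j] - t) < best_d:
                best, best_d = j, abs(det[j] - t)
        if best >= 0:
            used[best] = True
            matched += 1
    return matched, truth.size, det.size
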