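"""Synthetic ECG / EMG generators with exact ground truth.

Every downstream stage of the pipeline is exercised against signals built
here, so the generators are first-class, tested code. They are surrogates,
not physiological models:

* ECG is a sum-of-Gaussians PQRST template laid down once per R-R interval,
  which makes the R-apex times analytically known.
* EMG is band-limited white noise (20-450 Hz) amplitude-modulated by a
  trapezoidal envelope per motion window, which makes the segment RMS
  controllable.
* The excited vs fatigue contrast is carried entirely by the R-R jitter:
  Gaussian jitter with SD 30 ms (excited) vs 1 ms (fatigue). Fatigue jitter
  is truncated at +/-2.4 ms so that the range of ANY 10 consecutive
  intervals stays below the 5 ms fatigue-rule threshold by construction;
  excited series are re-drawn locally until every 10-interval window has a
  range of at least 5 ms.

All randomness flows through one ``numpy.random.Generator`` derived from an
explicit seed; identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import InvalidParameterError
from .types import (
    MOTION_GROUP_OF,
    MOTION_LABELS,
    GroundTruth,
    MotionGroup,
    MotionWindow,
    NoiseSpec,
    SampledSignal,
    Status,
)

__all__ = [
    "DEFAULT_MEAN_RR",
    "DEFAULT_JITTER_SD",
    "EcgTemplate",
    "SessionSignals",
    "gen_rr_series",
    "gen_ecg",
    "gen_ecg_at_bpm",
    "gen_emg",
    "gen_session",
]

#: Default mean R-R interval (ms) per status: ~75 bpm excited, ~67 bpm fatigue.
DEFAULT_MEAN_RR = {Status.EXCITED: 800.0, Status.FATIGUE: 900.0}

#: Default R-R jitter SD (ms) per status.
DEFAULT_JITTER_SD = {Status.EXCITED: 30.0, Status.FATIGUE: 1.0}

#: Fatigue-rule threshold the generator must respect (ms over 10 intervals).
_RULE_EPSILON_MS = 5.0
_RULE_K = 10

# Truncation bound for fatigue jitter: range of clipped jitter <= 4.8 < 5 ms.
_FATIGUE_CLIP_MS = 2.4


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_rr_series(
    status: Status | str,
    n: int,
    mean_rr: float | None = None,
    seed: int | np.random.Generator | None = None,
    jitter_sd: float | None = None,
) -> np.ndarray:
    """Generate ``n`` R-R intervals (ms) for an excited or fatigued subject.

    Fatigue series are regular: the max-min over every 10 consecutive
    intervals is guaranteed below 5 ms. Excited series are irregular: every
    10-interval window has a range of at least 5 ms.

    Parameters
    ----------
    status:
        ``"excited"`` or ``"fatigue"``.
    n:
        Number of intervals (>= 2).
    mean_rr:
        Mean interval in ms, within [300, 2000]. Defaults to 800 ms
        (excited) / 900 ms (fatigue).
    seed:
        Integer seed or an existing Generator.
    jitter_sd:
        Gaussian jitter SD in ms; defaults to 30 (excited) / 1 (fatigue).
    """
    status = Status(status)
    if n < 2:
        raise InvalidParameterError(f"need at least 2 intervals, got n={n}")
    if mean_rr is None:
        mean_rr = DEFAULT_MEAN_RR[status]
    if not (300.0 <= mean_rr <= 2000.0):
        raise InvalidParameterError(f"mean_rr must lie in [300, 2000] ms, got {mean_rr}")
    if jitter_sd is None:
        jitter_sd = DEFAULT_JITTER_SD[status]
    if jitter_sd < 0:
        raise InvalidParameterError("jitter_sd must be >= 0")
    rng = _rng(seed)

    if status is Status.FATIGUE:
        jitter = rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n)
        # Rejection-resample tails so the 10-interval range invariant holds
        # by construction for any jitter_sd.
        clip = _FATIGUE_CLIP_MS
        bad = np.abs(jitter) > clip
        while np.any(bad):
            jitter[bad] = rng.normal(0.0, jitter_sd, size=int(bad.sum()))
            bad = np.abs(jitter) > clip
        rr = mean_rr + jitter
    else:
        rr = mean_rr + (rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n))
        # Re-draw any 10-interval window that came out too regular, so the
        # excited/fatigue contrast is unambiguous. With SD 30 ms this loop
        # almost never fires.
        if jitter_sd > 0 and n >= _RULE_K:
            for _ in range(1000):
                ranges = _sliding_range(rr, _RULE_K)
                bad = np.flatnonzero(ranges < _RULE_EPSILON_MS)
                if bad.size == 0:
                    break
                i = int(bad[0])
                rr[i : i + _RULE_K] = mean_rr + rng.normal(0.0, jitter_sd, size=_RULE_K)
    if np.any(rr <= 0):
        raise InvalidParameterError(
            "jitter_sd too large relative to mean_rr: produced non-positive interval"
        )
    return rr


def _sliding_range(x: np.ndarray, k: int) -> np.ndarray:
    """max - min over every window of k consecutive values (stride 1)."""
    w = np.lib.stride_tricks.sliding_window_view(np.asarray(x, dtype=float), k)
    return w.max(axis=1) - w.min(axis=1)


@dataclass
class EcgTemplate:
    """Sum-of-Gaussians PQRST beat template.

    Each wave is a Gaussian bump at a fixed offset (ms) from the R apex with
    a fixed width (sigma, ms) and amplitude (V). The R bump is the per-beat
    global maximum, so the apex time doubles as analytic ground truth. For
    short R-R intervals (< 600 ms) the P and T offsets are compressed
    proportionally so adjacent beats do not collide at high heart rates.
    """

    # wave: (offset_ms, sigma_ms, amplitude_V)
    p: tuple = (-160.0, 25.0, 0.15)
    q: tuple = (-25.0, 8.0, -0.10)
    r: tuple = (0.0, 12.0, 1.00)
    s: tuple = (25.0, 8.0, -0.20)
    t: tuple = (180.0, 60.0, 0.30)
    compress_below_ms: float = 600.0

    def render(self, t_ms: np.ndarray, r_time: float, rr_prev: float, rr_next: float) -> np.ndarray:
        out = np.zeros_like(t_ms)
        f_prev = min(1.0, rr_prev / self.compress_below_ms)
        f_next = min(1.0, rr_next / self.compress_below_ms)
        for off, sig, amp in (self.p, self.q, self.r, self.s, self.t):
            f = f_prev if off < 0 else f_next
            # QRS timing is left intact; only the slow P/T waves move.
            if abs(off) > 50.0:
                off = off * f
                sig = sig * max(f, 0.5)
            out += amp * np.exp(-0.5 * ((t_ms - (r_time + off)) / sig) ** 2)
        return out


def gen_ecg(
    rr_intervals,
    fs: float = 500.0,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator | None = None,
    template: EcgTemplate | None = None,
    t0: float = 0.0,
    lead_in_ms: float = 400.0,
    tail_ms: float = 500.0,
) -> tuple[SampledSignal, GroundTruth]:
    """Synthesize a single-lead ECG from an R-R interval series.

    One PQRST template is laid down per beat; ``len(rr) + 1`` beats total,
    so ``rr=[1000, 1000, 1000]`` yields four R apexes 1000 ms apart. The
    returned :class:`GroundTruth` stores the exact apex times.

    ``fs`` must be at least 200 Hz so the ~100 ms QRS complex is resolvable.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.ndim != 1 or rr.size < 1:
        raise InvalidParameterError("rr_intervals must be a non-empty 1-D sequence")
    if np.any(rr <= 0):
        raise InvalidParameterError("rr_intervals must be positive")
    if fs < 200.0:
        raise InvalidParameterError(f"fs must be >= 200 Hz to resolve the QRS, got {fs}")
    noise = noise or NoiseSpec.clean()
    template = template or EcgTemplate()
    rng = _rng(seed)

    r_times = t0 + lead_in_ms + np.concatenate(([0.0], np.cumsum(rr)))
    duration = lead_in_ms + float(np.sum(rr)) + tail_ms
    n_samples = int(round(duration * fs / 1000.0)) + 1
    t_ms = t0 + np.arange(n_samples) * (1000.0 / fs)

    clean = np.zeros(n_samples)
    rr_pad = np.concatenate(([rr[0]], rr, [rr[-1]]))  # prev/next interval per beat
    for i, r_time in enumerate(r_times):
        lo = np.searchsorted(t_ms, r_time - 450.0)
        hi = np.searchsorted(t_ms, r_time + 450.0)
        clean[lo:hi] += template.render(t_ms[lo:hi], r_time, rr_pad[i], rr_pad[i + 1])

    sig = clean + _render_noise(t_ms, fs, noise, rng)
    truth = GroundTruth(
        r_peak_times=list(r_times),
        rr_intervals=list(rr),
    )
    return SampledSignal(sig, fs=fs, t0=t0, channel="ECG"), truth


def _render_noise(t_ms: np.ndarray, fs: float, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(t_ms)
    t_s = t_ms / 1000.0
    if noise.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.baseline_wander_amp * np.sin(2 * np.pi * noise.baseline_wander_freq * t_s + phase)
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t_s + phase)
    if noise.white_noise_sd > 0:
        out += rng.normal(0.0, noise.white_noise_sd, size=t_ms.size)
    if noise.motion_artifact_rate > 0 and noise.motion_artifact_amp > 0:
        duration_min = (t_ms[-1] - t_ms[0]) / 60000.0
        n_events = rng.poisson(noise.motion_artifact_rate * duration_min)
        centers = rng.uniform(t_ms[0], t_ms[-1], size=n_events)
        signs = rng.choice([-1.0, 1.0], size=n_events)
        sig_ms = noise.motion_artifact_width_ms
        for c, s in zip(centers, signs):
            lo = np.searchsorted(t_ms, c - 5 * sig_ms)
            hi = np.searchsorted(t_ms, c + 5 * sig_ms)
            out[lo:hi] += s * noise.motion_artifact_amp * np.exp(
                -0.5 * ((t_ms[lo:hi] - c) / sig_ms) ** 2
            )
    return out


def _bandlimited_unit_noise(
    n: int, fs: float, rng: np.random.Generator, band=(20.0, 450.0)
) -> np.ndarray:
    """White noise band-passed to the surface-EMG band, normalized to unit RMS."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        raise InvalidParameterError(f"fs={fs} too low for EMG band {band}")
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = float(np.sqrt(np.mean(x**2)))
    return x / rms if rms > 0 else x


def _trapezoid(t_ms: np.ndarray, onset: float, offset: float, ramp_ms: float) -> np.ndarray:
    """Unit-height trapezoidal envelope over [onset, offset] with linear ramps."""
    up = np.clip((t_ms - onset) / ramp_ms, 0.0, 1.0)
    down = np.clip((offset - t_ms) / ramp_ms, 0.0, 1.0)
    return np.minimum(up, down)


def gen_emg(
    motions,
    fs: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    baseline_rms: float = 0.05,
    dominant_rms: float = 1.5,
    nondominant_rms: float = 0.8,
    ramp_frac: float = 0.1,
    tail_ms: float = 1000.0,
    peak_overrides=None,
) -> tuple[SampledSignal, SampledSignal, GroundTruth]:
    """Synthesize two-channel (FCR, ECRL) surface EMG for a motion sequence.

    Parameters
    ----------
    motions:
        List of ``(label, onset_ms, duration_ms)`` with labels from the
        four-motion set; windows must not overlap.
    baseline_rms, dominant_rms, nondominant_rms:
        Target RMS (V) of the resting envelope and of the dominant /
        non-dominant channel inside a motion window. During forearm
        pronation and finger flexion the FCR channel dominates; during hand
        closing and wrist extension the ECRL channel dominates.
    peak_overrides:
        Optional list aligned with ``motions`` of ``(fcr_peak, ecrl_peak)``
        tuples overriding the per-window envelope peaks (used by
        :func:`gen_session` to impose amplitude decay).
    """
    windows = []
    for label, onset, dur in motions:
        if label not in MOTION_LABELS:
            raise InvalidParameterError(f"unknown motion label {label!r}")
        if dur <= 0:
            raise InvalidParameterError("motion duration must be positive")
        windows.append(MotionWindow(onset_ms=float(onset), offset_ms=float(onset + dur), label=label))
    order = sorted(range(len(windows)), key=lambda i: windows[i].onset_ms)
    for a, b in zip(order, order[1:]):
        if windows[b].onset_ms < windows[a].offset_ms:
            raise InvalidParameterError(
                f"motion windows overlap: {windows[a].label} and {windows[b].label}"
            )
    rng = _rng(seed)

    end_ms = max((w.offset_ms for w in windows), default=1000.0) + tail_ms
    n = int(round(end_ms * fs / 1000.0)) + 1
    t_ms = np.arange(n) * (1000.0 / fs)

    env = {"FCR": np.full(n, baseline_rms), "ECRL": np.full(n, baseline_rms)}
    for j, w in enumerate(windows):
        if peak_overrides is not None:
            fcr_peak, ecrl_peak = peak_overrides[j]
        elif w.group is MotionGroup.FCR_DOMINANT:
            fcr_peak, ecrl_peak = dominant_rms, nondominant_rms
        else:
            fcr_peak, ecrl_peak = nondominant_rms, dominant_rms
        ramp = ramp_frac * (w.offset_ms - w.onset_ms)
        shape = _trapezoid(t_ms, w.onset_ms, w.offset_ms, ramp)
        env["FCR"] = np.maximum(env["FCR"], baseline_rms + (fcr_peak - baseline_rms) * shape)
        env["ECRL"] = np.maximum(env["ECRL"], baseline_rms + (ecrl_peak - baseline_rms) * shape)

    fcr = SampledSignal(_bandlimited_unit_noise(n, fs, rng) * env["FCR"], fs=fs, channel="FCR")
    ecrl = SampledSignal(_bandlimited_unit_noise(n, fs, rng) * env["ECRL"], fs=fs, channel="ECRL")
    truth = GroundTruth(motion_windows=sorted(windows, key=lambda w: w.onset_ms))
    return fcr, ecrl, truth


def gen_ecg_at_bpm(
    bpm: float,
    duration_min: float,
    fs: float = 500.0,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator | None = None,
    jitter_sd: float = 15.0,
    min_interval_ms: float = 306.0,
) -> tuple[SampledSignal, GroundTruth]:
    """ECG at a given heart rate for a given duration.

    Convenience wrapper around :func:`gen_rr_series` + :func:`gen_ecg`.
    Intervals are floored at ``min_interval_ms`` (just above the R-peak
    detector's default 300 ms refractory period) so that at the highest
    heart rates the jitter cannot create beats the detector is, by design,
    forbidden to report.
    """
    if not (30.0 <= bpm <= 196.0):
        raise InvalidParameterError(f"bpm must lie in [30, 196], got {bpm}")
    rng = _rng(seed)
    mean_rr = 60000.0 / bpm
    n = max(2, int(np.ceil(duration_min * 60000.0 / mean_rr)))
    rr = gen_rr_series(Status.EXCITED, n=n, mean_rr=mean_rr, seed=rng, jitter_sd=jitter_sd)
    rr = np.maximum(rr, min_interval_ms)
    return gen_ecg(rr, fs=fs, noise=noise, seed=rng)


@dataclass
class SessionSignals:
    """One simulated training session: ECG plus two-channel EMG with truth."""

    ecg: SampledSignal
    fcr: SampledSignal
    ecrl: SampledSignal
    truth: GroundTruth
    envelope_peaks: list = field(default_factory=list)  # (onset_ms, fcr_peak, ecrl_peak)


def gen_session(
    status: Status | str,
    duration_min: float,
    decay: float = 0.0,
    seed: int | np.random.Generator | None = None,
    fs_ecg: float = 500.0,
    fs_emg: float = 1000.0,
    noise: NoiseSpec | None = None,
    burst_ms: float = 2000.0,
    rest_ms: float = 3000.0,
) -> SessionSignals:
    """Simulate a training session: repeated hand-motion bouts plus ECG.

    The four motions cycle in a fixed order, one 2 s burst every 5 s. The
    EMG envelope peak decays multiplicatively at ``decay`` per hour, i.e.
    a burst at elapsed time *t* has peak ``peak0 * (1 - decay) ** (t / 1 h)``,
    emulating the intensity drop observed over a long training session.
    Initial envelope peaks are 2.0 V (dominant) / 1.6 V (non-dominant) for
    an excited subject and 1.8 / 1.5 V for a fatigued one, matching the
    first-minute intensities of a representative session. ``truth`` stores
    per-minute ("bout") mean envelope peaks per channel.
    """
    status = Status(status)
    if duration_min < 1:
        raise InvalidParameterError("duration must be at least 1 minute")
    if not (0.0 <= decay < 1.0):
        raise InvalidParameterError("decay must lie in [0, 1) per hour")
    rng = _rng(seed)

    # --- ECG: enough beats to cover the session ---
    mean_rr = DEFAULT_MEAN_RR[status]
    n_beats = int(np.ceil(duration_min * 60000.0 / mean_rr)) + 2
    rr = gen_rr_series(status, n=n_beats, mean_rr=mean_rr, seed=rng)
    ecg, ecg_truth = gen_ecg(rr, fs=fs_ecg, noise=noise, seed=rng)

    # --- EMG: cycling motion bouts with decaying envelope ---
    dominant0, nondominant0 = (2.0, 1.6) if status is Status.EXCITED else (1.8, 1.5)
    period = burst_ms + rest_ms
    total_ms = duration_min * 60000.0
    motions, overrides = [], []
    k = 0
    onset = rest_ms / 2.0
    while onset + burst_ms <= total_ms:
        label = MOTION_LABELS[k % len(MOTION_LABELS)]
        scale = (1.0 - decay) ** (onset / 3_600_000.0)
        dom, non = dominant0 * scale, nondominant0 * scale
        if MOTION_GROUP_OF[label] is MotionGroup.FCR_DOMINANT:
            overrides.append((dom, non))
        else:
            overrides.append((non, dom))
        motions.append((label, onset, burst_ms))
        k += 1
        onset += period
    fcr, ecrl, emg_truth = gen_emg(
        motions, fs=fs_emg, seed=rng, peak_overrides=overrides, tail_ms=500.0
    )

    # Per-minute bout means of the envelope peaks.
    bout_means: dict[str, list[float]] = {"FCR": [], "ECRL": []}
    for minute in range(int(np.ceil(duration_min))):
        lo, hi = minute * 60000.0, (minute + 1) * 60000.0
        idx = [j for j, (_, o, _) in enumerate(motions) if lo <= o < hi]
        if idx:
            bout_means["FCR"].append(float(np.mean([overrides[j][0] for j in idx])))
            bout_means["ECRL"].append(float(np.mean([overrides[j][1] for j in idx])))
        else:
            bout_means["FCR"].append(float("nan"))
            bout_means["ECRL"].append(float("nan"))

    truth = GroundTruth(
        r_peak_times=ecg_truth.r_peak_times,
        rr_intervals=ecg_truth.rr_intervals,
        status=status,
        motion_windows=emg_truth.motion_windows,
        bout_means=bout_means,
    )
    peaks = [(m[1], o[0], o[1]) for m, o in zip(motions, overrides)]
    return SessionSignals(ecg=ecg, fcr=fcr, ecrl=ecrl, truth=truth, envelope_peaks=peaks)
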