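"""Surface-EMG RMS features, normalization, activity segmentation and
two-channel motion-group discrimination.

The activity-intensity feature is the segment RMS,

    RMS = sqrt( (1/N) * sum_i v_i^2 ),        N = 200 samples per segment,

computed over consecutive non-overlapping segments. Raw RMS has no common
baseline across individuals, so it is normalized against a benchmark
maximum RMS_M obtained from three maximal-effort calibration trials
(RMS_N = RMS / RMS_M). Activity events are maximal runs of supra-threshold
normalized RMS; events are assigned to a dominance group from the two
forearm channels: FCR > ECRL during forearm pronation and finger flexion,
ECRL > FCR during hand closing and wrist extension. Normalized values near
1 may sit in the sensor's saturation regime where RMS no longer tracks
intensity, so events are annotated as possibly saturated above 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidCalibrationError,
    InvalidInputError,
    InvalidParameterError,
    NoActivityError,
)
from .types import MotionGroup, SampledSignal

__all__ = [
    "EMGFeatureSeries",
    "CalibrationRecord",
    "MotionEvent",
    "rectify",
    "rms_segments",
    "calibrate_rms_max",
    "normalize",
    "segment_activity",
    "classify_motion",
    "detect_motion_events",
]

#: Normalized RMS above which the amplitude may be saturated.
SATURATION_LEVEL = 0.95


@dataclass
class EMGFeatureSeries:
    """Per-segment RMS features for one channel.

    ``rms`` is in volts; ``rms_normalized`` (dimensionless, present after
    :func:`normalize`) may exceed 1 when activity surpasses the calibration
    maximum. ``segment_ms`` is the duration of one N-sample segment.
    """

    channel: str
    n_per_segment: int
    fs: float
    segment_start_ms: np.ndarray
    rms: np.ndarray
    rms_normalized: np.ndarray | None = None
    rms_m: float | None = None

    def __post_init__(self):
        self.segment_start_ms = np.asarray(self.segment_start_ms, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if np.any(self.rms < 0):
            raise InvalidInputError("RMS values must be nonnegative")
        if self.n_per_segment < 1:
            raise InvalidParameterError("segment length N must be >= 1")
        if self.rms_normalized is not None:
            self.rms_normalized = np.asarray(self.rms_normalized, dtype=float)

    def __len__(self) -> int:
        return self.rms.size

    @property
    def segment_ms(self) -> float:
        return self.n_per_segment * 1000.0 / self.fs


@dataclass
class CalibrationRecord:
    """Benchmark maximum RMS for one channel.

    ``trial_rms`` holds the maximum segment RMS of each maximal-effort
    trial; ``rms_m`` is their arithmetic mean.
    """

    channel: str
    trial_rms: list[float]
    rms_m: float

    def __post_init__(self):
        if not self.trial_rms or any(v <= 0 for v in self.trial_rms):
            raise InvalidCalibrationError("trial RMS values must be positive")
        if not np.isclose(self.rms_m, float(np.mean(self.trial_rms))):
            raise InvalidCalibrationError("rms_m must equal the mean of the trial maxima")


@dataclass
class MotionEvent:
    """One detected activity event with its dominance-group assignment."""

    onset_ms: float
    offset_ms: float
    dominant_channel: str | None
    motion_group: MotionGroup
    peak_rms_n_fcr: float
    peak_rms_n_ecrl: float
    possibly_saturated: bool = False
    label: str | None = None  # per-motion label, only ever set from ground truth

    def __post_init__(self):
        if not (self.offset_ms > self.onset_ms):
            raise InvalidInputError("event offset must exceed onset")


def rectify(signal: SampledSignal) -> SampledSignal:
    """Full-wave rectification: absolute value of every sample."""
    return signal.copy_with(np.abs(signal.samples))


def rms_segments(signal: SampledSignal, n: int = 200) -> EMGFeatureSeries:
    """Segment RMS over consecutive non-overlapping N-sample segments.

    The trailing remainder (< N samples) is dropped. Requires at least one
    full segment.
    """
    if n < 1:
        raise InvalidParameterError("segment length N must be >= 1")
    x = signal.samples
    if x.size < n:
        raise InsufficientDataError(f"need >= {n} samples for one segment, got {x.size}")
    n_seg = x.size // n
    seg = x[: n_seg * n].reshape(n_seg, n)
    rms = np.sqrt(np.mean(seg * seg, axis=1))
    starts = signal.t0 + np.arange(n_seg) * n * (1000.0 / signal.fs)
    return EMGFeatureSeries(
        channel=signal.channel,
        n_per_segment=n,
        fs=signal.fs,
        segment_start_ms=starts,
        rms=rms,
    )


def calibrate_rms_max(trials: list[SampledSignal], n: int = 200) -> CalibrationRecord:
    """Benchmark RMS_M from maximal-effort trials.

    For each trial the maximum segment RMS is taken; RMS_M is the mean of
    the trial maxima. Three trials are customary (to average out effort
    variability) but any positive number is accepted.
    """
    if not trials:
        raise InvalidInputError("need at least one calibration trial")
    channels = {t.channel for t in trials}
    if len(channels) != 1:
        raise InvalidInputError(f"calibration trials mix channels: {sorted(channels)}")
    maxima = [float(rms_segments(t, n=n).rms.max()) for t in trials]
    return CalibrationRecord(
        channel=channels.pop(), trial_rms=maxima, rms_m=float(np.mean(maxima))
    )


def normalize(series: EMGFeatureSeries, cal: CalibrationRecord) -> EMGFeatureSeries:
    """Normalized RMS: RMS_N = RMS / RMS_M. Values above 1 are legal."""
    if cal.rms_m <= 0:
        raise InvalidCalibrationError("benchmark RMS_M must be positive")
    if cal.channel != series.channel:
        raise InvalidInputError(
            f"calibration channel {cal.channel} != series channel {series.channel}"
        )
    return EMGFeatureSeries(
        channel=series.channel,
        n_per_segment=series.n_per_segment,
        fs=series.fs,
        segment_start_ms=series.segment_start_ms,
        rms=series.rms,
        rms_normalized=series.rms / cal.rms_m,
        rms_m=cal.rms_m,
    )


def segment_activity(
    series: EMGFeatureSeries,
    threshold: float = 0.2,
    min_duration_segments: int = 3,
    merge_gap_segments: int = 2,
) -> list[tuple[float, float]]:
    """Activity windows from a normalized RMS series.

    Returns maximal runs of segments with ``rms_normalized >= threshold``
    lasting at least ``min_duration_segments``; runs separated by fewer
    than ``merge_gap_segments`` sub-threshold segments are merged first.
    Onset/offset are in ms (offset is the end of the last active segment).
    """
    if series.rms_normalized is None:
        raise InvalidInputError("series must be normalized before segmentation")
    active = series.rms_normalized >= threshold
    runs = _runs(active)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap_segments:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    seg_ms = series.segment_ms
    out = []
    for s, e in merged:
        if e - s >= min_duration_segments:
            out.append(
                (float(series.segment_start_ms[s]), float(series.segment_start_ms[e - 1] + seg_ms))
            )
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def classify_motion(
    fcr_event_rms: float,
    ecrl_event_rms: float,
    activity_threshold: float = 0.2,
) -> MotionGroup:
    """Assign an event to a dominance group from its two channel intensities.

    FCR > ECRL maps to the flexor-dominant motions (forearm pronation,
    finger flexion); ECRL > FCR to the extensor-dominant ones (hand
    closing, wrist extension). An exact tie is reported as
    :data:`MotionGroup.INDETERMINATE` rather than an error; activity below
    threshold on both channels is an error.
    """
    if fcr_event_rms < 0 or ecrl_event_rms < 0:
        raise InvalidInputError("event RMS values must be nonnegative")
    if fcr_event_rms < activity_threshold and ecrl_event_rms < activity_threshold:
        raise NoActivityError("both channels below the activity threshold")
    if fcr_event_rms > ecrl_event_rms:
        return MotionGroup.FCR_DOMINANT
    if ecrl_event_rms > fcr_event_rms:
        return MotionGroup.ECRL_DOMINANT
    return MotionGroup.INDETERMINATE


def detect_motion_events(
    fcr: EMGFeatureSeries,
    ecrl: EMGFeatureSeries,
    threshold: float = 0.2,
    min_duration_segments: int = 3,
) -> list[MotionEvent]:
    """Joint two-channel event detection and dominance classification.

    Segmentation runs on the elementwise maximum of the two normalized RMS
    series (either muscle can announce activity); each event is then
    classified from its per-channel peak normalized RMS.
    """
    for s in (fcr, ecrl):
        if s.rms_normalized is None:
            raise InvalidInputError("both series must be normalized")
    if len(fcr) != len(ecrl):
        raise InvalidInputError("channel series must have equal segment counts")
    combined = EMGFeatureSeries(
        channel=fcr.channel,
        n_per_segment=fcr.n_per_segment,
        fs=fcr.fs,
        segment_start_ms=fcr.segment_start_ms,
        rms=np.maximum(fcr.rms, ecrl.rms),
        rms_normalized=np.maximum(fcr.rms_normalized, ecrl.rms_normalized),
    )
    windows = segment_activity(
        combined, threshold=threshold, min_duration_segments=min_duration_segments
    )
    events = []
    for onset, offset in windows:
        m = (combined.segment_start_ms >= onset) & (combined.segment_start_ms < offset)
        pf = float(fcr.rms_normalized[m].max())
        pe = float(ecrl.rms_normalized[m].max())
        group = classify_motion(pf, pe, activity_threshold=threshold)
        dom = {"fcr_dominant": "FCR", "ecrl_dominant": "ECRL"}.get(group.value)
        events.append(
            MotionEvent(
                onset_ms=onset,
                offset_ms=offset,
                dominant_channel=dom,
                motion_group=group,
                peak_rms_n_fcr=pf,
                peak_rms_n_ecrl=pe,
                possibly_saturated=max(pf, pe) > SATURATION_LEVEL,
            )
        )
    return events
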