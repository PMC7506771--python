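"""Core domain containers shared by every pipeline stage.

Signals are plain uniformly-sampled voltage traces; everything downstream
(R peaks, R-R intervals, HRV statistics, EMG features, motion events) is a
small dataclass with explicit units. Times are milliseconds throughout,
voltages are volts, sampling rates are hertz.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Channel",
    "Status",
    "MotionGroup",
    "MOTION_LABELS",
    "MOTION_GROUP_OF",
    "SampledSignal",
    "MotionWindow",
    "GroundTruth",
    "NoiseSpec",
    "RPeakSeries",
    "RRSeries",
    "HRVWindowStat",
]


class Channel(str, enum.Enum):
    """Recording channel: the single ECG lead or one of the two forearm EMG sites."""

    ECG = "ECG"
    FCR = "FCR"  # flexor carpi radialis
    ECRL = "ECRL"  # extensor carpi radialis longus


class Status(str, enum.Enum):
    """Two-class physiological state used throughout: excited vs fatigue."""

    EXCITED = "excited"
    FATIGUE = "fatigue"


class MotionGroup(str, enum.Enum):
    """Dominance group a two-channel EMG event can be assigned to.

    Two forearm channels cannot separate all four trained hand motions; they
    separate the flexor-dominant pair from the extensor-dominant pair, with an
    explicit indeterminate value for exact ties.
    """

    FCR_DOMINANT = "fcr_dominant"  # forearm pronation, finger flexion
    ECRL_DOMINANT = "ecrl_dominant"  # hand closing, wrist extension
    INDETERMINATE = "indeterminate"


#: The four trained hand motions.
MOTION_LABELS = (
    "hand_closing",
    "forearm_pronation",
    "finger_flexion",
    "wrist_extension",
)

#: Which channel dominates during each motion.
MOTION_GROUP_OF = {
    "forearm_pronation": MotionGroup.FCR_DOMINANT,
    "finger_flexion": MotionGroup.FCR_DOMINANT,
    "hand_closing": MotionGroup.ECRL_DOMINANT,
    "wrist_extension": MotionGroup.ECRL_DOMINANT,
}


@dataclass
class SampledSignal:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples:
        Voltage values in volts.
    fs:
        Sampling rate in Hz (> 0).
    t0:
        Time of the first sample in milliseconds.
    channel:
        Channel label; one of ``"ECG"``, ``"FCR"``, ``"ECRL"``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel: str = "ECG"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidInputError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        self.channel = Channel(self.channel).value

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds."""
        return self.t0 + np.arange(self.samples.size) * (1000.0 / self.fs)

    @property
    def duration_ms(self) -> float:
        return (self.samples.size - 1) * 1000.0 / self.fs

    def copy_with(self, samples: np.ndarray) -> "SampledSignal":
        """New signal with the same clock/channel but different samples."""
        return SampledSignal(samples=samples, fs=self.fs, t0=self.t0, channel=self.channel)


@dataclass
class MotionWindow:
    """Ground-truth activity window: [onset, offset) in ms with a motion label."""

    onset_ms: float
    offset_ms: float
    label: str

    def __post_init__(self):
        if self.label not in MOTION_LABELS:
            raise InvalidParameterError(f"unknown motion label {self.label!r}")
        if not (self.offset_ms > self.onset_ms):
            raise InvalidParameterError("motion window offset must exceed onset")

    @property
    def group(self) -> MotionGroup:
        return MOTION_GROUP_OF[self.label]


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic signal, for testing and scoring."""

    r_peak_times: list[float] = field(default_factory=list)
    rr_intervals: list[float] = field(default_factory=list)
    status: Status | None = None
    motion_windows: list[MotionWindow] = field(default_factory=list)
    bout_means: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.r_peak_times, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidInputError("r_peak_times must be strictly increasing")
        rr = np.asarray(self.rr_intervals, dtype=float)
        if rr.size and not np.all(rr > 0):
            raise InvalidInputError("rr_intervals must be positive")


@dataclass
class NoiseSpec:
    """Additive noise model for synthetic ECG.

    Components: sinusoidal baseline wander (respiration/electrode drift),
    50 Hz powerline pickup, randomly timed motion-artifact bumps, and white
    sensor noise. All amplitudes in volts.
    """

    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.3
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    motion_artifact_rate: float = 0.0  # events per minute
    motion_artifact_amp: float = 0.0
    motion_artifact_width_ms: float = 15.0  # Gaussian sigma of one bump
    white_noise_sd: float = 0.0

    def __post_init__(self):
        for name in (
            "baseline_wander_amp",
            "powerline_amp",
            "motion_artifact_rate",
            "motion_artifact_amp",
            "white_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def clean(cls) -> "NoiseSpec":
        """No noise at all."""
        return cls()

    @classmethod
    def ambulatory(cls) -> "NoiseSpec":
        """Noise preset for a moving subject: wander, mains pickup, motion
        artifacts and sensor noise at levels typical of dry-contact wearables."""
        return cls(
            baseline_wander_amp=0.15,
            baseline_wander_freq=0.3,
            powerline_amp=0.02,
            motion_artifact_rate=4.0,
            motion_artifact_amp=2.0,
            motion_artifact_width_ms=15.0,
            white_noise_sd=0.02,
        )


@dataclass
class RPeakSeries:
    """Detected R peaks: times (ms), sample indices and amplitudes (V)."""

    peak_times: np.ndarray
    peak_indices: np.ndarray
    peak_amplitudes: np.ndarray
    min_rr_ms: float = 300.0

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if not (len(self.peak_times) == len(self.peak_indices) == len(self.peak_amplitudes)):
            raise InvalidInputError("peak arrays must have equal length")
        gaps = np.diff(self.peak_times)
        if gaps.size and not np.all(gaps > 0):
            raise InvalidInputError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_times.size


@dataclass
class RRSeries:
    """Successive R-R intervals (ms). ``anchor_times`` holds the time of the
    later peak of each pair, so interval *i* "happens" at ``anchor_times[i]``."""

    intervals: np.ndarray
    anchor_times: np.ndarray

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        if self.intervals.size != self.anchor_times.size:
            raise InvalidInputError("intervals and anchor_times must have equal length")
        if self.intervals.size and not np.all(self.intervals > 0):
            raise InvalidInputError("R-R intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class HRVWindowStat:
    """Statistics of one sliding window of k consecutive R-R intervals.

    ``variation`` is the windowed max - min (ms): the quantity the 10-beat
    fatigue rule thresholds. ``sdnn`` is the sample SD and ``rmssd`` the RMS
    of successive differences, the two classical short-term HRV measures.
    """

    window_size: int
    start_index: int
    anchor_time_ms: float
    variation: float
    mean_rr: float
    sdnn: float
    rmssd: float

    def __post_init__(self):
        if self.variation < 0 or self.sdnn < 0 or self.rmssd < 0:
            raise InvalidInputError("HRV statistics must be nonnegative")
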