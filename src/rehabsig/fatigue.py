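"""Excited-vs-fatigue state detection from R-R interval variability.

Two detectors are provided:

* **Rule** — the 10-beat criterion: a subject is flagged as fatigued as
  soon as the variation (max - min) of 10 consecutive R-R intervals falls
  below 5 ms. Regular heartbeat = drowsy/fatigued; irregular = excited.
* **SVM** — a linear support-vector machine on windowed time-domain HRV
  features (mean R-R, SDNN, RMSSD, variation), standardized with scaling
  statistics from a per-individual learning phase at the start of a
  session. When no explicit labels are available for the learning phase,
  the rule detector bootstraps them.

The SVM's feature scaling is part of the persisted model, so a model
trained on one person's learning phase carries that person's calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    InvalidTrainingSetError,
)
from .types import HRVWindowStat, RRSeries, Status

__all__ = [
    "FEATURE_NAMES",
    "FatigueRuleParams",
    "SvmModel",
    "ClassificationResult",
    "rule_fatigue",
    "extract_features",
    "train_svm",
    "classify_status",
]

#: Column order of the HRV feature matrix.
FEATURE_NAMES = ("mean_rr", "sdnn", "rmssd", "variation")


@dataclass
class FatigueRuleParams:
    """Parameters of the consecutive-beat fatigue rule.

    ``k`` consecutive R-R intervals with a max-min spread below ``epsilon``
    milliseconds flag fatigue. Defaults: k = 10 beats, epsilon = 5 ms.
    """

    k: int = 10
    epsilon_ms: float = 5.0

    def __post_init__(self):
        if self.k < 2:
            raise InvalidParameterError("k must be >= 2")
        if self.epsilon_ms <= 0:
            raise InvalidParameterError("epsilon must be positive")


def rule_fatigue(
    stats: list[HRVWindowStat], params: FatigueRuleParams | None = None
) -> tuple[bool, int | None]:
    """Apply the consecutive-beat rule to windowed HRV statistics.

    Returns ``(flag, first_trigger_index)``: the flag is True iff any
    window's variation is below ``params.epsilon_ms``, and the index is the
    earliest such window (None when the rule never fires). The stats must
    have been computed with ``window_size == params.k``.
    """
    params = params or FatigueRuleParams()
    for s in stats:
        if s.window_size != params.k:
            raise InvalidParameterError(
                f"stats window size {s.window_size} != rule k {params.k}"
            )
    for i, s in enumerate(stats):
        if s.variation < params.epsilon_ms:
            return True, i
    return False, None


def extract_features(rr: RRSeries, window: int = 10, stride: int = 5) -> np.ndarray:
    """Windowed HRV feature matrix for the SVM.

    Rows are strided windows of ``window`` consecutive intervals; columns
    are ``(mean_rr, sdnn, rmssd, variation)``. Row count is
    ``floor((len - window) / stride) + 1``.
    """
    if window < 2 or stride < 1:
        raise InvalidParameterError("window must be >= 2 and stride >= 1")
    x = rr.intervals
    if x.size < window:
        raise InsufficientDataError(f"need >= {window} intervals, got {x.size}")
    starts = np.arange(0, x.size - window + 1, stride)
    rows = np.empty((starts.size, 4))
    for r, s in enumerate(starts):
        w = x[s : s + window]
        rows[r] = (
            w.mean(),
            w.std(ddof=1),
            np.sqrt(np.mean(np.diff(w) ** 2)),
            w.max() - w.min(),
        )
    return rows


@dataclass
class SvmModel:
    """A trained linear SVM plus its learning-phase standardization.

    ``scale_mean``/``scale_sd`` standardize features before the decision
    function ``w . z + b``; positive decision values mean fatigue.
    """

    weights: np.ndarray
    bias: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    kernel: str = "linear"
    feature_names: tuple = FEATURE_NAMES
    learning_windows: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.scale_mean = np.asarray(self.scale_mean, dtype=float)
        self.scale_sd = np.asarray(self.scale_sd, dtype=float)
        if np.any(self.scale_sd <= 0):
            raise InvalidInputError("feature scaling SDs must be positive")

    @property
    def n_features(self) -> int:
        return self.weights.size

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=float))
        if f.shape[1] != self.n_features:
            raise InvalidInputError(
                f"feature dimension {f.shape[1]} != model dimension {self.n_features}"
            )
        z = (f - self.scale_mean) / self.scale_sd
        return z @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> list[Status]:
        return [Status.FATIGUE if d > 0 else Status.EXCITED for d in self.decision_values(features)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": self.kernel,
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "scale_mean": self.scale_mean.tolist(),
                "scale_sd": self.scale_sd.tolist(),
                "feature_names": list(self.feature_names),
                "learning_windows": self.learning_windows,
                "metadata": self.metadata,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SvmModel":
        d = json.loads(text)
        return cls(
            weights=d["weights"],
            bias=d["bias"],
            scale_mean=d["scale_mean"],
            scale_sd=d["scale_sd"],
            kernel=d.get("kernel", "linear"),
            feature_names=tuple(d.get("feature_names", FEATURE_NAMES)),
            learning_windows=d.get("learning_windows", 0),
            metadata=d.get("metadata", {}),
        )


def train_svm(
    features: np.ndarray,
    labels,
    C: float = 10.0,
    sd_floor: float = 1e-12,
) -> SvmModel:
    """Train a linear SVM on standardized HRV features.

    ``labels`` is a sequence of :class:`Status` (or their string values)
    matching the feature rows; both classes must be present. The feature
    standardization (mean/SD of the training windows — the learning phase)
    is stored in the returned model. Degenerate constant features get an SD
    floor so the decision function stays defined.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.array([1 if Status(l) is Status.FATIGUE else -1 for l in labels])
    if f.shape[0] != y.size:
        raise InvalidInputError("feature rows and labels must align")
    if len(np.unique(y)) < 2:
        raise InvalidTrainingSetError("training set must contain both classes")
    mean = f.mean(axis=0)
    sd = f.std(axis=0, ddof=0)
    sd = np.maximum(sd, sd_floor)
    z = (f - mean) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(z, y)
    return SvmModel(
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        scale_mean=mean,
        scale_sd=sd,
        learning_windows=f.shape[0],
        metadata={"C": C, "n_support": clf.n_support_.tolist()},
    )


@dataclass
class ClassificationResult:
    """Per-window status labels with decision values and alert events.

    ``alerts`` holds the window indices of excited-to-fatigue transitions
    in the smoothed label stream (the moments the system would notify the
    user to ease off).
    """

    labels: list[Status]
    decision_values: np.ndarray
    alerts: list[int]

    def __len__(self) -> int:
        return len(self.labels)


def classify_status(
    model: SvmModel, features: np.ndarray, smoothing: int = 3
) -> ClassificationResult:
    """Classify each feature window and majority-smooth the label stream.

    Each label is replaced by the majority vote over the trailing
    ``smoothing`` raw labels (fewer at the start), which suppresses
    single-window flapping. An alert is emitted at every excited-to-fatigue
    transition of the smoothed stream, including a fatigued first window.
    """
    if smoothing < 1:
        raise InvalidParameterError("smoothing must be >= 1")
    dv = model.decision_values(features)
    raw = dv > 0  # True = fatigue
    smoothed: list[bool] = []
    for i in range(raw.size):
        lo = max(0, i - smoothing + 1)
        votes = raw[lo : i + 1]
        smoothed.append(int(votes.sum()) * 2 > votes.size)
    labels = [Status.FATIGUE if s else Status.EXCITED for s in smoothed]
    alerts = [
        i
        for i, s in enumerate(smoothed)
        if s and (i == 0 or not smoothed[i - 1])
    ]
    return ClassificationResult(labels=labels, decision_values=dv, alerts=alerts)
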