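"""Exception hierarchy for the rehabsig pipeline.

Every stage raises a subclass of :class:`RehabSigError` so callers (and the
CLI) can distinguish user errors from bugs and attach the failing stage name.
"""


class RehabSigError(Exception):
    """Base class for all rehabsig errors."""


class InvalidParameterError(RehabSigError, ValueError):
    """A parameter is outside its documented range."""


class InvalidInputError(RehabSigError, ValueError):
    """An input object violates a precondition (wrong shape, too short, ...)."""


class InsufficientDataError(RehabSigError, ValueError):
    """Not enough samples / intervals / windows to compute the quantity."""


class InvalidTrainingSetError(RehabSigError, ValueError):
    """A training set is unusable (e.g. only one class present)."""


class InvalidCalibrationError(RehabSigError, ValueError):
    """A calibration record is unusable (e.g. non-positive benchmark RMS)."""


class NoActivityError(RehabSigError, ValueError):
    """Motion classification was requested on a segment without activity."""


class FormatError(RehabSigError, ValueError):
    """A file does not conform to the expected on-disk format.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConfigError(RehabSigError, ValueError):
    """A pipeline configuration document is invalid."""
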