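"""Exception hierarchy for dlmokit.

Validation outcomes ("no dynamic part", "insufficient number of data
points") are carried as statuses on :class:`~dlmokit.profile.ValidationReport`
rather than raised, except where an operation cannot proceed at all.
"""


class DlmokitError(Exception):
    """Base class for all dlmokit errors."""


class InputFormatError(DlmokitError):
    """A time or concentration value could not be parsed."""


class DuplicateTimeError(DlmokitError):
    """Two samples share the same timestamp."""


class ImplausibleSpanError(DlmokitError):
    """Profile spans more than 36 h after midnight unwrapping."""


class ProfileValidationError(DlmokitError):
    """Profile failed validation (carries the machine-readable status)."""

    def __init__(self, status: str, message: str | None = None):
        self.status = status
        super().__init__(message or status)


class NoAscendingError(DlmokitError):
    """No upward threshold crossing, or truncation exhausted the rise."""


class DegenerateRoiError(DlmokitError):
    """Region of interest collapsed to zero width or height."""


class DegenerateGeometryError(DlmokitError):
    """Parallelogram fit requested on degenerate (all-equal-y) points."""


class OptimizationFailureError(DlmokitError):
    """Parallelogram optimizer failed after restarts."""


class NoLateDataError(DlmokitError):
    """No data points at or after the candidate breakpoint."""


class BootstrapFailureError(DlmokitError):
    """Every bootstrap replicate failed to yield an estimate."""


class UndefinedCircularMeanError(DlmokitError):
    """Circular mean undefined (zero resultant length)."""
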