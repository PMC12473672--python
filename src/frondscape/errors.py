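"""Exception hierarchy for frondscape.

All argument-validation failures derive from :class:`InvalidArgumentError`
(itself a ``ValueError``) so callers can catch one type; more specific
subclasses name the failure mode the analysis stages signal.
"""


class FrondscapeError(Exception):
    """Base class for all frondscape-specific errors."""


class InvalidArgumentError(FrondscapeError, ValueError):
    """An argument violates a stated precondition."""


class DegenerateTransientError(FrondscapeError):
    """A fluorescence transient has no usable variable fluorescence (Fm <= F0)."""


class CoverageError(FrondscapeError):
    """A time grid does not cover the canonical landmark times."""


class OutOfRangeError(FrondscapeError):
    """A derived quantity fell outside its admissible range.

    Carries the name of the offending quantity.
    """

    def __init__(self, quantity: str, value: float, message: str | None = None):
        self.quantity = quantity
        self.value = value
        super().__init__(message or f"{quantity} = {value!r} out of admissible range")


class InconsistentRecordError(InvalidArgumentError):
    """Raw fluorescence levels of a quenching record are mutually inconsistent."""


class FitFailureError(FrondscapeError):
    """Curve fitting failed to converge after bounded restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class PlacementError(FrondscapeError):
    """Frond placement on the synthetic canvas failed after bounded retries."""


class InsufficientDataError(FrondscapeError):
    """Not enough data survived filtering to build the requested product."""


class TransformFailureError(FrondscapeError):
    """Log-transformation was required but responses are not strictly positive."""


class UndefinedDoublingError(InvalidArgumentError):
    """Doubling time is undefined for non-positive growth rates."""
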