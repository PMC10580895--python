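"""Exception and warning types shared across the package."""


class FermkinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FermkinError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(FermkinError, ValueError):
    """Input data violate a structural contract (schema, ordering, signs)."""


class FitError(FermkinError, RuntimeError):
    """A parameter estimation procedure could not produce a valid result."""


class SingularFitError(FitError):
    """The normal equations of a regression are singular (e.g. aliased
    model terms or a zero-variance predictor)."""


class AlignmentError(ValidationError):
    """Two series that must share a time grid do not."""


class SubstrateExhaustionWarning(UserWarning):
    """The substrate balance predicts S(t) < 0 before the requested time.

    Carries the predicted exhaustion time in hours as ``exhaustion_time``.
    """

    def __init__(self, message: str, exhaustion_time: float):
        super().__init__(message)
        self.exhaustion_time = exhaustion_time


class RangeWarning(UserWarning):
    """A factor level lies outside its declared design range."""
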