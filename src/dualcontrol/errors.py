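"""Exception types shared across the package."""


class DualControlError(Exception):
    """Base class for all package errors."""


class ValidationError(DualControlError, ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class UndefinedScoreError(DualControlError, ValueError):
    """Raised when a summary score is requested from incomplete data."""


class FitError(DualControlError, RuntimeError):
    """Raised when optimization fails entirely.

    Carries the best partial result (if any) in :attr:`best`.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
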