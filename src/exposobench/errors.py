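"""Exception hierarchy."""


class ExposobenchError(Exception):
    """Base class for package errors."""


class ValidationError(ExposobenchError, ValueError):
    """Input fails a structural precondition (shape, symmetry, range...)."""


class ConvergenceError(ExposobenchError, RuntimeError):
    """An iterative routine did not converge within its budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GenerationError(ExposobenchError, RuntimeError):
    """A stochastic generator could not satisfy its target within retries."""


class FeasibilityError(ExposobenchError, RuntimeError):
    """No configuration satisfying the requested constraint exists / was found."""
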