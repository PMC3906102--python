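"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter or input violates a model invariant."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested operation."""


class GridMismatchError(ValidationError):
    """Two time series do not share the same time grid."""


class StabilityError(ValidationError):
    """An explicit time step violates the scheme's stability bound."""


class ConvergenceError(RuntimeError):
    """An iterative procedure failed to converge within its cap."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
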