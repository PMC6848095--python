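"""Exception hierarchy shared across the package."""


class SpinerodError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpinerodError, ValueError):
    """A user-supplied parameter violates its documented domain."""


class DegenerateGeometryError(SpinerodError, ValueError):
    """Input geometry is degenerate (self-intersecting, zero-height, co-located points)."""


class ConfigurationError(SpinerodError, ValueError):
    """A run configuration is malformed or references unknown options."""


class InsufficientDataError(SpinerodError, ValueError):
    """Too few points/levels for the requested measurement."""


class InputMismatchError(SpinerodError, ValueError):
    """Paired inputs (initial/deformed curves, fields) do not match in size."""


class NormalizationError(SpinerodError, ArithmeticError):
    """Deformation normalization is undefined (max vertical deformation is zero)."""


class UndefinedRatioError(SpinerodError, ArithmeticError):
    """Displacement ratio undefined (mean Y displacement is zero)."""


class UndefinedCorrelationError(SpinerodError, ArithmeticError):
    """Correlation undefined (a field has zero variance)."""


class ConvergenceError(SpinerodError, RuntimeError):
    """Nonlinear solve failed to converge; carries last residual and load step."""

    def __init__(self, message: str, *, step: int | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.step = step
        self.residual = residual


class ConstraintError(SpinerodError, RuntimeError):
    """Stiffness is singular: an unconstrained rigid mode remains."""
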