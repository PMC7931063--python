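"""Exception hierarchy shared across the package."""


class Trip3pError(Exception):
    """Base class for all package errors."""


class ValidationError(Trip3pError, ValueError):
    """An input violates a documented invariant."""


class DegenerateGeometryError(ValidationError):
    """Geometrically degenerate input (collinear rays, vertex at the eye, ...)."""


class ConfigurationError(Trip3pError, ValueError):
    """A run configuration is unusable (empty grids, zero acceptance, ...)."""


class NumericalError(Trip3pError, RuntimeError):
    """A numerical routine failed to converge; carries the offending inputs."""

    def __init__(self, message: str, inputs=None):
        super().__init__(message)
        self.inputs = inputs
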