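"""Exception hierarchy.

Every error carries an ``exit_code`` so the CLI can map error classes to
distinct non-zero process exit codes.
"""


class RoutexposeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidConfigError(RoutexposeError):
    """A configuration value violates its invariants."""

    exit_code = 2


class InvalidParamsError(InvalidConfigError):
    """Utility-model parameters violate their invariants (e.g. temperature <= 0)."""


class DependencyError(RoutexposeError):
    """A pipeline stage was invoked before its upstream artifact exists."""

    exit_code = 3


class GeometryError(RoutexposeError):
    """An input geometry is invalid; the message names the offending feature."""

    exit_code = 4


class CoverageError(GeometryError):
    """Noise polygons leave more of a cell uncovered than the tolerance allows."""


class OutOfExtentError(GeometryError):
    """An itinerary leaves the grid extent."""


class EmptyNetworkError(RoutexposeError):
    """A street network was requested from an empty street set."""

    exit_code = 5


class NoRouteError(RoutexposeError):
    """No path exists between origin and destination on the mode subgraph."""

    exit_code = 5

    def __init__(self, origin, dest, mode):
        self.origin = tuple(origin)
        self.dest = tuple(dest)
        self.mode = mode
        super().__init__(f"no {mode} route from {self.origin} to {self.dest}")


class StratificationError(RoutexposeError):
    """A class required for a stratified split is absent."""

    exit_code = 6


class ClassMissingError(RoutexposeError):
    """Undersampling was asked to balance a class with zero rows."""

    exit_code = 6


class SchemaError(RoutexposeError):
    """Feature columns at prediction time do not match the training schema."""

    exit_code = 6


class StateError(RoutexposeError):
    """An operation was called on an unfitted model."""

    exit_code = 7


class NumericalGuardError(RoutexposeError):
    """A numerical guard tripped (e.g. a zero vote fraction after smoothing)."""

    exit_code = 7
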