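"""Exception hierarchy shared across the analysis modules."""


class UnguisError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(UnguisError, ValueError):
    """A measurement violates its physical constraints (names the field)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InsufficientDataError(UnguisError, ValueError):
    """Too few observations (or missing elements) for the requested analysis."""


class DegenerateBaselineError(UnguisError, ValueError):
    """A reference-group summary cannot support a t-test (zero variance, n < 2)."""


class DegenerateVariableError(UnguisError, ValueError):
    """A variable is constant across specimens, so correlations are undefined."""


class DegenerateHullError(UnguisError, ValueError):
    """A group's score cloud is collinear; no two-dimensional hull exists."""


class SingularCovarianceError(UnguisError, ValueError):
    """A pooled covariance matrix is singular and no ridge policy was enabled."""


class ConfigurationError(UnguisError, ValueError):
    """Inconsistent analysis configuration (e.g. baseline missing a variable)."""


class NexusParseError(UnguisError, ValueError):
    """Malformed NEXUS input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


class MatrixEditError(UnguisError, ValueError):
    """A matrix edit references an unknown taxon/character or breaks invariants."""
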