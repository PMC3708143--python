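"""Exception types shared across the package."""


class SparseSynergyError(Exception):
    """Base class for all package-specific errors."""


class InvalidCycleError(SparseSynergyError):
    """A step-cycle window has zero or negative duration."""


class InvalidBurstError(SparseSynergyError):
    """A burst violates its invariants (e.g. zero-length, offset <= onset)."""


class InsufficientDataError(SparseSynergyError):
    """Too few trials to compute the requested statistic."""


class InvalidClusterError(SparseSynergyError):
    """Cluster statistics violate the model (e.g. mean offset <= mean onset)."""


class DegenerateEllipseError(SparseSynergyError):
    """|rho| >= 1: the bivariate-normal ellipse collapses to a line."""


class SchemaError(SparseSynergyError):
    """An input table does not match the expected column schema."""


class ConfigurationError(SparseSynergyError):
    """A synthetic-data or pipeline configuration field is invalid."""
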