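"""Exception hierarchy.

Each public error carries a short machine-readable ``category`` used by the
command-line layer to pick an exit code, so batch pipelines can distinguish
a malformed file from a failed measurement without parsing messages.
"""


class RopZoneError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(RopZoneError):
    """A file could not be parsed or has the wrong schema/shape."""

    category = "format"


class GeometryError(RopZoneError):
    """Scan-geometry parameters invalid, or indices outside the grid."""

    category = "geometry"


class ConfigurationError(RopZoneError):
    """Inconsistent run or phantom configuration."""

    category = "config"


class AnnotationError(RopZoneError):
    """Landmark annotations missing, out of bounds, or degenerate."""

    category = "annotation"


class MeasurementError(RopZoneError):
    """A measurement could not be completed on otherwise valid input."""

    category = "measurement"


class InvariantViolationError(RopZoneError):
    """Input data violate a structural invariant (e.g. label ordering)."""

    category = "format"


class NoPathError(MeasurementError):
    """Geodesic endpoints lie in disconnected surface components."""


class AnalysisError(RopZoneError):
    """A cohort statistic is undefined on the supplied table."""

    category = "analysis"


class UndefinedStatisticError(AnalysisError):
    """Raised by estimators when the statistic is undefined on a sample

    (e.g. AUROC with a single outcome class); the cluster bootstrap
    catches this and redraws the replicate.
    """
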