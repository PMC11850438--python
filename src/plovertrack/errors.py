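"""Exception hierarchy shared across the package."""


class PloverTrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PloverTrackError):
    """A column mapping, variable mapping or run configuration is invalid."""


class EmptyTrackError(PloverTrackError):
    """No usable fixes remain after parsing and validation."""


class DomainError(PloverTrackError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UndefinedBearingError(DomainError):
    """Bearing requested between two identical points."""


class FormatError(PloverTrackError):
    """A wind-grid file does not satisfy the expected NetCDF layout."""


class OutOfDomainError(PloverTrackError):
    """A space-time query falls outside the hull of a wind grid."""


class PlanError(PloverTrackError):
    """A synthetic track plan is internally inconsistent or infeasible."""


class DegenerateFitError(PloverTrackError):
    """A regression was requested on data that cannot identify a slope."""
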