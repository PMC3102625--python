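"""Exception hierarchy for voltrack."""


class VoltrackError(Exception):
    """Base class for all voltrack errors."""


class FormatError(VoltrackError):
    """On-disk data is structurally inconsistent (shapes, affines, containers)."""


class MetadataError(VoltrackError):
    """Required metadata (frame times, VENC, spacing) is missing or invalid."""


class DataValidationError(VoltrackError):
    """Array contents violate a contract (non-finite values, shape mismatch)."""


class GeometryError(VoltrackError):
    """Geometric construction is impossible (degenerate landmarks, empty masks)."""


class DegenerateGeometryError(GeometryError):
    """A fit or frame cannot be built because the supporting points are degenerate."""


class TimeRangeError(VoltrackError):
    """A requested time lies outside the reachable span of the data."""


class ParameterError(VoltrackError):
    """Invalid parameter for an analytic object (zero normal, nonpositive radius...)."""


class DiagnosticError(VoltrackError):
    """A data-driven step produced an unusable result (e.g. empty stationary mask)."""


class AmbiguityError(VoltrackError):
    """A landmark could not be identified unambiguously (e.g. missing E/A peaks)."""


class UndefinedRatioError(VoltrackError):
    """A ratio with zero denominator was requested (e.g. agreement with no particles)."""


class ConfigError(VoltrackError):
    """Pipeline configuration is invalid; message names the offending field."""
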