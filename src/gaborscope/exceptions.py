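"""Exception types raised across the package."""


class GaborscopeError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(GaborscopeError):
    """A physical or numerical parameter is out of its valid domain."""


class InvalidInputError(GaborscopeError):
    """Input data violate a precondition (e.g. negative intensity)."""


class InvalidSceneError(GaborscopeError):
    """A synthetic scene is geometrically inconsistent (e.g. overlapping beads)."""


class InvalidRegionError(GaborscopeError):
    """A pixel region is too small, out of bounds, or overlaps another."""


class UndefinedMetricError(GaborscopeError):
    """A metric is mathematically undefined for the given data."""


class UnresolvableGeometryError(GaborscopeError):
    """Requested pattern geometry cannot be sampled on the given grid."""
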