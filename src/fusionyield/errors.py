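"""Exception hierarchy shared across the package."""


class FusionYieldError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedGridError(FusionYieldError):
    """Raster grid violates the square-pixel / integer-ratio contract."""


class GridAlignmentError(FusionYieldError):
    """Two rasters that must share a grid do not."""


class ShapeError(FusionYieldError):
    """Array dimensions incompatible with the requested block operation."""


class CoverageError(FusionYieldError):
    """A raster or polygon does not cover the required extent."""


class GeometryError(FusionYieldError):
    """Invalid vector geometry (self-intersection, out-of-extent, ...)."""


class InterpolationError(FusionYieldError):
    """Too few or degenerate control points for surface interpolation."""


class DegenerateClassError(FusionYieldError):
    """Requested more land-cover classes than the data can support."""


class StageDetectionError(FusionYieldError):
    """Season stages cannot be identified (e.g. monotone series)."""


class DegenerateFitError(FusionYieldError):
    """Regression input is degenerate (constant predictor, too few pairs)."""


class DomainError(FusionYieldError):
    """Scalar argument outside its mathematical domain."""
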