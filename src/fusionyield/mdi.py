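"""Mixed Degree Index: plot-level pixel-mixing diagnostics.

For every coarse pixel overlapping a plot (coverage >= 1%), the index
multiplies an area-based purity term

    m_par = (s_p / s_w) * (s_p / s_y)

(``s_p`` pixel-plot intersection area, ``s_w`` pure-pixel area, ``s_y``
plot area) by the relative coarse/fine NDVI discrepancy

    ndvi_pro = |ndvi_m - ndvi_l| / max(ndvi_m, ndvi_l)

and sums the products.  0 means pure, consistent pixels; values grow
with mixing and never exceed 1 for non-negative NDVI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .errors import CoverageError, DomainError
from .io_grid import GridRaster, PlotPolygon

logger = logging.getLogger(__name__)

__all__ = [
    "PixelOverlap",
    "MDIComponents",
    "MDIResult",
    "pixel_overlaps",
    "m_par",
    "ndvi_pro",
    "compute_mdi",
    "COVERAGE_THRESHOLD",
]

#: Coarse pixels covering less than this fraction of their area are excluded.
COVERAGE_THRESHOLD = 0.01


@dataclass(frozen=True)
class PixelOverlap:
    """Intersection of one coarse pixel with a plot."""

    pixel_id: int  # row-major scan index over the coarse raster
    row: int
    col: int
    s_p: float  # intersection area, m^2
    s_w: float  # pure coarse pixel area, m^2

    @property
    def coverage(self) -> float:
        return self.s_p / self.s_w


@dataclass(frozen=True)
class MDIComponents:
    pixel_id: int
    m_par: float
    ndvi_m: float
    ndvi_l: float
    ndvi_pro: float
    s_p: float


@dataclass
class MDIResult:
    plot_name: str
    resolution: float  # coarse pixel edge, m
    components: list[MDIComponents]
    mdi: float | None  # None when no pixel passes the coverage threshold


def pixel_overlaps(plot: PlotPolygon, coarse: GridRaster) -> list[PixelOverlap]:
    """Exact polygon-square intersection areas for coarse pixels.

    Pixels are numbered row-major (left to right, top to bottom) over
    the coarse raster; pixels with coverage below
    :data:`COVERAGE_THRESHOLD` are dropped.
    """
    geom = plot.geometry
    xmin, ymin, xmax, ymax = geom.bounds
    rxmin, rymin, rxmax, rymax = coarse.bounds
    if xmin >= rxmax or xmax <= rxmin or ymin >= rymax or ymax <= rymin:
        raise CoverageError(f"plot '{plot.name}' does not intersect the raster")
    ps = coarse.pixel_size
    s_w = ps * ps
    nrow, ncol = coarse.shape
    c0 = max(0, int(np.floor((xmin - coarse.origin_x) / ps)))
    c1 = min(ncol, int(np.ceil((xmax - coarse.origin_x) / ps)))
    r0 = max(0, int(np.floor((coarse.origin_y - ymax) / ps)))
    r1 = min(nrow, int(np.ceil((coarse.origin_y - ymin) / ps)))
    out: list[PixelOverlap] = []
    for r in range(r0, r1):
        for c in range(c0, c1):
            cell = box(
                coarse.origin_x + c * ps,
                coarse.origin_y - (r + 1) * ps,
                coarse.origin_x + (c + 1) * ps,
                coarse.origin_y - r * ps,
            )
            s_p = geom.intersection(cell).area
            if s_p / s_w >= COVERAGE_THRESHOLD:
                out.append(PixelOverlap(r * ncol + c, r, c, s_p, s_w))
    if not out:
        logger.warning("plot '%s': no coarse pixel reaches %.0f%% coverage",
                       plot.name, COVERAGE_THRESHOLD * 100)
    return out


def m_par(s_p: float, s_w: float, s_y: float) -> float:
    """Purity term (s_p/s_w) * (s_p/s_y)."""
    if s_w <= 0 or s_y <= 0:
        raise DomainError("s_w and s_y must be positive")
    if s_p < 0 or s_p > min(s_w, s_y) * (1 + 1e-9):
        raise DomainError("s_p must lie in [0, min(s_w, s_y)]")
    return (s_p / s_w) * (s_p / s_y)


def ndvi_pro(ndvi_m: float, ndvi_l: float) -> float:
    """Relative coarse/fine NDVI discrepancy |m - l| / max(m, l).

    When both values are <= 0 (non-vegetated degenerate case) the
    discrepancy is defined as 0, with a logged warning.
    """
    top = max(ndvi_l, ndvi_m)
    if top <= 0:
        logger.warning("ndvi_pro: max(ndvi_l, ndvi_m) <= 0, returning 0")
        return 0.0
    return abs(ndvi_m - ndvi_l) / top


def _fine_mean_over_intersection(
    fine: GridRaster, clipped_geom, row_range, col_range
) -> float:
    """Area-weighted mean of fine NDVI over a (pixel ∩ plot) polygon."""
    ps = fine.pixel_size
    total_w = 0.0
    total = 0.0
    for r in row_range:
        for c in col_range:
            cell = box(
                fine.origin_x + c * ps,
                fine.origin_y - (r + 1) * ps,
                fine.origin_x + (c + 1) * ps,
                fine.origin_y - r * ps,
            )
            w = clipped_geom.intersection(cell).area
            if w > 0:
                v = fine.values[r, c]
                if np.isfinite(v):
                    total_w += w
                    total += w * v
    return total / total_w if total_w > 0 else np.nan


def compute_mdi(
    plot: PlotPolygon, coarse_ndvi: GridRaster, fine_ndvi: GridRaster
) -> MDIResult:
    """Sum m_par * ndvi_pro over the plot's included coarse pixels.

    ``ndvi_l`` per pixel is the area-weighted mean of fine NDVI over the
    pixel ∩ plot footprint (the plot's own signal, not the whole-pixel
    mean).  An empty overlap list yields ``mdi=None``.
    """
    overlaps = pixel_overlaps(plot, coarse_ndvi)
    s_y = plot.geometry.area
    fps = fine_ndvi.pixel_size
    cps = coarse_ndvi.pixel_size
    comps: list[MDIComponents] = []
    for ov in overlaps:
        cell = box(
            coarse_ndvi.origin_x + ov.col * cps,
            coarse_ndvi.origin_y - (ov.row + 1) * cps,
            coarse_ndvi.origin_x + (ov.col + 1) * cps,
            coarse_ndvi.origin_y - ov.row * cps,
        )
        clipped = plot.geometry.intersection(cell)
        cxmin, cymin, cxmax, cymax = clipped.bounds
        fr0 = max(0, int(np.floor((fine_ndvi.origin_y - cymax) / fps)))
        fr1 = min(fine_ndvi.shape[0], int(np.ceil((fine_ndvi.origin_y - cymin) / fps)))
        fc0 = max(0, int(np.floor((cxmin - fine_ndvi.origin_x) / fps)))
        fc1 = min(fine_ndvi.shape[1], int(np.ceil((cxmax - fine_ndvi.origin_x) / fps)))
        ndvi_l = _fine_mean_over_intersection(
            fine_ndvi, clipped, range(fr0, fr1), range(fc0, fc1)
        )
        ndvi_m = float(coarse_ndvi.values[ov.row, ov.col])
        mp = m_par(ov.s_p, ov.s_w, s_y)
        npro = ndvi_pro(ndvi_m, ndvi_l) if np.isfinite(ndvi_l) else 0.0
        comps.append(MDIComponents(ov.pixel_id, mp, ndvi_m, ndvi_l, npro, ov.s_p))
    if not comps:
        return MDIResult(plot.name, cps, [], None)
    mdi = float(sum(c.m_par * c.ndvi_pro for c in comps))
    return MDIResult(plot.name, cps, comps, mdi)
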