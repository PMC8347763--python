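"""Six-stage flexible spatiotemporal fusion of fine and coarse NDVI.

Given one fine-resolution NDVI image at a reference date ``t1`` and
coarse NDVI at ``t1`` and a target date ``t2`` (coarse = fine grid
coarsened by an exact integer ratio), predict the fine image at ``t2``:

1. delineate the working extent (snapped to whole coarse pixels);
2. coarse temporal change ``t2 - t1``;
3. class-wise temporal prediction: unmix the coarse change into
   per-class fine changes by least squares on coarse-pixel class
   fractions, and compute per-coarse-pixel residuals;
4. thin-plate-spline spatial prediction of the fine image from the
   coarse ``t2`` image alone;
5. distribute each coarse residual over its fine pixels, guided by the
   spline prediction and a local class-homogeneity index;
6. refine each pixel's change with an inverse-distance-weighted mean
   over its spectrally most similar neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from sklearn.cluster import KMeans

from .errors import (
    CoverageError,
    DegenerateClassError,
    GridAlignmentError,
    InterpolationError,
)
from .io_grid import GridRaster, PlotPolygon, block_aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "FusionParams",
    "FusionInputs",
    "ClassMap",
    "TemporalPrediction",
    "delineate",
    "classify_fine",
    "coarse_change",
    "temporal_prediction",
    "tps_prediction",
    "distribute_residuals",
    "neighborhood_refine",
    "fsdaf_fuse",
]

_EPS_WEIGHT = 1e-6
_RIDGE_LAMBDA = 1e-6


@dataclass
class FusionParams:
    """Tuning knobs for the fusion stages.

    ``window_radius`` defaults to the coarse/fine ratio when left None.
    """

    n_classes: int = 4
    n_similar: int = 20
    window_radius: Optional[int] = None
    tps_smoothing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_similar < 1:
            raise ValueError("n_classes and n_similar must be >= 1")
        if self.window_radius is not None and self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.tps_smoothing < 0:
            raise ValueError("tps_smoothing must be non-negative")


@dataclass
class FusionInputs:
    fine_t1: GridRaster
    coarse_t1: GridRaster
    coarse_t2: GridRaster
    ratio: int
    params: FusionParams = field(default_factory=FusionParams)

    def __post_init__(self) -> None:
        self.ratio = int(self.ratio)
        if self.ratio < 1:
            raise ValueError("ratio must be a positive integer")
        if not self.coarse_t1.same_grid(self.coarse_t2):
            raise GridAlignmentError("coarse rasters must share a grid")
        agg = block_aggregate(self.fine_t1, self.ratio)
        if not agg.same_grid(self.coarse_t1):
            raise GridAlignmentError(
                "coarse grid must equal the fine grid coarsened by ratio"
            )


@dataclass
class ClassMap:
    """Fine-grid class labels plus per-coarse-pixel class fractions."""

    labels: np.ndarray  # int array on the fine grid, -1 where nodata
    fractions: np.ndarray  # (coarse_rows, coarse_cols, n_classes)
    centers: np.ndarray  # per-class mean NDVI at t1

    @property
    def n_classes(self) -> int:
        return self.fractions.shape[2]


class TemporalPrediction(NamedTuple):
    tp_fine: GridRaster
    residual: GridRaster
    delta_class: np.ndarray


class Delineation(NamedTuple):
    raster: GridRaster
    inside: np.ndarray  # True where the pixel center falls in the region


def delineate(
    fine_t1: GridRaster,
    region: Optional[PlotPolygon],
    ratio: int,
) -> Delineation:
    """Crop to the region's bounding box snapped out to whole coarse pixels.

    Cells outside the region are retained (they provide fusion context)
    but flagged False in ``inside``.  ``region=None`` keeps the full
    extent.
    """
    ratio = int(ratio)
    nrow, ncol = fine_t1.shape
    if region is None:
        return Delineation(fine_t1.copy(), np.ones((nrow, ncol), dtype=bool))
    xmin, ymin, xmax, ymax = region.geometry.bounds
    rxmin, rymin, rxmax, rymax = fine_t1.bounds
    if xmin >= rxmax or xmax <= rxmin or ymin >= rymax or ymax <= rymin:
        raise CoverageError("region does not intersect the raster extent")
    ps = fine_t1.pixel_size
    c0 = int(np.floor((xmin - fine_t1.origin_x) / ps))
    c1 = int(np.ceil((xmax - fine_t1.origin_x) / ps))
    r0 = int(np.floor((fine_t1.origin_y - ymax) / ps))
    r1 = int(np.ceil((fine_t1.origin_y - ymin) / ps))
    # snap outward to whole coarse pixels, clipped to the raster
    c0 = max(0, (c0 // ratio) * ratio)
    r0 = max(0, (r0 // ratio) * ratio)
    c1 = min(ncol, int(np.ceil(c1 / ratio)) * ratio)
    r1 = min(nrow, int(np.ceil(r1 / ratio)) * ratio)
    sub = GridRaster(
        fine_t1.values[r0:r1, c0:c1].copy(),
        fine_t1.origin_x + c0 * ps,
        fine_t1.origin_y - r0 * ps,
        ps,
        fine_t1.nodata,
    )
    from shapely import points as _mk_points
    from shapely.prepared import prep

    xs = sub.x_centers()
    ys = sub.y_centers()
    gx, gy = np.meshgrid(xs, ys)
    pts = _mk_points(np.column_stack([gx.ravel(), gy.ravel()]))
    prepared = prep(region.geometry)
    inside = np.fromiter(
        (prepared.contains(p) for p in pts), dtype=bool, count=pts.size
    ).reshape(sub.shape)
    return Delineation(sub, inside)


def classify_fine(
    fine_t1: GridRaster, n_classes: int, seed: int, ratio: int
) -> ClassMap:
    """Cluster fine NDVI values into ``n_classes`` and count block fractions."""
    vals = fine_t1.values
    valid = np.isfinite(vals)
    n_valid = int(valid.sum())
    if n_classes > n_valid:
        raise DegenerateClassError("more classes than valid fine pixels")
    n_distinct = np.unique(vals[valid]).size
    if n_classes > n_distinct:
        raise DegenerateClassError(
            f"{n_classes} classes requested but only {n_distinct} distinct values"
        )
    labels = np.full(vals.shape, -1, dtype=int)
    if n_classes == 1:
        labels[valid] = 0
        centers = np.array([float(np.mean(vals[valid]))])
    else:
        km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed)
        labels[valid] = km.fit_predict(vals[valid].reshape(-1, 1))
        centers = km.cluster_centers_.ravel().copy()
    nrow, ncol = vals.shape
    ratio = int(ratio)
    cr, cc = nrow // ratio, ncol // ratio
    fractions = np.zeros((cr, cc, n_classes))
    lab_blocks = labels.reshape(cr, ratio, cc, ratio)
    for k in range(n_classes):
        fractions[:, :, k] = (lab_blocks == k).sum(axis=(1, 3)) / (ratio * ratio)
    return ClassMap(labels, fractions, centers)


def coarse_change(coarse_t1: GridRaster, coarse_t2: GridRaster) -> GridRaster:
    """Elementwise coarse ``t2 - t1``."""
    if not coarse_t1.same_grid(coarse_t2):
        raise GridAlignmentError("coarse rasters must share a grid")
    return coarse_t1.with_values(coarse_t2.values - coarse_t1.values)


def temporal_prediction(
    fine_t1: GridRaster,
    delta_c: GridRaster,
    cmap: ClassMap,
    ratio: int,
    coarse_t2: Optional[GridRaster] = None,
) -> TemporalPrediction:
    """Unmix the coarse change into per-class fine changes.

    Solves ``fractions @ delta_class ~= delta_c`` by least squares; the
    temporal prediction is ``fine_t1 + delta_class[label]``.  The
    residual raster is ``coarse_t2 - block_aggregate(tp_fine)`` when
    ``coarse_t2`` is given, otherwise the coarse change left unexplained
    by the class deltas.
    """
    ratio = int(ratio)
    k = cmap.n_classes
    F = cmap.fractions.reshape(-1, k)
    b = delta_c.values.ravel()
    ok = np.isfinite(b)
    Fo, bo = F[ok], b[ok]
    if np.linalg.matrix_rank(Fo) < k:
        logger.warning(
            "class-fraction matrix is rank deficient; using ridge fallback"
        )
        A = Fo.T @ Fo + _RIDGE_LAMBDA * np.eye(k)
        delta_class = np.linalg.solve(A, Fo.T @ bo)
    else:
        delta_class, *_ = np.linalg.lstsq(Fo, bo, rcond=None)
    change = np.where(cmap.labels >= 0, delta_class[np.clip(cmap.labels, 0, None)], np.nan)
    tp = fine_t1.with_values(fine_t1.values + change)
    agg_tp = block_aggregate(tp, ratio)
    if coarse_t2 is not None:
        residual = agg_tp.with_values(coarse_t2.values - agg_tp.values)
    else:
        agg_t1 = block_aggregate(fine_t1, ratio)
        implied = agg_tp.values - agg_t1.values
        residual = agg_tp.with_values(delta_c.values - implied)
    return TemporalPrediction(tp, residual, delta_class)


def tps_prediction(
    coarse_t2: GridRaster, fine_grid: GridRaster, smoothing: float = 0.0
) -> GridRaster:
    """Thin-plate-spline surface through coarse pixel centers, sampled on
    the fine grid.

    Uses the r^2 log r kernel plus an affine part, so constants and
    planes are reproduced exactly; with ``smoothing=0`` the surface
    interpolates the control values.
    """
    cx = coarse_t2.x_centers()
    cy = coarse_t2.y_centers()
    gx, gy = np.meshgrid(cx, cy)
    vals = coarse_t2.values.ravel()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    ok = np.isfinite(vals)
    pts, vals = pts[ok], vals[ok]
    if len(vals) < 3:
        raise InterpolationError("need at least 3 coarse control points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise InterpolationError("coarse pixel centers are collinear")
    interp = RBFInterpolator(
        pts, vals, kernel="thin_plate_spline", smoothing=smoothing, degree=1
    )
    fx = fine_grid.x_centers()
    fy = fine_grid.y_centers()
    fgx, fgy = np.meshgrid(fx, fy)
    out = interp(np.column_stack([fgx.ravel(), fgy.ravel()]))
    return fine_grid.with_values(out.reshape(fine_grid.shape))


def _homogeneity(labels: np.ndarray, ratio: int) -> np.ndarray:
    """Fraction of same-class neighbours in a (2*ratio+1)^2 window."""
    size = 2 * int(ratio) + 1
    n_classes = labels.max() + 1
    ones = np.ones_like(labels, dtype=float)
    denom = ndimage.uniform_filter(ones, size=size, mode="constant", cval=0.0)
    hom = np.zeros(labels.shape, dtype=float)
    for k in range(n_classes):
        ind = (labels == k).astype(float)
        cnt = ndimage.uniform_filter(ind, size=size, mode="constant", cval=0.0)
        sel = labels == k
        hom[sel] = (cnt[sel] / denom[sel])
    return hom


def distribute_residuals(
    tpred: TemporalPrediction,
    sp_fine: GridRaster,
    fine_t1: GridRaster,
    ratio: int,
    cmap: ClassMap,
) -> GridRaster:
    """Allocate each coarse residual across its fine pixels.

    Per fine pixel the guidance score is
    ``max(eps, homogeneity * (1 - |sp - tp| / max block discrepancy))``;
    scores are normalised within each coarse block so the block mean of
    the allocation equals the coarse residual.
    """
    ratio = int(ratio)
    tp = tpred.tp_fine.values
    nrow, ncol = tp.shape
    cr, cc = nrow // ratio, ncol // ratio
    disc = np.abs(sp_fine.values - tp)
    disc_blocks = disc.reshape(cr, ratio, cc, ratio)
    max_disc = disc_blocks.max(axis=(1, 3))
    max_disc_full = np.repeat(np.repeat(max_disc, ratio, 0), ratio, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(max_disc_full > 0, 1.0 - disc / max_disc_full, 1.0)
    hom = _homogeneity(cmap.labels, ratio)
    score = np.maximum(_EPS_WEIGHT, hom * rel)
    score_blocks = score.reshape(cr, ratio, cc, ratio)
    score_sum = score_blocks.sum(axis=(1, 3))
    score_sum_full = np.repeat(np.repeat(score_sum, ratio, 0), ratio, 1)
    res_full = np.repeat(np.repeat(tpred.residual.values, ratio, 0), ratio, 1)
    alloc = score / score_sum_full * (ratio * ratio) * res_full
    return tpred.tp_fine.with_values(alloc)


def neighborhood_refine(
    prelim_fine: GridRaster,
    fine_t1: GridRaster,
    params: FusionParams,
    ratio: int = 1,
) -> GridRaster:
    """Smooth each pixel's preliminary change over similar neighbours.

    For each fine pixel, pick the ``n_similar`` window pixels with the
    smallest |fine_t1 difference| (ties broken by spatial distance, then
    window scan order); the final change is their inverse-distance
    (1/(1+d)) weighted mean.  The pixel itself always qualifies.
    """
    radius = params.window_radius if params.window_radius is not None else int(ratio)
    radius = max(1, int(radius))
    base = fine_t1.values
    change = prelim_fine.values - base
    nrow, ncol = base.shape
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
    ]
    n_off = len(offs)
    big = np.inf
    spec = np.full((n_off, nrow, ncol), big)
    chg = np.zeros((n_off, nrow, ncol))
    dist = np.zeros(n_off)
    for idx, (dy, dx) in enumerate(offs):
        dist[idx] = np.hypot(dy, dx)
        src_r = slice(max(0, dy), min(nrow, nrow + dy))
        src_c = slice(max(0, dx), min(ncol, ncol + dx))
        dst_r = slice(max(0, -dy), min(nrow, nrow - dy))
        dst_c = slice(max(0, -dx), min(ncol, ncol - dx))
        diff = np.abs(base[src_r, src_c] - base[dst_r, dst_c])
        spec[idx][dst_r, dst_c] = diff
        chg[idx][dst_r, dst_c] = change[src_r, src_c]
    spec[~np.isfinite(spec)] = big
    n_sim = min(params.n_similar, n_off)
    flat_spec = spec.reshape(n_off, -1)
    flat_chg = chg.reshape(n_off, -1)
    # deterministic ordering: spectral distance, then spatial, then scan order
    off_rank = np.arange(n_off, dtype=float)[:, None] * np.ones((1, flat_spec.shape[1]))
    spat = dist[:, None] * np.ones((1, flat_spec.shape[1]))
    order = np.lexsort((off_rank, spat, flat_spec), axis=0)
    sel = order[:n_sim]
    cols = np.arange(flat_spec.shape[1])[None, :]
    sel_spec = flat_spec[sel, cols]
    sel_chg = flat_chg[sel, cols]
    sel_dist = dist[sel]
    valid = np.isfinite(sel_spec)
    w = np.where(valid, 1.0 / (1.0 + sel_dist), 0.0)
    wsum = w.sum(axis=0)
    wsum = np.where(wsum > 0, wsum, 1.0)
    final_change = (w * np.where(valid, sel_chg, 0.0)).sum(axis=0) / wsum
    out = base + final_change.reshape(nrow, ncol)
    return fine_t1.with_values(out)


def fsdaf_fuse(
    inputs: FusionInputs, return_diagnostics: bool = False
) -> GridRaster | tuple[GridRaster, dict]:
    """Run the full six-stage fusion and return the fine prediction at t2.

    The output is clipped to the NDVI domain [-1, 1].
    """
    p = inputs.params
    ratio = inputs.ratio
    fine_t1 = inputs.fine_t1
    cmap = classify_fine(fine_t1, p.n_classes, p.seed, ratio)
    delta_c = coarse_change(inputs.coarse_t1, inputs.coarse_t2)
    tpred = temporal_prediction(
        fine_t1, delta_c, cmap, ratio, coarse_t2=inputs.coarse_t2
    )
    sp_fine = tps_prediction(inputs.coarse_t2, fine_t1, p.tps_smoothing)
    alloc = distribute_residuals(tpred, sp_fine, fine_t1, ratio, cmap)
    prelim = fine_t1.with_values(tpred.tp_fine.values + alloc.values)
    refined = neighborhood_refine(prelim, fine_t1, p, ratio)
    out = fine_t1.with_values(np.clip(refined.values, -1.0, 1.0))
    logger.info(
        "fsdaf: delta_class=%s residual mean abs=%.5f",
        np.array2string(tpred.delta_class, precision=4),
        float(np.nanmean(np.abs(tpred.residual.values))),
    )
    if return_diagnostics:
        diag = {
            "delta_class": tpred.delta_class,
            "residual": tpred.residual,
            "tp_fine": tpred.tp_fine,
            "sp_fine": sp_fine,
            "class_map": cmap,
        }
        return out, diag
    return out
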