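"""Yield-monitor preprocessing, NDVI-yield regression and accuracy metrics.

Harvest-track points are cleaned with a moving-window 3-standard-
deviation rule (leave-one-out statistics), rasterised to fine cells,
paired with NDVI pixels, and fed to an ordinary-least-squares linear
model ``yield = a * NDVI + b`` evaluated with R² and RMSE.  Fusion
accuracy against a fine reference uses the coefficient of determination
of the fused-on-reference regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy

from .errors import DegenerateFitError, DomainError
from .io_grid import GridRaster, PlotPolygon, SceneStack

logger = logging.getLogger(__name__)

__all__ = [
    "YieldPoints",
    "YieldModelFit",
    "rasterize_yield",
    "filter_outliers",
    "pair_ndvi_yield",
    "fit_yield_model",
    "r2_adj",
    "correlation_by_date",
    "read_yield_points",
    "write_yield_points",
]

DEFAULT_OUTLIER_WINDOW = 21
YIELD_CELL_SIZE = 0.5  # metres, yield-map rasterisation cell


@dataclass
class YieldPoints:
    """Georeferenced yield-monitor records in harvest-track order."""

    x: np.ndarray
    y: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not (self.x.shape == self.y.shape == self.value.shape):
            raise ValueError("x, y and value must have equal length")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class YieldModelFit:
    a: float  # slope, yield units per NDVI
    b: float  # intercept, yield units
    r2: float
    rmse: float
    n: int


def read_yield_points(path) -> YieldPoints:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        return YieldPoints(
            df[cols["x"]].to_numpy(),
            df[cols["y"]].to_numpy(),
            df[cols["yield"]].to_numpy(),
        )
    except KeyError as exc:
        raise ValueError(f"yield CSV must have columns x, y, yield: {exc}") from exc


def write_yield_points(pts: YieldPoints, path) -> None:
    pd.DataFrame({"x": pts.x, "y": pts.y, "yield": pts.value}).to_csv(
        path, index=False
    )


def rasterize_yield(pts: YieldPoints, cell: float = YIELD_CELL_SIZE) -> GridRaster:
    """Bin points to a square grid; each cell holds the mean of its points.

    The grid origin snaps to multiples of ``cell`` just outside the
    point cloud; empty cells are nodata.
    """
    if len(pts) == 0:
        raise DomainError("cannot rasterize an empty point set")
    if cell <= 0:
        raise DomainError("cell size must be positive")
    ox = np.floor(pts.x.min() / cell) * cell
    oy = np.ceil(pts.y.max() / cell) * cell
    cols = np.floor((pts.x - ox) / cell).astype(int)
    rows = np.floor((oy - pts.y) / cell).astype(int)
    nrow, ncol = rows.max() + 1, cols.max() + 1
    total = np.zeros((nrow, ncol))
    count = np.zeros((nrow, ncol))
    np.add.at(total, (rows, cols), pts.value)
    np.add.at(count, (rows, cols), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / count, np.nan)
    return GridRaster(out, ox, oy, cell)


def filter_outliers(
    pts: YieldPoints, window: int = DEFAULT_OUTLIER_WINDOW
) -> YieldPoints:
    """Moving-window 3-SD outlier removal along the harvest track.

    For each point, the mean and (sample) SD of the surrounding window
    are computed excluding the candidate itself; the point is removed
    iff it deviates from that mean by more than 3 SD.  All decisions
    are taken against the original values in a single pass.
    """
    if window < 3:
        raise DomainError("window must be >= 3")
    v = pts.value
    n = len(v)
    half = window // 2
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neigh = np.concatenate([v[lo:i], v[i + 1 : hi]])
        if neigh.size < 2:
            continue
        mu = neigh.mean()
        sd = neigh.std(ddof=1)
        if abs(v[i] - mu) > 3.0 * sd:
            keep[i] = False
    return YieldPoints(pts.x[keep], pts.y[keep], v[keep])


def pair_ndvi_yield(
    ndvi: GridRaster, yld: GridRaster, plot: PlotPolygon
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each in-plot NDVI pixel with the mean yield inside its footprint.

    ``yld`` must be on a strictly finer grid.  NDVI pixels whose
    footprint contains no populated yield cell are dropped.
    """
    if yld.pixel_size >= ndvi.pixel_size:
        raise DomainError("yield raster must be finer than the NDVI raster")
    xs = ndvi.x_centers()
    ys = ndvi.y_centers()
    gx, gy = np.meshgrid(xs, ys)
    inside = contains_xy(plot.geometry, gx.ravel(), gy.ravel()).reshape(ndvi.shape)
    yx = yld.x_centers()
    yy = yld.y_centers()
    ndvi_out = []
    yld_out = []
    ps = ndvi.pixel_size
    for r, c in zip(*np.nonzero(inside)):
        x0 = ndvi.origin_x + c * ps
        y0 = ndvi.origin_y - (r + 1) * ps
        csel = (yx >= x0) & (yx < x0 + ps)
        rsel = (yy > y0) & (yy <= y0 + ps)
        block = yld.values[np.ix_(np.nonzero(rsel)[0], np.nonzero(csel)[0])]
        good = np.isfinite(block)
        nv = ndvi.values[r, c]
        if good.any() and np.isfinite(nv):
            ndvi_out.append(nv)
            yld_out.append(float(block[good].mean()))
    if not ndvi_out:
        raise DomainError("no NDVI/yield pairs inside the plot")
    return np.asarray(ndvi_out), np.asarray(yld_out)


def fit_yield_model(
    pairs: tuple[Sequence[float], Sequence[float]]
) -> YieldModelFit:
    """OLS fit of ``yield = a * ndvi + b`` with R² and RMSE."""
    x = np.asarray(pairs[0], dtype=float)
    y = np.asarray(pairs[1], dtype=float)
    if x.size < 3:
        raise DegenerateFitError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant NDVI predictor")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return YieldModelFit(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        rmse,
        int(x.size),
    )


def r2_adj(
    fused: Sequence[float], reference: Sequence[float], literal: bool = False
) -> float:
    """Agreement of fused values with a fine reference.

    Default: the coefficient of determination (squared Pearson r) of the
    least-squares line of fused on reference — always in [0, 1].  With
    ``literal=True`` the raw variance-ratio form
    ``sum((ref - mean_ref)^2) / sum((fused - mean_ref)^2)`` is returned
    instead (not bounded by 1; provided for comparison only).
    """
    f = np.asarray(fused, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape or f.size < 3:
        raise DegenerateFitError("need equal-length inputs with >= 3 samples")
    if np.ptp(r) == 0:
        raise DegenerateFitError("constant reference values")
    if literal:
        rbar = r.mean()
        denom = np.sum((f - rbar) ** 2)
        if denom == 0:
            raise DegenerateFitError("fused values identical to reference mean")
        return float(np.sum((r - rbar) ** 2) / denom)
    if np.ptp(f) == 0:
        return 0.0
    rho = np.corrcoef(f, r)[0, 1]
    return float(rho**2)


def correlation_by_date(
    stacks: Sequence[SceneStack],
    yld: GridRaster,
    plot: PlotPolygon,
) -> list[pd.Series]:
    """Pearson r between per-date NDVI and yield, one series per stack.

    Dates with fewer than 3 valid pairs are reported as NaN.
    """
    out = []
    for stack in stacks:
        corr = {}
        for doy in stack.doys:
            try:
                x, y = pair_ndvi_yield(stack[doy], yld, plot)
            except DomainError:
                corr[doy] = np.nan
                continue
            if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                corr[doy] = np.nan
                continue
            corr[doy] = float(np.corrcoef(x, y)[0, 1])
        out.append(pd.Series(corr, name=f"ratio{stack.ratio}"))
    return out
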