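"""Raster/vector I/O, grid alignment and integer-ratio aggregation.

Rasters live on north-up planar grids: ``(origin_x, origin_y)`` is the
outer corner of pixel ``(row 0, col 0)``, rows increase southward and
arrays are row-major with 0-based indices.  Nodata is carried internally
as NaN; the sentinel value is only used on disk.

GeoTIFF is read and written through :mod:`tifffile` using the standard
georeferencing tags (ModelPixelScale 33550, ModelTiepoint 33922,
GDAL_NODATA 42113).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import MultiPolygon, Polygon, shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

from .errors import (
    CoverageError,
    GeometryError,
    GridAlignmentError,
    ShapeError,
    UnsupportedGridError,
)

__all__ = [
    "GridRaster",
    "SceneStack",
    "BandMapping",
    "PlotPolygon",
    "read_raster",
    "write_raster",
    "compute_ndvi",
    "block_aggregate",
    "resample_to_integer_grid",
    "read_plots",
]

_GRID_TOL = 1e-6

#: GeoTIFF tag codes used for georeferencing.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class GridRaster:
    """A 2-D single-band raster on a square-pixel planar grid.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells.
    origin_x, origin_y
        Planar coordinates of the outer (north-west) corner of pixel
        ``(0, 0)``.
    pixel_size
        Edge length of a (square) pixel in metres.
    nodata
        Sentinel written to disk in place of NaN.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 30.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ShapeError("raster values must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise UnsupportedGridError("pixel_size must be positive")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where nodata."""
        return np.isnan(self.values)

    def x_centers(self) -> np.ndarray:
        ncol = self.shape[1]
        return self.origin_x + (np.arange(ncol) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        nrow = self.shape[0]
        return self.origin_y - (np.arange(nrow) + 0.5) * self.pixel_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster extent."""
        nrow, ncol = self.shape
        return (
            self.origin_x,
            self.origin_y - nrow * self.pixel_size,
            self.origin_x + ncol * self.pixel_size,
            self.origin_y,
        )

    def same_grid(self, other: "GridRaster", tol: float = _GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )

    def with_values(self, values: np.ndarray) -> "GridRaster":
        """New raster on the same grid holding ``values``."""
        return GridRaster(
            np.asarray(values, dtype=float),
            self.origin_x,
            self.origin_y,
            self.pixel_size,
            self.nodata,
        )

    def copy(self) -> "GridRaster":
        return self.with_values(self.values.copy())


@dataclass
class SceneStack:
    """Date-indexed collection of rasters sharing one grid.

    ``ratio`` records the coarse/fine integer edge ratio relative to the
    companion fine grid (1 for the fine stack itself).
    """

    rasters: Mapping[int, GridRaster]
    ratio: int = 1

    def __post_init__(self) -> None:
        if int(self.ratio) != self.ratio or self.ratio < 1:
            raise UnsupportedGridError("ratio must be a positive integer")
        self.ratio = int(self.ratio)
        doys = list(self.rasters.keys())
        if doys != sorted(doys) or len(set(doys)) != len(doys):
            raise ValueError("DOY keys must be strictly increasing")
        for d in doys:
            if not 1 <= d <= 366:
                raise ValueError(f"DOY {d} outside [1, 366]")
        rs = list(self.rasters.values())
        for r in rs[1:]:
            if not r.same_grid(rs[0]):
                raise GridAlignmentError("stack rasters must share one grid")

    @property
    def doys(self) -> list[int]:
        return list(self.rasters.keys())

    def __getitem__(self, doy: int) -> GridRaster:
        return self.rasters[doy]

    def __iter__(self) -> Iterator[int]:
        return iter(self.rasters)

    def __len__(self) -> int:
        return len(self.rasters)


#: Fine-sensor band -> coarse-sensor band correspondence for the six
#: shared reflective bands (blue, green, red, NIR, SWIR1, SWIR2).
DEFAULT_BAND_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 3),
    (2, 4),
    (3, 1),
    (4, 2),
    (5, 6),
    (7, 7),
)


@dataclass(frozen=True)
class BandMapping:
    """Ordered fine-band/coarse-band index pairs."""

    pairs: tuple[tuple[int, int], ...] = DEFAULT_BAND_PAIRS

    def coarse_band(self, fine_band: int) -> int:
        for f, c in self.pairs:
            if f == fine_band:
                return c
        raise KeyError(f"fine band {fine_band} has no coarse counterpart")


@dataclass
class PlotPolygon:
    """A named plot boundary in the rasters' planar coordinates."""

    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not isinstance(self.geometry, (Polygon, MultiPolygon)):
            raise GeometryError(
                f"plot '{self.name}' must be a (multi)polygon, "
                f"got {self.geometry.geom_type}"
            )
        if not self.geometry.is_valid:
            raise GeometryError(f"plot '{self.name}' geometry is invalid")
        if self.geometry.is_empty:
            raise GeometryError(f"plot '{self.name}' geometry is empty")


# ---------------------------------------------------------------------------
# raster I/O


def read_raster(path: str | Path, format: str = "GTiff") -> GridRaster:
    """Read a single-band GeoTIFF into a :class:`GridRaster`.

    The geotransform is taken from the ModelPixelScale/ModelTiepoint
    tags; non-square pixels are rejected.  Cells equal to the
    GDAL_NODATA sentinel become NaN.
    """
    path = Path(path)
    if format != "GTiff":
        raise UnsupportedGridError(f"unsupported raster format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = np.asarray(page.asarray(), dtype=float)
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        scale = tuple(scale_tag.value) if scale_tag is not None else None
        tie = tuple(tie_tag.value) if tie_tag is not None else None
        nodata_raw = nodata_tag.value if nodata_tag is not None else None
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise UnsupportedGridError("only single-band rasters are supported")
    if scale is None or tie is None:
        raise UnsupportedGridError(f"{path} lacks georeferencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-9, abs_tol=1e-9):
        raise UnsupportedGridError(
            f"non-square pixels ({sx} x {sy}) are not supported"
        )
    # tiepoint: raster (i, j, k) -> model (x, y, z); we require the
    # conventional corner anchor at raster (0, 0).
    origin_x = float(tie[3]) - float(tie[0]) * sx
    origin_y = float(tie[4]) + float(tie[1]) * sy
    nodata = -9999.0
    if nodata_raw is not None:
        if isinstance(nodata_raw, bytes):
            nodata_raw = nodata_raw.decode()
        nodata = float(str(nodata_raw).strip("\x00").strip())
        if math.isnan(nodata):
            pass
        else:
            arr = np.where(arr == np.float32(nodata), np.nan, arr)
    return GridRaster(arr, origin_x, origin_y, sx, nodata)


def write_raster(r: GridRaster, path: str | Path) -> None:
    """Write a :class:`GridRaster` as a single-band float32 GeoTIFF."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory {path.parent} does not exist")
    arr = np.asarray(r.values, dtype=np.float32)
    arr = np.where(np.isnan(arr), np.float32(r.nodata), arr)
    ps = float(r.pixel_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(r.origin_x), float(r.origin_y), 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(r.nodata))),
    ]
    try:
        tifffile.imwrite(path, arr, extratags=extratags)
    except PermissionError as exc:  # pragma: no cover - OS dependent
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# grid arithmetic


def compute_ndvi(red: GridRaster, nir: GridRaster) -> GridRaster:
    """(NIR - Red)/(NIR + Red) per pixel; 0/0 pixels become nodata."""
    if not red.same_grid(nir):
        raise GridAlignmentError("red and nir rasters must share a grid")
    for name, band in (("red", red), ("nir", nir)):
        finite = band.values[np.isfinite(band.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"{name} reflectance outside [0, 1]")
    denom = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir.values - red.values) / denom, np.nan)
    return red.with_values(out)


def block_aggregate(fine: GridRaster, ratio: int) -> GridRaster:
    """Aggregate ``ratio`` x ``ratio`` fine blocks to their nodata-ignoring mean."""
    ratio = int(ratio)
    if ratio < 1:
        raise ShapeError("ratio must be a positive integer")
    nrow, ncol = fine.shape
    if nrow % ratio or ncol % ratio:
        raise ShapeError(
            f"raster shape {fine.shape} not divisible by ratio {ratio}"
        )
    blocks = fine.values.reshape(nrow // ratio, ratio, ncol // ratio, ratio)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        out = np.nanmean(blocks, axis=(1, 3))
    return GridRaster(
        out,
        fine.origin_x,
        fine.origin_y,
        fine.pixel_size * ratio,
        fine.nodata,
    )


def resample_to_integer_grid(
    coarse: GridRaster, fine: GridRaster, ratio: int
) -> GridRaster:
    """Nearest-neighbour resampling onto the integer-aligned coarse grid.

    The target grid is the fine grid coarsened by ``ratio``; each target
    cell takes the value of the input cell whose center is nearest to the
    target cell center.
    """
    ratio = int(ratio)
    if ratio < 1:
        raise ShapeError("ratio must be a positive integer")
    nrow, ncol = fine.shape
    if nrow % ratio or ncol % ratio:
        raise ShapeError(
            f"fine shape {fine.shape} not divisible by ratio {ratio}"
        )
    cxmin, cymin, cxmax, cymax = coarse.bounds
    fxmin, fymin, fxmax, fymax = fine.bounds
    tol = _GRID_TOL
    if cxmin > fxmin + tol or cymin > fymin + tol or cxmax < fxmax - tol or cymax < fymax - tol:
        raise CoverageError("coarse raster does not cover the fine extent")
    tgt_ps = fine.pixel_size * ratio
    tx = fine.origin_x + (np.arange(ncol // ratio) + 0.5) * tgt_ps
    ty = fine.origin_y - (np.arange(nrow // ratio) + 0.5) * tgt_ps
    # nearest center per axis; exact ties resolve to the north/west cell
    cols = np.ceil((tx - coarse.origin_x) / coarse.pixel_size - 1.0).astype(int)
    rows = np.ceil((coarse.origin_y - ty) / coarse.pixel_size - 1.0).astype(int)
    cols = np.clip(cols, 0, coarse.shape[1] - 1)
    rows = np.clip(rows, 0, coarse.shape[0] - 1)
    out = coarse.values[np.ix_(rows, cols)]
    return GridRaster(out, fine.origin_x, fine.origin_y, tgt_ps, coarse.nodata)


# ---------------------------------------------------------------------------
# vector I/O


def read_plots(path: str | Path) -> list[PlotPolygon]:
    """Read plot polygons from a GeoJSON feature collection.

    Features must carry a ``name`` (or ``Name``/``id``) property; invalid
    geometries raise :class:`GeometryError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".shp", ".dbf", ".shx"}:
        raise UnsupportedGridError(
            "ESRI Shapefile reading is not available in this build; "
            "convert to GeoJSON"
        )
    data = json.loads(path.read_text())
    features = data.get("features", [])
    plots: list[PlotPolygon] = []
    for i, feat in enumerate(features):
        geom = _shapely_shape(feat["geometry"])
        props = feat.get("properties") or {}
        name = props.get("name") or props.get("Name") or props.get("id") or str(i)
        plots.append(PlotPolygon(str(name), geom))
    return plots


def write_plots(plots: Sequence[PlotPolygon], path: str | Path) -> None:
    """Write plots as a GeoJSON feature collection."""
    from shapely.geometry import mapping

    features = [
        {
            "type": "Feature",
            "properties": {"name": p.name},
            "geometry": mapping(p.geometry),
        }
        for p in plots
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
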