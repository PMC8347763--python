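"""Synthetic fine/coarse NDVI scenes with known ground truth.

A fine grid is partitioned into crop plots and background covers (other
crops, fallow, a road), each following its own seasonal rise-and-fall
logistic NDVI curve, modulated by a smooth within-field texture.  Coarse
stacks are exact block means of the fine stack plus optional Gaussian
noise; per-pixel yield is a linear function of peak-season NDVI plus
noise.  Everything is deterministic for a fixed seed and the noise-free
truth is retained so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely import contains_xy
from shapely.affinity import translate
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError
from .io_grid import GridRaster, PlotPolygon, SceneStack, block_aggregate
from .yield_model import YieldPoints

__all__ = [
    "GrowthCurve",
    "SceneConfig",
    "SceneBundle",
    "growth_value",
    "generate_scene",
    "make_mixing_ladder",
    "default_scene_config",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Double-logistic seasonal NDVI curve."""

    base: float
    amplitude: float
    rise_mid: float
    fall_mid: float
    rise_rate: float = 0.12
    fall_rate: float = 0.12

    def __post_init__(self) -> None:
        if self.base < 0 or self.base + self.amplitude > 1:
            raise ValueError("curve must stay within [0, 1]")
        if self.amplitude > 0 and not self.rise_mid < self.fall_mid:
            raise ValueError("rise_mid must precede fall_mid")


def growth_value(c: GrowthCurve, doy: float) -> float:
    """Curve value at ``doy``: base + amplitude * (rise - fall logistic)."""
    rise = 1.0 / (1.0 + math.exp(-c.rise_rate * (doy - c.rise_mid)))
    fall = 1.0 / (1.0 + math.exp(-c.fall_rate * (doy - c.fall_mid)))
    return float(np.clip(c.base + c.amplitude * (rise - fall), 0.0, 1.0))


@dataclass(frozen=True)
class CoverRegion:
    """A polygon painted with a named cover; later regions overpaint."""

    cover: str
    geometry: BaseGeometry


@dataclass
class SceneConfig:
    fine_shape: tuple[int, int] = (96, 96)
    fine_pixel: float = 30.0
    ratios: tuple[int, ...] = (8, 16)
    doys: tuple[int, ...] = (150, 174, 190, 206, 222, 230, 246, 254, 270)
    covers: dict[str, GrowthCurve] = field(default_factory=dict)
    default_cover: str = "fallow"
    regions: tuple[CoverRegion, ...] = ()
    plots: tuple[tuple[str, str], ...] = ()  # (plot name, region cover) pairs
    plot_geoms: dict[str, BaseGeometry] = field(default_factory=dict)
    texture_amplitude: float = 0.10
    texture_sigma: float = 4.0  # fine pixels
    noise_sd_fine: float = 0.0
    noise_sd_coarse: float = 0.0
    yield_a: float = 2.5
    yield_b: float = 0.3
    yield_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.ratios:
            if self.fine_shape[0] % r or self.fine_shape[1] % r:
                raise ValueError(
                    f"fine_shape {self.fine_shape} not divisible by ratio {r}"
                )
        if min(self.noise_sd_fine, self.noise_sd_coarse, self.yield_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def origin(self) -> tuple[float, float]:
        return 0.0, self.fine_shape[0] * self.fine_pixel

    @property
    def extent(self) -> BaseGeometry:
        ox, oy = self.origin
        return box(ox, oy - self.fine_shape[0] * self.fine_pixel,
                   ox + self.fine_shape[1] * self.fine_pixel, oy)


@dataclass
class SceneBundle:
    """Everything a downstream stage needs, including noise-free truth."""

    config: SceneConfig
    fine: SceneStack
    coarse: dict[int, SceneStack]
    truth_fine: SceneStack
    truth_coarse: dict[int, SceneStack]
    plots: list[PlotPolygon]
    cover_labels: np.ndarray  # cover index per fine pixel
    cover_names: list[str]
    yield_points: YieldPoints
    truth_peak: GridRaster  # per-pixel seasonal max of noise-free NDVI


def default_scene_config(**overrides) -> SceneConfig:
    """Three-plot layout echoing a field-scale study design.

    Plot A is aligned to the coarsest blocks, plot B is irregular and
    split by a road strip, plot C is offset so its boundary cuts coarse
    pixels; the surroundings mix two other crops, fallow land and the
    road.
    """
    covers = {
        "cotton": GrowthCurve(0.15, 0.70, 185.0, 262.0, 0.15, 0.12),
        "crop2": GrowthCurve(0.12, 0.55, 165.0, 240.0, 0.12, 0.10),
        "crop3": GrowthCurve(0.10, 0.45, 200.0, 280.0, 0.10, 0.12),
        "fallow": GrowthCurve(0.12, 0.06, 170.0, 260.0, 0.05, 0.05),
        "road": GrowthCurve(0.05, 0.0, 150.0, 250.0),
    }
    shape = tuple(overrides.get("fine_shape", (96, 96)))
    pixel = float(overrides.get("fine_pixel", 30.0))
    ratios = tuple(overrides.get("ratios", (8, 16)))
    height = shape[0] * pixel
    width = shape[1] * pixel
    ce = max(ratios) * pixel  # coarsest block edge, for aligning plot A

    def snap(v: float) -> float:
        return round(v / ce) * ce

    # plot A snaps to whole coarse blocks (pure pixels by construction)
    plot_a = box(snap(0.17 * width), snap(0.50 * height),
                 snap(0.50 * width), snap(0.83 * height))
    # plot B: irregular, split by a road strip covering ~13% of its box
    plot_b_outer = box(0.573 * width, 0.542 * height,
                       0.906 * width, 0.854 * height)
    road = box(0.573 * width, 0.678 * height, 0.906 * width, 0.718 * height)
    plot_b = plot_b_outer.difference(road)
    # plot C: deliberately offset so its boundary cuts coarse pixels
    plot_c = box(0.115 * width, 0.115 * height, 0.448 * width, 0.427 * height)
    regions = (
        CoverRegion("crop2", box(0.0, 0.0, 0.5 * width, height)),
        CoverRegion("crop3", box(0.5 * width, 0.0, width, 0.5 * height)),
        CoverRegion("cotton", plot_a),
        CoverRegion("cotton", plot_b_outer),
        CoverRegion("road", road),
        CoverRegion("cotton", plot_c),
    )
    cfg = SceneConfig(
        covers=covers,
        default_cover="fallow",
        regions=regions,
        plots=(("A", "cotton"), ("B", "cotton"), ("C", "cotton")),
        plot_geoms={"A": plot_a, "B": plot_b, "C": plot_c},
    )
    return replace(cfg, **overrides) if overrides else cfg


def _cover_map(cfg: SceneConfig) -> tuple[np.ndarray, list[str]]:
    names = list(cfg.covers.keys())
    idx = {n: i for i, n in enumerate(names)}
    nrow, ncol = cfg.fine_shape
    ox, oy = cfg.origin
    xs = ox + (np.arange(ncol) + 0.5) * cfg.fine_pixel
    ys = oy - (np.arange(nrow) + 0.5) * cfg.fine_pixel
    gx, gy = np.meshgrid(xs, ys)
    labels = np.full((nrow, ncol), idx[cfg.default_cover], dtype=int)
    for region in cfg.regions:
        if not region.geometry.intersects(cfg.extent):
            raise GeometryError(
                f"region for cover '{region.cover}' lies outside the scene"
            )
        inside = contains_xy(region.geometry, gx.ravel(), gy.ravel())
        labels.ravel()[inside] = idx[region.cover]
    return labels, names


def _texture(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1]."""
    if cfg.texture_amplitude <= 0:
        return np.ones(cfg.fine_shape)
    raw = gaussian_filter(rng.standard_normal(cfg.fine_shape), cfg.texture_sigma)
    lo, hi = raw.min(), raw.max()
    unit = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    return 1.0 - cfg.texture_amplitude * unit


def generate_scene(cfg: SceneConfig) -> SceneBundle:
    """Build fine/coarse stacks, plots, yield points and retained truth."""
    rng = np.random.default_rng(cfg.seed)
    labels, names = _cover_map(cfg)
    texture = _texture(cfg, rng)
    nrow, ncol = cfg.fine_shape
    ox, oy = cfg.origin

    curves = [cfg.covers[n] for n in names]
    truth_rasters: dict[int, GridRaster] = {}
    fine_rasters: dict[int, GridRaster] = {}
    for doy in cfg.doys:
        base = np.array([c.base for c in curves])[labels]
        season = np.array(
            [growth_value(c, doy) - c.base for c in curves]
        )[labels]
        vals = np.clip(base + texture * season, 0.0, 1.0)
        truth_rasters[doy] = GridRaster(vals, ox, oy, cfg.fine_pixel)
        noisy = vals
        if cfg.noise_sd_fine > 0:
            noisy = np.clip(
                vals + rng.normal(0.0, cfg.noise_sd_fine, vals.shape), -1.0, 1.0
            )
        fine_rasters[doy] = GridRaster(noisy, ox, oy, cfg.fine_pixel)

    truth_fine = SceneStack(dict(sorted(truth_rasters.items())), ratio=1)
    fine = SceneStack(dict(sorted(fine_rasters.items())), ratio=1)

    coarse: dict[int, SceneStack] = {}
    truth_coarse: dict[int, SceneStack] = {}
    for ratio in cfg.ratios:
        cs: dict[int, GridRaster] = {}
        ts: dict[int, GridRaster] = {}
        for doy in cfg.doys:
            agg = block_aggregate(fine[doy], ratio)
            ts[doy] = block_aggregate(truth_fine[doy], ratio)
            vals = agg.values
            if cfg.noise_sd_coarse > 0:
                vals = np.clip(
                    vals + rng.normal(0.0, cfg.noise_sd_coarse, vals.shape),
                    -1.0,
                    1.0,
                )
            cs[doy] = agg.with_values(vals)
        coarse[ratio] = SceneStack(cs, ratio=ratio)
        truth_coarse[ratio] = SceneStack(ts, ratio=ratio)

    plots = []
    for name, _cover in cfg.plots:
        geom = cfg.plot_geoms[name]
        if not geom.intersects(cfg.extent):
            raise GeometryError(f"plot '{name}' lies outside the scene extent")
        plots.append(PlotPolygon(name, geom))

    truth_peak = GridRaster(
        np.max(np.stack([truth_fine[d].values for d in cfg.doys]), axis=0),
        ox,
        oy,
        cfg.fine_pixel,
    )

    xs = ox + (np.arange(ncol) + 0.5) * cfg.fine_pixel
    ys = oy - (np.arange(nrow) + 0.5) * cfg.fine_pixel
    gx, gy = np.meshgrid(xs, ys)
    in_any = np.zeros((nrow, ncol), dtype=bool)
    for p in plots:
        in_any |= contains_xy(p.geometry, gx.ravel(), gy.ravel()).reshape(
            nrow, ncol
        )
    px = gx[in_any]
    py = gy[in_any]
    peak = truth_peak.values[in_any]
    yld = cfg.yield_a * peak + cfg.yield_b
    if cfg.yield_noise_sd > 0:
        yld = yld + rng.normal(0.0, cfg.yield_noise_sd, yld.shape)
    yield_points = YieldPoints(px, py, yld)

    return SceneBundle(
        cfg,
        fine,
        coarse,
        truth_fine,
        truth_coarse,
        plots,
        labels,
        names,
        yield_points,
        truth_peak,
    )


def make_mixing_ladder(
    cfg: SceneConfig,
    offsets: Sequence[float],
    plot_name: str = "C",
) -> list[SceneBundle]:
    """Scenes identical except one plot slides eastward by each offset."""
    scenes = []
    base_geom = cfg.plot_geoms[plot_name]
    cover = dict(cfg.plots)[plot_name]
    for off in offsets:
        geom = translate(base_geom, xoff=float(off))
        if not geom.within(cfg.extent):
            raise GeometryError(
                f"offset {off} pushes plot '{plot_name}' outside the extent"
            )
        regions = tuple(
            CoverRegion(r.cover, geom)
            if r.geometry.equals(base_geom) and r.cover == cover
            else r
            for r in cfg.regions
        )
        geoms = dict(cfg.plot_geoms)
        geoms[plot_name] = geom
        scenes.append(
            generate_scene(replace(cfg, regions=regions, plot_geoms=geoms))
        )
    return scenes
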