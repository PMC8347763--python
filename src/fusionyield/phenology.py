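"""Per-plot NDVI time series and growing-season stage selection.

Seasonal stages are read off the daily-interpolated series and its
finite-difference derivative: the season starts when the (smoothed)
derivative first exceeds a rise threshold, reaches its middle when the
derivative falls back below a plateau threshold, peaks at the maximum
NDVI and ends at the first post-peak date with non-positive derivative
and NDVI below a fraction of the peak.  Selected dates snap to the
available fine-image observation dates, since a reference image must
actually exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely import contains_xy

from .errors import CoverageError, DomainError, InterpolationError, StageDetectionError
from .io_grid import PlotPolygon, SceneStack

__all__ = [
    "NDVISeries",
    "StageSelection",
    "StageThresholds",
    "extract_series",
    "interpolate_daily",
    "derivative",
    "identify_stages",
]


@dataclass
class NDVISeries:
    doy: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.doy.shape != self.value.shape:
            raise ValueError("doy and value must have equal length")
        if self.doy.size and np.any(np.diff(self.doy) <= 0):
            raise ValueError("DOYs must be strictly increasing")

    def __len__(self) -> int:
        return self.doy.size

    def at(self, doy: int) -> float:
        idx = np.searchsorted(self.doy, doy)
        if idx >= len(self.doy) or self.doy[idx] != doy:
            raise KeyError(f"DOY {doy} not in series")
        return float(self.value[idx])


@dataclass(frozen=True)
class StageSelection:
    early_doy: int
    middle_doy: int
    end_doy: int
    peak_doy: int

    def __post_init__(self) -> None:
        if not (self.early_doy < self.middle_doy <= self.peak_doy <= self.end_doy):
            raise StageDetectionError(
                f"stage ordering violated: early={self.early_doy} "
                f"middle={self.middle_doy} peak={self.peak_doy} end={self.end_doy}"
            )


@dataclass(frozen=True)
class StageThresholds:
    """Config defaults for stage detection (NDVI/day and peak fraction)."""

    rise: float = 0.004
    plateau: float = 0.002
    end_fraction: float = 0.9
    smooth_days: int = 7


def extract_series(stack: SceneStack, plot: PlotPolygon) -> NDVISeries:
    """Per-date mean NDVI over pixels whose centers fall inside the plot."""
    first = next(iter(stack.rasters.values()))
    xs = first.x_centers()
    ys = first.y_centers()
    gx, gy = np.meshgrid(xs, ys)
    inside = contains_xy(plot.geometry, gx.ravel(), gy.ravel()).reshape(first.shape)
    if not inside.any():
        raise CoverageError(
            f"no pixel centers inside plot '{plot.name}'"
        )
    doys = stack.doys
    vals = [float(np.nanmean(stack[d].values[inside])) for d in doys]
    return NDVISeries(np.array(doys), np.array(vals), plot.name)


def interpolate_daily(s: NDVISeries) -> NDVISeries:
    """Piecewise-linear values at every integer DOY spanning the series."""
    if len(s) < 2:
        raise InterpolationError("need at least 2 observations to interpolate")
    days = np.arange(s.doy[0], s.doy[-1] + 1)
    vals = np.interp(days, s.doy, s.value)
    return NDVISeries(days, vals, s.label)


def derivative(s: NDVISeries) -> NDVISeries:
    """Central finite differences (one-sided at the ends), NDVI per day."""
    if len(s) < 2:
        raise DomainError("need at least 2 samples to differentiate")
    d = np.gradient(s.value, s.doy.astype(float))
    return NDVISeries(s.doy, d, s.label)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: values.size]


def identify_stages(
    s: NDVISeries,
    obs_doys: Sequence[int],
    thresholds: StageThresholds = StageThresholds(),
) -> StageSelection:
    """Select early/middle/end reference dates and the season peak.

    ``s`` should be a daily (interpolated) series spanning the season;
    ``obs_doys`` are the dates for which fine images actually exist.
    """
    obs = np.asarray(sorted(obs_doys), dtype=int)
    if obs.size == 0:
        raise StageDetectionError("no observation dates supplied")
    obs = obs[(obs >= s.doy[0]) & (obs <= s.doy[-1])]
    if obs.size == 0:
        raise StageDetectionError("no observation dates within the series span")
    deriv = derivative(s)
    sm = _smooth(deriv.value, thresholds.smooth_days)

    obs_vals = np.interp(obs, s.doy, s.value)
    peak_doy = int(obs[np.argmax(obs_vals)])
    peak_val = float(np.max(s.value))

    rising = np.nonzero(sm > thresholds.rise)[0]
    if rising.size == 0:
        raise StageDetectionError("no rise phase found (derivative never "
                                  f"exceeds {thresholds.rise}/day)")
    rise_start_doy = int(s.doy[rising[0]])
    early_candidates = obs[obs >= rise_start_doy]
    if early_candidates.size == 0:
        raise StageDetectionError("no observation date at or after the rise onset")
    early_doy = int(early_candidates[0])

    after_rise = np.nonzero((s.doy > rise_start_doy) & (sm < thresholds.plateau))[0]
    if after_rise.size == 0:
        raise StageDetectionError("derivative never settles below the plateau "
                                  "threshold after the rise")
    plateau_doy = int(s.doy[after_rise[0]])
    middle_doy = int(obs[np.argmin(np.abs(obs - plateau_doy))])

    post_peak = (s.doy > peak_doy) & (sm <= 0) & (
        s.value < thresholds.end_fraction * peak_val
    )
    idx = np.nonzero(post_peak)[0]
    if idx.size == 0:
        raise StageDetectionError("no end-of-season decline found after the peak")
    end_start_doy = int(s.doy[idx[0]])
    end_candidates = obs[obs >= end_start_doy]
    if end_candidates.size == 0:
        raise StageDetectionError("no observation date in the decline phase")
    end_doy = int(end_candidates[0])

    return StageSelection(early_doy, middle_doy, end_doy, peak_doy)
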