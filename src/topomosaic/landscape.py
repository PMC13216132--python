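"""Pixel classification, landscape tiling and landscape-level aggregation.

Continuous percent tree cover is binarized at a threshold (65% by default,
the frequency minimum between the open and closed cover modes in the study
region); the grid is then divided into square non-overlapping landscape
tiles, each classified from its class fractions:

* ``excluded`` — under 75% of the tile's pixels are valid;
* ``mosaic`` — both open and closed fractions in [0.05, 0.95];
* ``homogeneous_closed`` / ``homogeneous_open`` — otherwise.

Boundary conventions (documented, tested): "closed" requires percent cover
strictly above the threshold; the mosaic bounds are inclusive.  Class
fractions are computed over valid pixels, the valid fraction over all tile
pixels.  Trailing partial tiles are dropped rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelmax

from .raster import Raster

__all__ = [
    "DEFAULT_THRESHOLD",
    "BimodalityError",
    "LandscapeWindow",
    "tile_grid",
    "find_bimodal_threshold",
    "classify_pixels",
    "classify_landscape",
    "aggregate_to_landscapes",
    "composition_histogram",
    "build_landscape_table",
]

#: pipeline default when bimodality detection is skipped (percent tree cover)
DEFAULT_THRESHOLD = 65.0

MOSAIC_BOUNDS = (0.05, 0.95)
MIN_VALID_FRACTION = 0.75


class BimodalityError(ValueError):
    """Raised when a cover distribution does not show two modes."""


@dataclass(frozen=True)
class LandscapeWindow:
    """One tile: id plus half-open pixel bounds (row0, row1, col0, col1)."""

    tile_id: int
    row0: int
    row1: int
    col0: int
    col1: int

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return (self.row0, self.row1, self.col0, self.col1)

    @property
    def size(self) -> int:
        return self.row1 - self.row0

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))


def tile_grid(shape: tuple[int, int], tile_size: int) -> list[LandscapeWindow]:
    """Non-overlapping tiles covering the grid; trailing partials dropped."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    rows, cols = shape
    windows = []
    tid = 0
    for r0 in range(0, rows - tile_size + 1, tile_size):
        for c0 in range(0, cols - tile_size + 1, tile_size):
            windows.append(LandscapeWindow(tid, r0, r0 + tile_size, c0, c0 + tile_size))
            tid += 1
    return windows


def find_bimodal_threshold(
    percent_values: np.ndarray, grid_step: float = 0.1
) -> float:
    """Locate the density minimum between the two cover modes.

    The empirical distribution is smoothed by a Gaussian KDE (Scott's rule);
    the threshold is the argmin of the density between the two
    highest-density local maxima.  Raises :class:`BimodalityError` when
    fewer than two modes are found.
    """
    vals = np.asarray(percent_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 1000:
        raise ValueError("need at least 1000 valid cover values")
    kde = stats.gaussian_kde(vals)
    grid = np.arange(0.0, 100.0 + grid_step, grid_step)
    dens = kde(grid)
    (peaks,) = argrelmax(dens)
    if peaks.size < 2:
        raise BimodalityError("cover distribution is unimodal; no threshold found")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    between = slice(lo, hi + 1)
    return float(grid[between][np.argmin(dens[between])])


def classify_pixels(percent: Raster, threshold: float = DEFAULT_THRESHOLD) -> Raster:
    """Binarize percent cover: closed (1) iff strictly above the threshold."""
    closed = (percent.values > threshold).astype(np.uint8)
    closed[percent.nodata_mask] = 0
    return Raster(closed, percent.cell_size, percent.nodata_mask.copy(), tuple(percent.origin))


def classify_landscape(
    fraction_closed: float,
    fraction_valid: float,
    mosaic_bounds: tuple[float, float] = MOSAIC_BOUNDS,
    min_valid: float = MIN_VALID_FRACTION,
) -> str:
    """Landscape class from its fractions alone (reproducible rule)."""
    if fraction_valid < min_valid:
        return "excluded"
    lo, hi = mosaic_bounds
    if lo <= fraction_closed <= hi:
        return "mosaic"
    if fraction_closed > hi:
        return "homogeneous_closed"
    return "homogeneous_open"


def aggregate_to_landscapes(
    covariate: Raster, tiles: list[LandscapeWindow]
) -> pd.Series:
    """Mean of valid covariate cells per tile (NaN where a tile is all nodata)."""
    out = {}
    for w in tiles:
        sub = covariate.values[w.slice()]
        ok = ~covariate.nodata_mask[w.slice()]
        out[w.tile_id] = float(sub[ok].mean()) if ok.any() else np.nan
    return pd.Series(out, name="covariate_mean")


def composition_histogram(
    records: pd.DataFrame, n_bins: int = 18, bounds: tuple[float, float] = MOSAIC_BOUNDS
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of closed-cover fraction over mosaic landscapes.

    Returns (counts, bin_edges) over fixed-width bins spanning ``bounds``.
    """
    mosaics = records[records["landscape_class"] == "mosaic"]
    if len(mosaics) == 0:
        raise ValueError("no mosaic landscapes in the table")
    edges = np.linspace(bounds[0], bounds[1], n_bins + 1)
    counts, _ = np.histogram(np.clip(mosaics["fraction_closed"], *bounds), bins=edges)
    return counts, edges


def build_landscape_table(
    labels: Raster,
    elevation: Raster | None,
    tile_size: int,
    mosaic_bounds: tuple[float, float] = MOSAIC_BOUNDS,
    min_valid: float = MIN_VALID_FRACTION,
    climate: dict[str, Raster] | None = None,
) -> tuple[pd.DataFrame, list[LandscapeWindow]]:
    """One row per tile: fractions, class, roughness, optional climate means."""
    tiles = tile_grid(labels.shape, tile_size)
    rows = []
    for w in tiles:
        lab = labels.values[w.slice()]
        valid = ~labels.nodata_mask[w.slice()]
        n_total = lab.size
        n_valid = int(valid.sum())
        if n_valid > 0:
            frac_closed = float(lab[valid].astype(bool).mean())
        else:
            frac_closed = np.nan
        frac_valid = n_valid / n_total
        cls = (
            "excluded"
            if n_valid == 0
            else classify_landscape(frac_closed, frac_valid, mosaic_bounds, min_valid)
        )
        rough = np.nan
        if elevation is not None:
            sub = elevation.values[w.slice()]
            sub_ok = ~elevation.nodata_mask[w.slice()]
            if sub_ok.sum() >= 2:
                rough = float(np.std(sub[sub_ok]))
        rows.append(
            {
                "tile_id": w.tile_id,
                "row0": w.row0,
                "col0": w.col0,
                "tile_size": w.size,
                "fraction_closed": frac_closed,
                "fraction_open": 1.0 - frac_closed if np.isfinite(frac_closed) else np.nan,
                "fraction_valid": frac_valid,
                "landscape_class": cls,
                "roughness": rough,
            }
        )
    table = pd.DataFrame(rows)
    if climate:
        for name, rast in climate.items():
            table[f"{name}_mean"] = aggregate_to_landscapes(rast, tiles).values
    return table, tiles
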