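"""Topographic predictors derived from elevation.

Six per-pixel features drive all downstream models: the topographic position
index (TPI) at three neighbourhood radii (50, 500 and 5000 m by default),
slope angle, and the sine/cosine components of aspect (eastness/northness).

TPI is elevation minus the mean elevation in a square box window (side
``2*round(radius/cell) + 1`` pixels, centre included, reflecting edges) —
the uniform-filter formulation, so "radius" sets the half-side of the box.
Slope and aspect use Horn's 3x3 finite-difference gradient, the standard
method of GRASS ``r.slope.aspect``.  Aspect is the compass direction of
steepest descent (0 deg = north, 90 deg = east); flat cells get
``aspect_sin = aspect_cos = 0`` as a documented sentinel so no pixel is lost
to an undefined orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster

__all__ = [
    "FEATURE_NAMES",
    "FeatureStack",
    "tpi",
    "slope",
    "aspect_components",
    "roughness",
    "compute_features",
]

#: canonical predictor order used everywhere (models, ALE, CSV columns)
FEATURE_NAMES = ("TPI_50m", "TPI_500m", "TPI_5000m", "slope", "aspect_sin", "aspect_cos")

DEFAULT_TPI_RADII_M = (50.0, 500.0, 5000.0)


@dataclass
class FeatureStack:
    """Per-pixel table of the six topographic predictors on a shared grid."""

    features: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        for name, arr in self.features.items():
            if arr.shape != self.nodata_mask.shape:
                raise ValueError(f"feature {name} shape differs from mask shape")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.features[name]

    def to_frame(self, valid_only: bool = True) -> pd.DataFrame:
        """Long-format table: one row per (valid) pixel with row/col indices."""
        rows, cols = np.indices(self.shape)
        sel = ~self.nodata_mask if valid_only else np.ones(self.shape, dtype=bool)
        data = {"row": rows[sel], "col": cols[sel]}
        for name, arr in self.features.items():
            data[name] = arr[sel]
        return pd.DataFrame(data)


def _masked_uniform_mean(values: np.ndarray, valid: np.ndarray, size: int) -> np.ndarray:
    """Box-window mean ignoring invalid cells (reflecting edges)."""
    filled = np.where(valid, values, 0.0)
    num = ndimage.uniform_filter(filled, size=size, mode="reflect")
    den = ndimage.uniform_filter(valid.astype(np.float64), size=size, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / den
    return mean


def tpi(elev: Raster, radius_m: float) -> Raster:
    """Topographic position index: elevation minus the box-window mean."""
    if radius_m < elev.cell_size:
        raise ValueError(
            f"TPI radius {radius_m} m is smaller than one cell ({elev.cell_size} m)"
        )
    half = int(round(radius_m / elev.cell_size))
    size = 2 * half + 1
    mean = _masked_uniform_mean(elev.values.astype(np.float64), elev.valid_mask, size)
    out = elev.values - mean
    out[elev.nodata_mask] = 0.0
    return Raster(out, elev.cell_size, elev.nodata_mask.copy(), tuple(elev.origin))


# Horn 3x3 weights for the gradient in the +x (east) direction; +y (north)
# is the transpose.  Row 0 of the grid is north, so dz/dnorth uses -d/drow.
_HORN_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 8.0


def _horn_gradients(elev: Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if elev.shape[0] < 3 or elev.shape[1] < 3:
        raise ValueError("slope/aspect require a grid of at least 3x3 cells")
    z = elev.values.astype(np.float64)
    gx = ndimage.correlate(z, _HORN_X, mode="reflect") / elev.cell_size
    gy = -ndimage.correlate(z, _HORN_X.T, mode="reflect") / elev.cell_size
    # any masked neighbour invalidates the stencil
    bad = ndimage.binary_dilation(elev.nodata_mask, structure=np.ones((3, 3), bool))
    return gx, gy, bad


def slope(elev: Raster) -> Raster:
    """Slope angle in degrees from Horn's 3x3 gradient."""
    gx, gy, bad = _horn_gradients(elev)
    deg = np.degrees(np.arctan(np.hypot(gx, gy)))
    deg[bad] = 0.0
    return Raster(deg, elev.cell_size, bad, tuple(elev.origin))


def aspect_components(elev: Raster) -> tuple[Raster, Raster]:
    """(eastness, northness) of the downhill direction; 0 on flat cells."""
    gx, gy, bad = _horn_gradients(elev)
    mag = np.hypot(gx, gy)
    flat = mag < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        a_sin = np.where(flat, 0.0, -gx / mag)
        a_cos = np.where(flat, 0.0, -gy / mag)
    a_sin[bad] = 0.0
    a_cos[bad] = 0.0
    return (
        Raster(a_sin, elev.cell_size, bad, tuple(elev.origin)),
        Raster(a_cos, elev.cell_size, bad.copy(), tuple(elev.origin)),
    )


def roughness(elev: Raster, window=None) -> float:
    """Population standard deviation of valid elevation, optionally in a tile.

    ``window`` is anything with pixel bounds ``(row0, row1, col0, col1)``
    (half-open), e.g. a :class:`~topomosaic.landscape.LandscapeWindow`, or
    None for the whole raster.
    """
    if window is None:
        vals = elev.valid_values()
    else:
        r0, r1, c0, c1 = window.bounds if hasattr(window, "bounds") else window
        sub = elev.values[r0:r1, c0:c1]
        sub_mask = elev.nodata_mask[r0:r1, c0:c1]
        vals = sub[~sub_mask]
    if vals.size < 2:
        raise ValueError("roughness needs at least 2 valid cells")
    return float(np.std(vals))


def compute_features(
    elev: Raster, tpi_radii_m=DEFAULT_TPI_RADII_M
) -> FeatureStack:
    """Derive the full six-feature stack from an elevation raster."""
    feats: dict[str, np.ndarray] = {}
    mask = elev.nodata_mask.copy()
    for r in tpi_radii_m:
        label = f"TPI_{int(r)}m"
        t = tpi(elev, r)
        feats[label] = t.values
        mask |= t.nodata_mask
    s = slope(elev)
    a_sin, a_cos = aspect_components(elev)
    feats["slope"] = s.values
    feats["aspect_sin"] = a_sin.values
    feats["aspect_cos"] = a_cos.values
    mask |= s.nodata_mask
    return FeatureStack(feats, mask, elev.cell_size)
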