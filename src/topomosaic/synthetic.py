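"""Synthetic terrain and vegetation with known ground truth.

Real analyses of forest-savanna mosaics start from a digital elevation model
and a percent-tree-cover map.  This module produces stand-ins for both with
controlled statistical structure, so that every downstream stage — feature
derivation, landscape classification, model fitting, effect summarisation —
can be validated against a known generative process.

Three generators:

* :func:`generate_elevation` — a Gaussian random field with a power-law
  spectrum (spectral/Fourier synthesis), giving spatially autocorrelated
  terrain whose roughness is set by two parameters (spectral exponent and
  amplitude).  Periodicity artefacts from the FFT are accepted; tiles are
  analysed locally.
* :func:`generate_vegetation` — a binary open/closed state drawn per pixel
  from a logistic model on the standardized topographic features, plus a
  bimodal percent-cover raster consistent with the state.  Coefficients act
  on z-scored features, so "which feature drives the pattern" is
  well-defined ground truth.
* :func:`generate_feedback_only` — a patchy binary field statistically
  independent of any terrain, emulating a mosaic maintained purely by
  vegetation-fire feedbacks: the null landscape in which topography-based
  classifiers should perform at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import Raster
from .terrain import DEFAULT_TPI_RADII_M, FEATURE_NAMES, FeatureStack, compute_features

__all__ = [
    "TerrainSpec",
    "VegetationSpec",
    "generate_elevation",
    "generate_vegetation",
    "generate_feedback_only",
]


@dataclass
class TerrainSpec:
    """Parameters of the spectral terrain synthesis.

    ``spectral_exponent`` is the power-law slope beta of the field's power
    spectrum P(f) ~ f**-beta; larger values give smoother, more correlated
    terrain (beta ~ 2-3 resembles natural relief).  ``amplitude`` is the
    target standard deviation of elevation in metres.
    """

    shape: tuple[int, int] = (256, 256)
    cell_size: float = 30.0
    spectral_exponent: float = 2.5
    amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class VegetationSpec:
    """Logistic ground-truth model for the open/closed vegetation state.

    The vegetation state comes from a latent-threshold logistic model: the
    linear predictor ``eta = intercept + sum_f coefficients[f] * z(f)`` (with
    z(f) the raster-wide z-score of topographic feature f) plus logit-scale
    noise is thresholded at zero.  With i.i.d. logistic noise of scale
    ``noise_sd`` this is exactly P(closed) = logistic(eta / noise_sd): at
    ``noise_sd = 1`` the textbook logistic-regression generating process, at
    ``noise_sd = 0`` the deterministic limit (ties broken by a fair coin), so
    the noise scale dials the attainable classification accuracy from chance
    to 1.  With ``noise_correlation_length > 0`` the noise is instead a
    smoothed Gaussian field rescaled to the matching standard deviation, so
    misclassified pixels form spatial patches.  Percent tree cover is then
    drawn from a two-component normal mixture conditioned on the state
    (``mode_open``/``mode_closed`` centres, common ``mode_sd``), clipped to
    [0, 100].
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 1.0
    noise_correlation_length: float = 0.0
    mode_open: float = 15.0
    mode_closed: float = 90.0
    mode_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.coefficients:
            if name not in FEATURE_NAMES:
                raise ValueError(
                    f"unknown feature {name!r}; known features: {FEATURE_NAMES}"
                )
        if not (0 <= self.mode_open < self.mode_closed <= 100):
            raise ValueError("need 0 <= mode_open < mode_closed <= 100")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _power_law_field(shape: tuple[int, int], beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian field with spectrum ~ f**-beta, unit-ish scale."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.rfftfreq(cols)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill the DC component
    amp = f ** (-beta / 2.0)
    noise = rng.normal(size=(rows, f.shape[1])) + 1j * rng.normal(size=(rows, f.shape[1]))
    return np.fft.irfft2(amp * noise, s=shape)


def generate_elevation(spec: TerrainSpec) -> Raster:
    """Synthesize an elevation raster; sample std equals ``spec.amplitude``."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    if spec.amplitude == 0 or rows * cols == 1:
        return Raster(np.zeros(spec.shape), spec.cell_size)
    z = _power_law_field(spec.shape, spec.spectral_exponent, rng)
    sd = z.std()
    if sd == 0:  # degenerate tiny grids
        return Raster(np.zeros(spec.shape), spec.cell_size)
    z = z * (spec.amplitude / sd)
    return Raster(z - z.mean(), spec.cell_size)


def _standardize(arr: np.ndarray, valid: np.ndarray) -> np.ndarray:
    v = arr[valid]
    sd = v.std()
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - v.mean()) / sd


def generate_vegetation(
    elev: Raster,
    spec: VegetationSpec,
    features: FeatureStack | None = None,
    tpi_radii_m=DEFAULT_TPI_RADII_M,
) -> tuple[Raster, Raster]:
    """Draw (labels, percent-cover) rasters from the logistic ground truth.

    Returns ``labels`` (1 = closed, 0 = open, uint8) and ``percent``
    (0-100 float).  ``features`` may be passed to reuse a precomputed stack.
    """
    if not np.all(np.isfinite(elev.valid_values())):
        raise ValueError("elevation contains non-finite valid values")
    if features is None:
        features = compute_features(elev, tpi_radii_m)
    rng = np.random.default_rng(spec.seed)
    valid = ~features.nodata_mask

    eta = np.full(elev.shape, float(spec.intercept))
    for name, coef in spec.coefficients.items():
        eta = eta + coef * _standardize(features[name], valid)
    if spec.noise_sd > 0:
        if spec.noise_correlation_length > 0:
            noise = ndimage.gaussian_filter(
                rng.normal(size=elev.shape), spec.noise_correlation_length, mode="wrap"
            )
            nsd = noise.std()
            # match the sd of logistic(scale=noise_sd) noise
            target_sd = spec.noise_sd * np.pi / np.sqrt(3.0)
            noise = noise * (target_sd / nsd) if nsd > 0 else noise * 0.0
        else:
            noise = rng.logistic(scale=spec.noise_sd, size=elev.shape)
        latent = eta + noise
    else:
        latent = eta
    closed = latent > 0
    ties = latent == 0
    if ties.any():  # deterministic limit with a zero predictor: fair coin
        closed = closed | (ties & (rng.random(elev.shape) < 0.5))
    percent = np.where(
        closed,
        rng.normal(spec.mode_closed, spec.mode_sd, elev.shape),
        rng.normal(spec.mode_open, spec.mode_sd, elev.shape),
    )
    percent = np.clip(percent, 0.0, 100.0)
    mask = features.nodata_mask.copy()
    labels = Raster(closed.astype(np.uint8), elev.cell_size, mask, tuple(elev.origin))
    return labels, Raster(percent, elev.cell_size, mask.copy(), tuple(elev.origin))


def generate_feedback_only(
    shape: tuple[int, int],
    patch_scale: float = 8.0,
    closed_fraction_target: float = 0.5,
    seed: int = 0,
    cell_size: float = 30.0,
) -> Raster:
    """Patchy binary labels independent of any topography.

    A white-noise field is smoothed at ``patch_scale`` pixels and thresholded
    at the empirical quantile matching ``closed_fraction_target``, giving
    spatial patches of roughly that scale whose placement is independent of
    every elevation raster.  ``patch_scale <= 1`` yields an i.i.d. Bernoulli
    field.
    """
    if not 0 < closed_fraction_target < 1:
        raise ValueError("closed_fraction_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if patch_scale <= 1:
        closed = rng.random(shape) < closed_fraction_target
        return Raster(closed.astype(np.uint8), cell_size)
    fld = ndimage.gaussian_filter(rng.normal(size=shape), patch_scale, mode="wrap")
    thr = np.quantile(fld, 1.0 - closed_fraction_target)
    return Raster((fld > thr).astype(np.uint8), cell_size)
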