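"""Top-level Model/Results interface for the mosaic-topography analysis.

:class:`MosaicTopographyModel` is constructed from a percent-tree-cover
raster and an elevation raster (plus an optional mask) and holds the full
analysis configuration: the binarization threshold, tile size, mosaic and
validity bounds, TPI radii and forest hyperparameters.  Its :meth:`fit`
runs the whole pipeline — feature derivation, landscape classification,
regional and per-landscape model fitting, ALE effect summarisation — and
returns a :class:`MosaicTopographyResults` carrying the estimates and a
``summary()`` table.

Example
-------
>>> from topomosaic import synthetic, model
>>> elev = synthetic.generate_elevation(synthetic.TerrainSpec(shape=(192, 192), seed=1))
>>> veg = synthetic.VegetationSpec(coefficients={"TPI_500m": -5.0}, seed=1)
>>> labels, percent = synthetic.generate_vegetation(elev, veg)
>>> res = model.MosaicTopographyModel(percent, elev, tile_size=96).fit(seed=1)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landscape as _landscape
from . import summarize as _summarize
from . import terrain as _terrain
from .landscape import DEFAULT_THRESHOLD
from .models import ModelConfig
from .raster import Raster, apply_mask
from .summarize import LandscapeResult, RegionalResult

__all__ = ["MosaicTopographyModel", "MosaicTopographyResults"]


class MosaicTopographyModel:
    """Topography -> tree-cover-state analysis over one pair of rasters.

    Parameters
    ----------
    cover : Raster
        Percent tree cover (0-100) — or, with ``cover_is_binary=True``, an
        already-binarized open(0)/closed(1) raster.
    elevation : Raster
        Elevation in metres on (or alignable to) the same grid.
    mask : Raster, optional
        Cells to exclude (nonzero or nodata = exclude), e.g. human impact
        or water.
    tile_size : int
        Landscape tile side in pixels (333 at 30 m/px is roughly a 10-km,
        0.1-degree landscape).
    threshold : float
        Percent-cover threshold separating open from closed; ``None``
        triggers bimodality detection on the cover histogram.
    """

    def __init__(
        self,
        cover: Raster,
        elevation: Raster,
        mask: Raster | None = None,
        tile_size: int = 333,
        threshold: float | None = DEFAULT_THRESHOLD,
        mosaic_bounds: tuple[float, float] = _landscape.MOSAIC_BOUNDS,
        min_valid: float = _landscape.MIN_VALID_FRACTION,
        tpi_radii_m=_terrain.DEFAULT_TPI_RADII_M,
        model_config: ModelConfig | None = None,
        n_regional_per_class: int = 5,
        n_local_total: int = 5000,
        subset_bounds: tuple[float, float] = _summarize.DEFAULT_SUBSET_BOUNDS,
        cover_is_binary: bool = False,
        climate: dict[str, Raster] | None = None,
    ) -> None:
        if mask is not None:
            cover = apply_mask(cover, mask)
        self.cover = cover
        self.elevation = elevation
        self.tile_size = tile_size
        self.threshold = threshold
        self.mosaic_bounds = mosaic_bounds
        self.min_valid = min_valid
        self.tpi_radii_m = tuple(tpi_radii_m)
        self.model_config = model_config
        self.n_regional_per_class = n_regional_per_class
        self.n_local_total = n_local_total
        self.subset_bounds = subset_bounds
        self.cover_is_binary = cover_is_binary
        self.climate = climate or {}

    @classmethod
    def from_files(cls, cover_path, elevation_path, mask_path=None, **kwargs):
        """Build the model straight from raster files (TIFF or ASCII grid)."""
        from .raster import read_raster

        mask = read_raster(mask_path) if mask_path else None
        return cls(read_raster(cover_path), read_raster(elevation_path), mask=mask, **kwargs)

    def fit(self, seed: int = 0, with_regional: bool = True, with_local: bool = True
            ) -> "MosaicTopographyResults":
        """Run the pipeline and return a results object."""
        threshold = self.threshold
        if self.cover_is_binary:
            labels = self.cover
        else:
            if threshold is None:
                threshold = _landscape.find_bimodal_threshold(self.cover.valid_values())
            labels = _landscape.classify_pixels(self.cover, threshold)
        features = _terrain.compute_features(self.elevation, self.tpi_radii_m)
        table, tiles = _landscape.build_landscape_table(
            labels, self.elevation, self.tile_size,
            self.mosaic_bounds, self.min_valid, climate=self.climate or None,
        )
        config = self.model_config or ModelConfig(seed=seed)
        regional = None
        if with_regional:
            regional = _summarize.run_regional(
                labels, features, table, tiles, config, seed=seed,
                n_per_class=self.n_regional_per_class, subset_bounds=self.subset_bounds,
            )
        local = []
        if with_local:
            local = _summarize.run_local(
                labels, features, table, tiles, config, seed=seed,
                n_total=self.n_local_total,
            )
        return MosaicTopographyResults(
            model=self, threshold=float(threshold) if threshold is not None else np.nan,
            landscape_table=table, regional=regional, local_results=local, seed=seed,
        )


@dataclass
class MosaicTopographyResults:
    """Estimates and diagnostics from a fitted mosaic-topography analysis."""

    model: MosaicTopographyModel
    threshold: float
    landscape_table: pd.DataFrame
    regional: RegionalResult | None
    local_results: list[LandscapeResult]
    seed: int
    _local_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def local_table(self) -> pd.DataFrame:
        if self._local_table is None:
            self._local_table = _summarize.local_results_table(self.local_results)
        return self._local_table

    @property
    def n_mosaic(self) -> int:
        return int((self.landscape_table["landscape_class"] == "mosaic").sum())

    @property
    def mean_local_accuracy(self) -> float:
        acc = self.local_table["accuracy"].dropna() if len(self.local_results) else pd.Series(dtype=float)
        return float(acc.mean()) if len(acc) else np.nan

    def share_local_above(self, threshold: float = 0.625) -> float:
        """Share of fitted local models whose accuracy exceeds ``threshold``."""
        acc = self.local_table["accuracy"].dropna()
        return float((acc > threshold).mean()) if len(acc) else np.nan

    def top_feature_counts(self) -> pd.Series:
        fitted = self.local_table.dropna(subset=["accuracy"])
        return fitted["top_feature"].value_counts()

    def summary(self) -> str:
        """Plain-text summary table of the fitted analysis."""
        t = self.landscape_table
        counts = t["landscape_class"].value_counts()
        lines = [
            "Mosaic topography analysis",
            "=" * 60,
            f"tiles: {len(t)}  tile size: {self.model.tile_size} px  "
            f"cover threshold: {self.threshold:g}%",
            "landscape classes: "
            + ", ".join(f"{k}={int(v)}" for k, v in counts.items()),
        ]
        if self.regional is not None:
            r = self.regional
            lines += [
                "-" * 60,
                f"regional model:  accuracy {r.accuracy:.3f}  (n={r.n_samples})",
                f"  top feature: {r.top_feature}",
                "  importances: "
                + ", ".join(f"{f}={v:.3f}" for f, v in r.importances.items()),
                "  effect directions: "
                + ", ".join(f"{f}={v:+.2f}" for f, v in r.directions.items()),
            ]
        if self.local_results:
            fitted = self.local_table.dropna(subset=["accuracy"])
            n_skip = len(self.local_results) - len(fitted)
            lines += [
                "-" * 60,
                f"local models: {len(fitted)} fitted, {n_skip} skipped",
            ]
            if len(fitted):
                lines += [
                    f"  mean accuracy {self.mean_local_accuracy:.3f}; "
                    f"share > 0.625: {self.share_local_above():.2f}",
                    "  top-feature counts: "
                    + ", ".join(f"{k}={v}" for k, v in self.top_feature_counts().items()),
                ]
        lines.append("=" * 60)
        return "\n".join(lines)
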