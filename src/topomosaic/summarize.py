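"""Regional and per-landscape model runs, and cross-landscape aggregation.

``run_regional`` fits one forest on balanced samples pooled across all
mosaic tiles (optionally repeated within composition subsets — mostly open /
balanced / mostly closed); ``run_local`` fits an independent forest per
mosaic tile and records accuracy, impurity importances and the ALE-based
effect direction of every feature.  The aggregation helpers reproduce the
summaries used to map and relate these metrics: 2-D binned statistics with
a minimum landscape count per bin, and covariate-binned means with a rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _models
from .ale import ALECurve, abs_effect_direction, ale_curve, effect_direction
from .landscape import LandscapeWindow
from .models import ModelConfig
from .raster import Raster
from .sampling import SampleSet, sample_local, sample_regional, split_train_test
from .terrain import FeatureStack

__all__ = [
    "LandscapeResult",
    "RegionalResult",
    "run_regional",
    "run_local",
    "bin_2d",
    "relate",
    "composition_subsets",
    "local_results_table",
]

DEFAULT_SUBSET_BOUNDS = (1.0 / 3.0, 2.0 / 3.0)


@dataclass
class LandscapeResult:
    """Metrics of one local model (or the reason the tile was skipped)."""

    tile_id: int
    accuracy: float | None = None
    importances: dict[str, float] = field(default_factory=dict)
    top_feature: str | None = None
    directions: dict[str, float] = field(default_factory=dict)
    abs_directions: dict[str, float] = field(default_factory=dict)
    fraction_closed: float = np.nan
    roughness: float = np.nan
    n_samples: int = 0
    skipped: str | None = None


@dataclass
class RegionalResult:
    """Pooled-model metrics, plus per-composition-subset replicas."""

    accuracy: float
    importances: dict[str, float]
    top_feature: str
    curves: dict[str, ALECurve]
    directions: dict[str, float]
    n_samples: int
    subsets: dict[str, "RegionalResult"] = field(default_factory=dict)


def _mosaic_windows(table: pd.DataFrame, tiles: list[LandscapeWindow]) -> list[LandscapeWindow]:
    mosaic_ids = set(table.loc[table["landscape_class"] == "mosaic", "tile_id"])
    return [w for w in tiles if w.tile_id in mosaic_ids]


def _fit_and_summarize(
    samples: SampleSet, config: ModelConfig, seed: int, ale_bins: int = 20
) -> RegionalResult:
    train, test = split_train_test(samples, seed=seed)
    model = _models.fit(train, config)
    imps = _models.feature_importance(model)
    curves = {f: ale_curve(model, train, f, n_bins=ale_bins) for f in samples.feature_names}
    dirs = {f: effect_direction(c) for f, c in curves.items()}
    return RegionalResult(
        accuracy=_models.accuracy(model, test),
        importances=imps,
        top_feature=_models.top_feature(imps),
        curves=curves,
        directions=dirs,
        n_samples=len(samples),
    )


def run_regional(
    labels: Raster,
    features: FeatureStack,
    table: pd.DataFrame,
    tiles: list[LandscapeWindow],
    config: ModelConfig | None = None,
    seed: int = 0,
    n_per_class: int = 5,
    subset_bounds: tuple[float, float] = DEFAULT_SUBSET_BOUNDS,
    with_subsets: bool = True,
) -> RegionalResult:
    """One pooled model over all mosaic tiles; subset replicas optional."""
    config = config or ModelConfig(seed=seed)
    windows = _mosaic_windows(table, tiles)
    if len(windows) < 2:
        raise ValueError("need at least 2 mosaic tiles for a regional model")
    samples = sample_regional(labels, features, windows, n_per_class=n_per_class, seed=seed)
    result = _fit_and_summarize(samples, config, seed)
    if with_subsets:
        subset_ids = composition_subsets(table, bounds=subset_bounds)
        for name, ids in subset_ids.items():
            sub_windows = [w for w in windows if w.tile_id in ids]
            if len(sub_windows) < 2:
                continue
            sub_samples = sample_regional(
                labels, features, sub_windows, n_per_class=n_per_class, seed=seed
            )
            if len(sub_samples) < 10:
                continue
            result.subsets[name] = _fit_and_summarize(sub_samples, config, seed)
    return result


def run_local(
    labels: Raster,
    features: FeatureStack,
    table: pd.DataFrame,
    tiles: list[LandscapeWindow],
    config: ModelConfig | None = None,
    seed: int = 0,
    n_total: int = 5000,
    ale_bins: int = 20,
) -> list[LandscapeResult]:
    """One independent model per mosaic tile; skips are recorded, not fatal."""
    config = config or ModelConfig(seed=seed)
    windows = _mosaic_windows(table, tiles)
    meta = table.set_index("tile_id")
    results: list[LandscapeResult] = []
    for w in windows:
        frac = float(meta.loc[w.tile_id, "fraction_closed"])
        rough = float(meta.loc[w.tile_id, "roughness"])
        samples = sample_local(labels, features, w, n_total=n_total, seed=seed)
        if samples is None:
            results.append(
                LandscapeResult(
                    w.tile_id, fraction_closed=frac, roughness=rough,
                    skipped="minority class below the per-tile minimum",
                )
            )
            continue
        try:
            train, test = split_train_test(samples, seed=seed)
            tile_config = ModelConfig(
                config.n_trees, config.min_samples_leaf, config.max_depth,
                seed=(config.seed + w.tile_id) % (2**31 - 1),
            )
            model = _models.fit(train, tile_config)
        except ValueError as exc:
            results.append(
                LandscapeResult(
                    w.tile_id, fraction_closed=frac, roughness=rough, skipped=str(exc)
                )
            )
            continue
        imps = _models.feature_importance(model)
        dirs, abs_dirs = {}, {}
        for f in samples.feature_names:
            curve = ale_curve(model, train, f, n_bins=ale_bins)
            dirs[f] = effect_direction(curve)
            abs_dirs[f] = abs_effect_direction(curve)
        results.append(
            LandscapeResult(
                tile_id=w.tile_id,
                accuracy=_models.accuracy(model, test),
                importances=imps,
                top_feature=_models.top_feature(imps),
                directions=dirs,
                abs_directions=abs_dirs,
                fraction_closed=frac,
                roughness=rough,
                n_samples=len(samples),
            )
        )
    return results


def local_results_table(results: list[LandscapeResult]) -> pd.DataFrame:
    """Flatten per-landscape results into one row per tile."""
    rows = []
    for r in results:
        row = {
            "tile_id": r.tile_id,
            "accuracy": r.accuracy,
            "top_feature": r.top_feature,
            "fraction_closed": r.fraction_closed,
            "roughness": r.roughness,
            "n_samples": r.n_samples,
            "skipped": r.skipped,
        }
        for f, v in r.importances.items():
            row[f"importance_{f}"] = v
        for f, v in r.directions.items():
            row[f"direction_{f}"] = v
        for f, v in r.abs_directions.items():
            row[f"abs_direction_{f}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def bin_2d(
    table: pd.DataFrame,
    x: str,
    y: str,
    value: str = "fraction_closed",
    n_bins: int = 10,
    min_count: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regular-grid 2-D binned mean of ``value``; sparse bins masked.

    Returns (statistic, x_edges, y_edges) with bins holding fewer than
    ``min_count`` landscapes set to NaN.
    """
    sub = table[[x, y, value]].dropna()
    stat, xe, ye, _ = stats.binned_statistic_2d(
        sub[x], sub[y], sub[value], statistic="mean", bins=n_bins
    )
    counts, _, _, _ = stats.binned_statistic_2d(
        sub[x], sub[y], sub[value], statistic="count", bins=[xe, ye]
    )
    stat = np.where(counts >= min_count, stat, np.nan)
    return stat, xe, ye


def relate(
    table: pd.DataFrame, metric: str, covariate: str, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Covariate-binned means of a metric plus a Spearman rank correlation."""
    sub = table[[metric, covariate]].dropna()
    if len(sub) < 10:
        raise ValueError("need at least 10 landscapes to relate metrics")
    cov = sub[covariate].to_numpy(dtype=float)
    if np.allclose(cov, cov[0]):
        raise ValueError(f"covariate {covariate!r} is constant; correlation undefined")
    edges = np.linspace(cov.min(), cov.max(), n_bins + 1)
    which = np.clip(np.digitize(cov, edges) - 1, 0, n_bins - 1)
    binned = pd.DataFrame(
        {
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "mean": [
                sub[metric].to_numpy()[which == b].mean() if (which == b).any() else np.nan
                for b in range(n_bins)
            ],
            "count": [(which == b).sum() for b in range(n_bins)],
        }
    )
    rho = float(stats.spearmanr(cov, sub[metric]).statistic)
    return binned, rho


def composition_subsets(
    table: pd.DataFrame, bounds: tuple[float, float] = DEFAULT_SUBSET_BOUNDS
) -> dict[str, set[int]]:
    """Partition mosaic tiles by closed fraction: mostly open / balanced / mostly closed."""
    lo, hi = bounds
    mos = table[table["landscape_class"] == "mosaic"]
    fc = mos["fraction_closed"]
    return {
        "mostly_open": set(mos.loc[fc < lo, "tile_id"]),
        "balanced": set(mos.loc[(fc >= lo) & (fc <= hi), "tile_id"]),
        "mostly_closed": set(mos.loc[fc > hi, "tile_id"]),
    }
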