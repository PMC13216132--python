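"""First-order Accumulated Local Effects (ALE) and effect-direction summaries.

ALE describes how one feature moves a fitted model's predicted probability
of closed tree cover, free of the extrapolation bias of partial-dependence
plots: within each feature bin, the model is evaluated at the bin's two
edges with all other features held at the observed rows' values, the mean
finite difference is the bin's local effect, and the accumulated (cumsum)
effects are centred to a weighted mean of zero.

The implementation follows the definition directly (quantile bins, default
20; duplicate quantile edges merged with weights pooled), because the
downstream summary statistic — the Spearman correlation of the curve, whose
sign gives the effect direction and whose magnitude gives its monotonicity —
operates on the raw curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import FittedModel
from .sampling import SampleSet

__all__ = ["ALECurve", "ale_curve", "effect_direction", "abs_effect_direction"]


@dataclass
class ALECurve:
    """Centred accumulated effects of one feature of one fitted model."""

    feature: str
    edges: np.ndarray     # n_bins + 1, strictly increasing
    centers: np.ndarray   # n_bins
    values: np.ndarray    # centred ALE, probability units
    weights: np.ndarray   # per-bin row counts
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "edge_lo": self.edges[:-1],
                "edge_hi": self.edges[1:],
                "center": self.centers,
                "ale": self.values,
                "weight": self.weights,
            }
        )


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    return np.unique(edges)  # merge duplicate edges on heavy-tied features


def ale_curve(
    model: FittedModel, data: SampleSet, feature: str, n_bins: int = 20
) -> ALECurve:
    """First-order ALE of ``feature`` over the rows of ``data``.

    Bin edges are empirical quantiles of the feature.  A constant feature
    yields a flagged single-bin curve of zeros rather than an error, so
    per-tile sweeps never abort on a degenerate feature.
    """
    if feature not in data.feature_names:
        raise KeyError(f"feature {feature!r} not in sample set {data.feature_names}")
    if len(data) == 0:
        raise ValueError("empty sample set")
    X = data.X
    j = list(data.feature_names).index(feature)
    x = X[:, j]
    edges = _quantile_edges(x, n_bins)
    if edges.size < 2:  # constant feature
        c = float(edges[0]) if edges.size else 0.0
        return ALECurve(
            feature,
            np.array([c, c]),
            np.array([c]),
            np.zeros(1),
            np.array([len(data)], dtype=float),
            degenerate=True,
        )
    # bin assignment: (edges[k-1], edges[k]]; lowest bin takes its left edge
    k = np.searchsorted(edges, x, side="left") - 1
    k = np.clip(k, 0, edges.size - 2)
    n_eff = edges.size - 1
    local = np.zeros(n_eff)
    weights = np.zeros(n_eff)
    for b in range(n_eff):
        rows = np.nonzero(k == b)[0]
        weights[b] = rows.size
        if rows.size == 0:
            continue
        lo = X[rows].copy()
        hi = X[rows].copy()
        lo[:, j] = edges[b]
        hi[:, j] = edges[b + 1]
        local[b] = float(
            np.mean(model.predict_proba_closed(hi) - model.predict_proba_closed(lo))
        )
    acc = np.cumsum(local)
    total = weights.sum()
    centred = acc - (np.sum(acc * weights) / total if total > 0 else 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ALECurve(feature, edges, centers, centred, weights)


def _direction(xs: np.ndarray, curve: ALECurve) -> float:
    if curve.degenerate or curve.values.size < 3 or np.allclose(curve.values, curve.values[0]):
        return 0.0
    rho = stats.spearmanr(xs, curve.values).statistic
    return float(rho) if np.isfinite(rho) else 0.0

def effect_direction(curve: ALECurve) -> float:
    """Spearman correlation of bin centres vs ALE values.

    Sign gives the direction of the feature's effect on P(closed); magnitude
    its monotonicity.  Degenerate (flat or <3 bin) curves report 0.
    """
    return _direction(curve.centers, curve)


def abs_effect_direction(curve: ALECurve) -> float:
    """Spearman correlation of |bin centre| vs ALE values.

    Captures symmetric V-shaped responses (e.g. cover increasing at both
    locally high and locally low positions) that a signed direction misses.
    """
    return _direction(np.abs(curve.centers), curve)
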