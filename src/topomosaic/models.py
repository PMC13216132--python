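"""Random-forest open/closed classifier: fit, accuracy, importance.

The classifier is deliberately small and fixed: 100 trees, minimum 10
samples per leaf, maximum depth 10, so that regional and local models are
directly comparable and cheap to fit per tile.  The ensemble engine is
scikit-learn's ``RandomForestClassifier``; this module pins the three
hyperparameters, the seed policy and the feature/class ordering contract.
Unstated hyperparameters follow the engine defaults and are captured in
:meth:`ModelConfig.manifest` for the run record.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .sampling import SampleSet

__all__ = ["ModelConfig", "FittedModel", "fit", "accuracy", "feature_importance",
           "top_feature"]


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 100
    min_samples_leaf: int = 10
    max_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.min_samples_leaf, self.max_depth) < 1:
            raise ValueError("n_trees, min_samples_leaf and max_depth must be >= 1")

    def manifest(self) -> dict:
        """Full hyperparameter record, including engine defaults."""
        d = asdict(self)
        d.update(engine="sklearn.RandomForestClassifier", criterion="gini",
                 max_features="sqrt", bootstrap=True)
        return d


@dataclass
class FittedModel:
    """Trained ensemble with its feature order, class order and provenance."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: ModelConfig
    n_train: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_proba_closed(self, X: np.ndarray) -> np.ndarray:
        """P(closed): soft vote — fraction of trees voting class 1."""
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        closed_col = list(self.estimator.classes_).index(1)
        return proba[:, closed_col]


def fit(train: SampleSet, config: ModelConfig | None = None) -> FittedModel:
    """Fit the forest on a training SampleSet; deterministic under the seed."""
    config = config or ModelConfig()
    y = train.y
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class; cannot fit")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_samples_leaf,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(train.X, y)
    return FittedModel(est, train.feature_names, config, len(train))


def accuracy(model: FittedModel, test: SampleSet) -> float:
    """Fraction of correct predictions on a held-out set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    return float(np.mean(model.predict(test.X) == test.y))


def feature_importance(model: FittedModel) -> dict[str, float]:
    """Impurity-based importances, one weight per feature, summing to 1.

    When every split is uninformative sklearn returns all-zero importances;
    these are passed through unchanged (callers treat argmax ties
    lexicographically via :func:`top_feature`).
    """
    imp = model.estimator.feature_importances_
    return {name: float(v) for name, v in zip(model.feature_names, imp)}


def top_feature(importances: dict[str, float]) -> str:
    """Argmax feature, ties broken lexicographically."""
    best = max(sorted(importances), key=lambda k: importances[k])
    return best
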