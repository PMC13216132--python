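"""Balanced pixel sampling for the regional and local classifiers.

The regional model draws a small, equal number of open and closed pixels
from every mosaic tile (5 + 5 by default) so it learns within-landscape
configuration rather than between-landscape composition; each local model
draws a larger balanced sample (5000 by default) from its own tile.  All
draws are without replacement, respect the nodata mask, and preserve class
balance: when one class runs short, the other is shrunk to match.  Tiles
whose minority class is below a floor (50 pixels) are skipped for local
modelling, with the reason recorded.

Reproducibility: one master seed fans out to per-tile substreams by mixing
the tile id into a ``numpy.random.SeedSequence``, so any tile's sample can
be regenerated independently of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster
from .terrain import FeatureStack
from .landscape import LandscapeWindow

__all__ = ["SampleSet", "sample_regional", "sample_local", "split_train_test",
           "LOCAL_MIN_PER_CLASS"]

#: minimum minority-class pixel count for a tile to get a local model
LOCAL_MIN_PER_CLASS = 50


@dataclass
class SampleSet:
    """Feature/label rows with provenance (tile id, pixel coords, seed)."""

    data: pd.DataFrame  # columns: feature names..., label, tile_id, row, col
    feature_names: tuple[str, ...]
    seed: int | None = None
    provenance: str = ""
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    def class_counts(self) -> dict[int, int]:
        vc = self.data["label"].value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _tile_rng(master_seed: int, tile_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(tile_id,)))


def _tile_pixel_pools(
    labels: Raster, features: FeatureStack, window: LandscapeWindow
) -> tuple[np.ndarray, np.ndarray]:
    """(open_coords, closed_coords): arrays of (row, col) of valid pixels."""
    sl = window.slice()
    valid = ~(labels.nodata_mask[sl] | features.nodata_mask[sl])
    lab = labels.values[sl].astype(bool)
    rr, cc = np.nonzero(valid & ~lab)
    open_coords = np.column_stack([rr + window.row0, cc + window.col0])
    rr, cc = np.nonzero(valid & lab)
    closed_coords = np.column_stack([rr + window.row0, cc + window.col0])
    return open_coords, closed_coords


def _rows_from_coords(
    features: FeatureStack, coords: np.ndarray, label: int, tile_id: int
) -> pd.DataFrame:
    data = {
        name: features[name][coords[:, 0], coords[:, 1]] for name in features.names
    }
    data["label"] = label
    data["tile_id"] = tile_id
    data["row"] = coords[:, 0]
    data["col"] = coords[:, 1]
    return pd.DataFrame(data)


def sample_regional(
    labels: Raster,
    features: FeatureStack,
    mosaic_tiles: list[LandscapeWindow],
    n_per_class: int = 5,
    seed: int = 0,
) -> SampleSet:
    """Draw ``n_per_class`` open + closed pixels from every mosaic tile.

    Tiles short of one class contribute all available pixels of that class
    and an equal number of the other (balance preserved, shortfall noted).
    """
    if not mosaic_tiles:
        raise ValueError("no mosaic tiles to sample from")
    notes: list[str] = []
    frames = []
    for w in mosaic_tiles:
        rng = _tile_rng(seed, w.tile_id)
        open_c, closed_c = _tile_pixel_pools(labels, features, w)
        n = min(n_per_class, len(open_c), len(closed_c))
        if n < n_per_class:
            notes.append(
                f"tile {w.tile_id}: only {n} per class "
                f"(open={len(open_c)}, closed={len(closed_c)})"
            )
        if n == 0:
            continue
        sel_o = open_c[rng.choice(len(open_c), size=n, replace=False)]
        sel_c = closed_c[rng.choice(len(closed_c), size=n, replace=False)]
        frames.append(_rows_from_coords(features, sel_o, 0, w.tile_id))
        frames.append(_rows_from_coords(features, sel_c, 1, w.tile_id))
    if not frames:
        raise ValueError("no sampleable pixels in any mosaic tile")
    data = pd.concat(frames, ignore_index=True)
    return SampleSet(data, features.names, seed=seed, provenance="regional", notes=notes)


def sample_local(
    labels: Raster,
    features: FeatureStack,
    tile: LandscapeWindow,
    n_total: int = 5000,
    seed: int = 0,
    min_per_class: int = LOCAL_MIN_PER_CLASS,
) -> SampleSet | None:
    """Balanced within-tile sample for one local model.

    Takes ``n_total / 2`` pixels per class without replacement, capped at the
    minority-class count (both classes shrunk to the cap).  Returns None —
    the skip signal — when the minority class has fewer than
    ``min_per_class`` pixels.
    """
    rng = _tile_rng(seed, tile.tile_id)
    open_c, closed_c = _tile_pixel_pools(labels, features, tile)
    per_class = min(n_total // 2, len(open_c), len(closed_c))
    if per_class < min_per_class:
        return None
    sel_o = open_c[rng.choice(len(open_c), size=per_class, replace=False)]
    sel_c = closed_c[rng.choice(len(closed_c), size=per_class, replace=False)]
    data = pd.concat(
        [
            _rows_from_coords(features, sel_o, 0, tile.tile_id),
            _rows_from_coords(features, sel_c, 1, tile.tile_id),
        ],
        ignore_index=True,
    )
    return SampleSet(data, features.names, seed=seed, provenance="local")


def split_train_test(
    samples: SampleSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SampleSet, SampleSet]:
    """Disjoint, exhaustive, label-stratified train/test split."""
    if len(samples) < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for lab in sorted(samples.data["label"].unique()):
        idx = samples.data.index[samples.data["label"] == lab].to_numpy()
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    mk = lambda ix, tag: SampleSet(
        samples.data.loc[ix].reset_index(drop=True),
        samples.feature_names,
        seed=seed,
        provenance=f"{samples.provenance}/{tag}",
    )
    return mk(tr, "train"), mk(te, "test")
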