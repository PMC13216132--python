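import numpy as np
import pandas as pd
import pytest

from topomosaic.raster import Raster
from topomosaic.sampling import SampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_elev(rng):
    """Random 50x50 elevation raster, 30 m cells."""
    return Raster(rng.normal(100.0, 20.0, (50, 50)), cell_size=30.0)


def make_sample_set(X, y, feature_names=None, tile_id=0):
    """Build a SampleSet straight from arrays (test convenience)."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    data = pd.DataFrame(X, columns=list(feature_names))
    data["label"] = np.asarray(y, dtype=int)
    data["tile_id"] = tile_id
    data["row"] = np.arange(len(data))
    data["col"] = 0
    return SampleSet(data, tuple(feature_names), seed=0, provenance="test")
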