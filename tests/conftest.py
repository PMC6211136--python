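import numpy as np
import pytest

from logicforest.data_model import Dataset, PredictorDescriptor


def make_dataset(X, y, names=None):
    """Wrap raw binary arrays into a Dataset with generic descriptors."""
    X = np.asarray(X, dtype=np.uint8)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    descs = [
        PredictorDescriptor(n, "exposure", None, "raw_binary", (n, f"not {n}"))
        for n in names
    ]
    return Dataset(X, np.asarray(y, dtype=np.uint8), descs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_and_dataset(rng):
    """n=400 noiseless y = x1 AND x2 over 8 independent predictors."""
    X = rng.integers(0, 2, size=(400, 8)).astype(np.uint8)
    y = (X[:, 1] & X[:, 2]).astype(np.uint8)
    return make_dataset(X, y)
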