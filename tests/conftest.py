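import numpy as np
import pytest

from carslogit import Dataset, SimConfig, generate


def make_dataset(X, y, names=None, refs=None):
    X = np.asarray(X, dtype=float)
    if names is None:
        names = tuple(f"X{j + 1}" for j in range(X.shape[1]))
    return Dataset(X=X, Y=np.asarray(y), column_names=names, reference_levels=refs)


@pytest.fixture
def small_dataset():
    """12 rows, two binary predictors, both classes present."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, size=(12, 2)).astype(float)
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 0])
    return make_dataset(X, y)


@pytest.fixture
def planted_dataset():
    """n=500, v=10, strong effects on the first two columns."""
    cfg = SimConfig(
        n_samples=500,
        n_variables=10,
        informative_indices=(0, 1),
        effect_sizes=(1.5, 1.5),
        intercept=-1.5,
        seed=11,
    )
    ds, truth = generate(cfg)
    return ds, truth


@pytest.fixture
def null_dataset():
    """n=400, v=8, response independent of every predictor."""
    cfg = SimConfig(n_samples=400, n_variables=8, intercept=0.0, seed=5)
    ds, _ = generate(cfg)
    return ds
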