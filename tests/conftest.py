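import numpy as np
import pytest

from discimpute import CONTINUOUS, DISCRETE, Dataset


@pytest.fixture
def toy_mixed() -> Dataset:
    """8 records, 2 continuous + 1 discrete feature, 2 classes, complete."""
    X = np.array([
        [1.0, 10.0, 0],
        [2.0, 20.0, 1],
        [3.0, 30.0, 0],
        [4.0, 40.0, 2],
        [5.0, 50.0, 1],
        [6.0, 60.0, 0],
        [7.0, 70.0, 2],
        [8.0, 80.0, 1],
    ], dtype=float)
    return Dataset(
        X=X,
        mask=np.zeros_like(X, dtype=bool),
        feature_types=[CONTINUOUS, CONTINUOUS, DISCRETE],
        y=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        feature_names=["a", "b", "c"],
    )


@pytest.fixture
def toy_masked(toy_mixed) -> Dataset:
    """toy_mixed with two masked cells in different records."""
    d = toy_mixed.copy()
    d.mask[1, 0] = True
    d.mask[6, 1] = True
    return d


def make_random_instance(rng, n_max=30, n_classes_max=3):
    """Small random (values, labels) pair for oracle sweeps."""
    n = int(rng.integers(2, n_max + 1))
    c = int(rng.integers(2, n_classes_max + 1))
    if rng.random() < 0.5:
        values = rng.integers(0, 8, size=n).astype(float)  # heavy ties
    else:
        values = np.round(rng.normal(size=n), 2)
    labels = rng.integers(0, c, size=n)
    return values, labels
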