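import numpy as np
import pytest

from mkmdigwo import Dataset, SyntheticSpec, make_dataset, worked_example_fixtures


@pytest.fixture(scope="session")
def fx():
    """The printed worked-example vectors."""
    return worked_example_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_separable():
    """Small two-class dataset whose feature 0 is a copy of the labels."""
    rng = np.random.default_rng(0)
    n = 40
    y = np.arange(n) % 2
    X = np.column_stack([
        y.astype(float),                       # label copy
        y + rng.normal(0, 0.3, n),             # informative, noisy
        rng.normal(0, 1, n),                   # noise
        rng.normal(0, 1, n),                   # noise
    ])
    return Dataset(X, y, ["copy", "inf", "n1", "n2"])


@pytest.fixture(scope="session")
def synth_small():
    """Default-structure synthetic dataset plus its ground truth."""
    return make_dataset(SyntheticSpec(seed=11))
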