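import numpy as np
import pytest

from mcmfs import table2_fixture


@pytest.fixture
def table2():
    return table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_discrete_dataset(rng, n=None, d=None, q=None):
    """Small random multi-label dataset for property tests."""
    n = n or int(rng.integers(4, 50))
    d = d or int(rng.integers(2, 6))
    q = q or int(rng.integers(1, 4))
    features = rng.integers(0, int(rng.integers(2, 5)), size=(n, d))
    labels = rng.integers(0, 2, size=(n, q))
    from mcmfs import DiscreteDataset

    return DiscreteDataset(features, labels)
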