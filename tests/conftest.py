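import numpy as np
import pytest

from zilpgm import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """The 3x2 hand-evaluated toy matrix used across likelihood tests."""
    return CountMatrix(np.array([[0, 1], [2, 0], [1, 1]]))


@pytest.fixture
def poisson_counts(rng):
    """A small well-behaved Poisson count matrix (no structural zeros)."""
    return CountMatrix(rng.poisson(2.0, size=(40, 6)))
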