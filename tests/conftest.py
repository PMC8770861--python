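import numpy as np
import pytest

from fglgnscca import DataMatrix, HyperParams, default_structures, make_truth, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair(rng):
    """A small correlated (X, Y) pair with known block-sparse truth."""
    truth = make_truth(30, 20)
    X, Y = simulate(80, truth, noise_level=0.5, seed=5)
    return X, Y, truth


@pytest.fixture
def small_structures(small_pair):
    X, Y, _ = small_pair
    return default_structures(X, Y)


@pytest.fixture
def default_hp():
    return HyperParams()


@pytest.fixture
def random_matrix(rng):
    def _make(n=40, d=10, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return DataMatrix.from_values(r.standard_normal((n, d)))

    return _make
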