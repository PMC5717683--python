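import numpy as np
import pytest

from wnetgen import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_nets():
    """A small batch of random connected networks of mixed sizes."""
    return [
        fixtures.random_conforming(n, 1.0, 50.0, seed=seed)
        for n, seed in [(5, 11), (6, 12), (6, 13), (8, 14), (10, 15)]
    ]


def random_positive_unit_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    """Nonnegative vector of unit Euclidean norm, at least two distinct values."""
    while True:
        x = rng.uniform(0.0, 1.0, size=n)
        nrm = np.linalg.norm(x)
        if nrm > 0 and np.ptp(x) > 1e-9:
            return x / nrm
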