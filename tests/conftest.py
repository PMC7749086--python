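import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """A 50x50 8-bit RGB patch of uniform noise."""
    return rng.integers(0, 256, (50, 50, 3), dtype=np.uint8)


@pytest.fixture
def spd_factory(rng):
    """Factory for random well-conditioned SPD matrices."""

    def make(dim: int = 8) -> np.ndarray:
        A = rng.normal(size=(dim, dim))
        lam = rng.uniform(0.1, 3.0, size=dim)
        Q, _ = np.linalg.qr(A)
        M = (Q * lam) @ Q.T
        return (M + M.T) / 2.0

    return make
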