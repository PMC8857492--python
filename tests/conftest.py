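import numpy as np
import pytest

from ifn3d import ContactMatrix


def symmetric_poisson(n: int, lam: float, seed: int,
                      bin_size: int = 10_000) -> ContactMatrix:
    """Flat-law Poisson matrix (no decay): the simplest null contact map."""
    rng = np.random.default_rng(seed)
    raw = rng.poisson(lam, size=(n, n)).astype(float)
    counts = np.triu(raw) + np.triu(raw, 1).T
    return ContactMatrix("chrT", bin_size, counts)


def decay_matrix(n: int, seed: int, alpha: float = 1.0, depth: float = 2e5,
                 bin_size: int = 10_000) -> ContactMatrix:
    """Power-law decay Poisson matrix without compartments or loops."""
    idx = np.arange(n)
    mu = (1.0 + np.abs(np.subtract.outer(idx, idx))) ** (-alpha)
    mu *= depth / mu[np.triu_indices(n)].sum()
    rng = np.random.default_rng(seed)
    raw = rng.poisson(mu).astype(float)
    counts = np.triu(raw) + np.triu(raw, 1).T
    return ContactMatrix("chrT", bin_size, counts)


@pytest.fixture
def random_matrix() -> ContactMatrix:
    return symmetric_poisson(30, 12.0, seed=7)


@pytest.fixture
def balanced_decay():
    from ifn3d import ice_balance, mask_low_coverage

    return ice_balance(mask_low_coverage(decay_matrix(80, seed=3), 0.0))
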