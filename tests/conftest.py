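import numpy as np
import pytest

from sarqr import QuantileSAR, build_rook_lattice
from sarqr.sampler import GibbsSampler


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_small_model(n=25, tau=0.5, seed=7, q=2, p=2, max_knots=20):
    """A small synthetic model on a rook lattice (n must be a square)."""
    rng = np.random.default_rng(seed)
    wm = build_rook_lattice(n)
    X = rng.standard_normal((n, p))
    Z = rng.uniform(-2.0, 0.0, (n, q))
    U = rng.uniform(0.0, 1.0, n)
    alpha = [lambda u: 2 * np.cos(2 * np.pi * u) + 1, lambda u: 2 * u][:q]
    signal = X @ np.r_[1.0, -1.0][:p]
    for j in range(q):
        signal = signal + Z[:, j] * alpha[j](U)
    eps = rng.standard_normal(n)
    y = np.linalg.solve(np.eye(n) - 0.5 * wm.W, signal + eps)
    return QuantileSAR(y, X, Z, U, wm, tau=tau, max_knots=max_knots)


@pytest.fixture
def small_model():
    return make_small_model()


@pytest.fixture
def small_sampler(small_model):
    return GibbsSampler(small_model, np.random.default_rng(99))
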