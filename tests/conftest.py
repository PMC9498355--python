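import numpy as np
import pytest

from flowct.glow3d import FlowConfig, Glow3D
from flowct.phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_flow():
    """A small random-initialized flow on 4^3 inputs, actnorm initialized."""
    cfg = FlowConfig(shape=(4, 4, 4, 1), levels=2, depth=2, width=8, seed=3)
    model = Glow3D(cfg)
    r = np.random.default_rng(3)
    model.initialize_actnorm(r.random((4, 4, 4, 4, 1)))
    return model


@pytest.fixture(scope="session")
def flow16():
    """A 16^3 flow with random init for invertibility / likelihood checks."""
    cfg = FlowConfig(shape=(16, 16, 16, 1), levels=2, depth=2, width=16, seed=5)
    model = Glow3D(cfg)
    r = np.random.default_rng(5)
    model.initialize_actnorm(r.random((4, 16, 16, 16, 1)))
    return model


@pytest.fixture(scope="session")
def phantom_pair():
    spec = PhantomSpec(shape=(16, 16, 16), seed=42)
    return generate_phantom(spec, 0), generate_phantom(spec, 1)


def finite_difference_grad(leaf, value_fn, eps=1e-6):
    """Central finite-difference gradient of scalar value_fn wrt leaf.data."""
    g = np.zeros_like(leaf.data)
    it = np.nditer(leaf.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = leaf.data[i]
        leaf.data[i] = orig + eps
        fp = value_fn()
        leaf.data[i] = orig - eps
        fm = value_fn()
        leaf.data[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
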