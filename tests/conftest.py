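import math

import pytest

from mmskin.dispersion import DispersionParams
from mmskin.io import default_registry
from mmskin.layered import Layer, LayerStack


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def gel(registry):
    return registry.material("gel")


@pytest.fixture(scope="session")
def thin_p95_stack(registry):
    return registry.stack("skin_thin_p95")


@pytest.fixture(scope="session")
def thin_mean_stack(registry):
    return registry.stack("skin_thin_mean")


@pytest.fixture(scope="session")
def gel_ptfe100(registry):
    return registry.stack("gel_ptfe100")


def random_debye(rng, lossy=True):
    """Random physically plausible Debye material."""
    eps_inf = rng.uniform(1.0, 10.0)
    eps_s = eps_inf + rng.uniform(0.0, 60.0)
    sigma = rng.uniform(0.1, 10.0) if lossy else 0.0
    tau = rng.uniform(1.0, 20.0) * 1e-12
    return DispersionParams(eps_inf, eps_s, sigma, tau)


def random_stack(rng, max_layers=5):
    """Random layered stack over a lossy half-space."""
    n = rng.integers(0, max_layers)
    layers = [Layer(random_debye(rng, lossy=rng.random() < 0.5),
                    rng.uniform(5e-6, 2e-3)) for _ in range(n)]
    layers.append(Layer(random_debye(rng, lossy=True), math.inf))
    return LayerStack(layers)
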