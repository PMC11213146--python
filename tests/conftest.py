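import warnings

import numpy as np
import pytest

from cellcontext import generate_world, world_to_graph

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def small_world():
    """Desk-scale fixture world shared across tests (read-only)."""
    return generate_world(n_molecules=120, n_genes=30, d_latent=8, noise_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def small_graph(small_world):
    graph, declared = world_to_graph(small_world)
    return graph, declared


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
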