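import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from amend.network import InteractionNetwork
from amend.synthetic import SyntheticSpec, generate_instance


@pytest.fixture(scope="session")
def default_instance():
    """The default planted-module benchmark instance (seed 1)."""
    return generate_instance(SyntheticSpec())


@pytest.fixture(scope="session")
def small_instance():
    """A reduced planted-module instance for fast pipeline tests."""
    spec = SyntheticSpec(n_background=150, module_size=10, seed=7)
    return generate_instance(spec)


@pytest.fixture
def triangle():
    return InteractionNetwork([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return InteractionNetwork([("a", "b"), ("b", "c")])


def random_connected_network(rng: np.random.Generator, n_max: int = 14,
                             n_min: int = 4) -> InteractionNetwork:
    """Random connected graph with 3..n_max nodes (largest component)."""
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.2, 0.6))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    return InteractionNetwork(nx.relabel_nodes(g, {v: f"n{v:02d}" for v in g.nodes}))
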