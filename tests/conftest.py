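import numpy as np
import pytest

from stsvm import ExpressionDataset, Network, pstep_rwk
from stsvm.synthdata import SimulationConfig, simulate


@pytest.fixture
def path_graph():
    """A - B - C path."""
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def edge_graph():
    """Single edge A - B."""
    return Network.from_edges([("A", "B")])


@pytest.fixture
def edge_kernel(edge_graph):
    return pstep_rwk(edge_graph, a=2.0, p=2)


@pytest.fixture
def toy_dataset():
    """6 features x 12 samples with two clearly separated features."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(6, 12))
    labels = np.array([1] * 6 + [-1] * 6)
    values[0, labels == 1] += 3.0
    values[1, labels == 1] += 3.0
    features = [f"F{i}" for i in range(6)]
    samples = [f"S{i}" for i in range(12)]
    return ExpressionDataset(features, samples, values, labels)


@pytest.fixture
def separable_module_sim():
    """Small scale-free simulation with a strong planted module."""
    cfg = SimulationConfig(
        n_genes=200, n_pos=25, n_neg=25, module_size=12, effect_size=2.0
    )
    return simulate(cfg, seed=11)


def random_network(rng, n, model="er", p_edge=0.15):
    """Random small graph as a Network (test helper)."""
    import networkx as nx

    if model == "er":
        g = nx.erdos_renyi_graph(n, p_edge, seed=int(rng.integers(2**31 - 1)))
    else:
        m = min(2, n - 1)
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31 - 1)))
    names = [f"n{i:03d}" for i in range(n)]
    return Network.from_edges(
        [(names[u], names[v]) for u, v in g.edges()], extra_nodes=names
    )
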