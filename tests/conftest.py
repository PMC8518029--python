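import numpy as np
import pytest

from hogcn import InteractionGraph, toy_fixture


@pytest.fixture
def path3():
    return toy_fixture("path3")


@pytest.fixture
def triangle():
    return toy_fixture("triangle")


@pytest.fixture
def l3_demo():
    return toy_fixture("l3_demo")


@pytest.fixture
def bipartite_2x2():
    return toy_fixture("bipartite_2x2")


def random_graph(n_nodes: int, edge_prob: float, seed: int) -> InteractionGraph:
    """Erdos-Renyi graph with string node ids, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(ii)) < edge_prob
    edges = np.stack([ii[keep], jj[keep]], axis=1)
    return InteractionGraph([f"v{i}" for i in range(n_nodes)], edges)


@pytest.fixture
def random_graph_factory():
    return random_graph
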