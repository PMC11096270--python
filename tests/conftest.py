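import networkx as nx
import pytest

from grnbench import GeneNetwork


def net_from(edges, directed=True, nodes=None):
    return GeneNetwork.from_edges(edges, directed=directed, nodes=nodes)


@pytest.fixture
def path3():
    """Undirected path a–b–c."""
    return net_from([("a", "b"), ("b", "c")], directed=False)


@pytest.fixture
def star4():
    """Undirected star: hub h with leaves x, y, z."""
    return net_from([("h", "x"), ("h", "y"), ("h", "z")], directed=False)


@pytest.fixture
def triangle():
    return net_from([("a", "b"), ("b", "c"), ("a", "c")], directed=False)


def complete_graph(n, directed=False):
    g = nx.complete_graph([f"v{i}" for i in range(n)])
    return GeneNetwork(g.to_directed() if directed else g)


def cycle_graph(n):
    g = nx.cycle_graph([f"v{i}" for i in range(n)])
    return GeneNetwork(g)
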