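"""Graph metrics and centralities: closed forms, hand-worked examples, and
equivalence with the handwritten brute-force oracle."""

import numpy as np
import pytest

import oracles
from grnbench import GeneNetwork
from grnbench.errors import UndefinedMetricError
from grnbench.metrics import (
    CENTRALITY_METRICS,
    GRAPH_METRICS,
    average_shortest_path_length,
    betweenness_centrality,
    degree_assortativity,
    degree_centrality,
    degree_centralization,
    global_clustering,
    global_efficiency,
    local_efficiency,
    pagerank_centrality,
    radiality_centrality,
    topology_profile,
)

from conftest import complete_graph, cycle_graph, net_from


class TestPathLengthAndEfficiency:
    def test_complete_graph_aspl_is_one(self):
        assert average_shortest_path_length(complete_graph(6)) == pytest.approx(1.0)

    def test_path3_aspl(self, path3):
        # ordered distances: 1,1,1,1,2,2 -> 8/6
        assert average_shortest_path_length(path3) == pytest.approx(4 / 3)

    def test_four_cycle_aspl(self):
        assert average_shortest_path_length(cycle_graph(4)) == pytest.approx(4 / 3)

    def test_complete_graph_efficiency_is_one(self):
        for n in (3, 4, 5):
            assert global_efficiency(complete_graph(n)) == pytest.approx(1.0)

    def test_path3_efficiency(self, path3):
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_edgeless_pair_efficiency_zero(self):
        net = net_from([], directed=False, nodes=["a", "b"])
        assert global_efficiency(net) == 0.0

    def test_triangle_local_efficiency_one(self, triangle):
        assert local_efficiency(triangle) == pytest.approx(1.0)

    def test_star_local_efficiency_zero(self, star4):
        assert local_efficiency(star4) == 0.0

    def test_k4_local_efficiency_one(self):
        assert local_efficiency(complete_graph(4)) == pytest.approx(1.0)

    def test_adding_edges_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(0)
        count = 0
        while count < 200:
            nodes, edges = oracles.random_connected_graph(rng, n_max=10)
            net = net_from(edges, directed=False, nodes=nodes)
            candidates = [
                (u, v)
                for i, u in enumerate(nodes)
                for v in nodes[i + 1:]
                if not net.has_edge(u, v)
            ]
            if not candidates:
                continue
            u, v = candidates[rng.integers(len(candidates))]
            before = global_efficiency(net)
            net.graph.add_edge(u, v)
            assert global_efficiency(net) >= before - 1e-12
            count += 1


class TestHubTopologyMetrics:
    def test_star_assortativity_minus_one(self, star4):
        assert degree_assortativity(star4) == pytest.approx(-1.0)

    def test_regular_graphs_zero_by_convention(self):
        assert degree_assortativity(cycle_graph(5)) == 0.0
        assert degree_assortativity(complete_graph(4)) == 0.0

    def test_star_centralization_one(self):
        for n in (4, 7):
            hub = "h"
            net = net_from(
                [(hub, f"x{i}") for i in range(n - 1)], directed=False
            )
            assert degree_centralization(net) == pytest.approx(1.0)

    def test_cycle_centralization_zero(self):
        assert degree_centralization(cycle_graph(6)) == 0.0

    def test_directed_star_in_centralization(self):
        # center->leaves, n=4: leaf in-degrees 1, center 0; sum (1-in) = 1; /9
        net = net_from([("h", "x"), ("h", "y"), ("h", "z")])
        assert degree_centralization(net, "directed") == pytest.approx(1 / 9)

    def test_centralization_needs_three_nodes(self):
        with pytest.raises(UndefinedMetricError):
            degree_centralization(net_from([("a", "b")], directed=False))

    def test_triangle_clustering_one(self, triangle):
        assert global_clustering(triangle) == pytest.approx(1.0)

    def test_star_clustering_zero(self, star4):
        assert global_clustering(star4) == 0.0

    def test_k4_minus_edge_clustering(self):
        # degree-3 nodes: 2/3; degree-2 nodes: 1 -> mean 5/6
        net = complete_graph(4)
        net.graph.remove_edge("v2", "v3")
        assert global_clustering(net) == pytest.approx(5 / 6)


class TestCentralities:
    def test_star_degree_centrality(self, star4):
        table = degree_centrality(star4)
        assert table["h"] == pytest.approx(1.0)
        assert table["x"] == pytest.approx(1 / 3)

    def test_directed_chain_out_centrality(self):
        net = net_from([("A", "B"), ("B", "C")])
        table = degree_centrality(net, "directed")
        assert table["A"] == pytest.approx(1 / 2)
        assert table["C"] == 0.0

    def test_path3_betweenness(self, path3):
        table = betweenness_centrality(path3)
        assert table["b"] == pytest.approx(1.0)
        assert table["a"] == 0.0 and table["c"] == 0.0

    def test_complete_graph_betweenness_zero(self):
        table = betweenness_centrality(complete_graph(5))
        assert all(v == 0.0 for v in table.values.values())

    def test_four_cycle_pagerank_uniform(self):
        table = pagerank_centrality(cycle_graph(4))
        for v in table.values.values():
            assert v == pytest.approx(0.25, abs=1e-8)

    def test_pagerank_sums_to_one(self):
        rng = np.random.default_rng(1)
        nodes, edges = oracles.random_connected_graph(rng, directed=True)
        net = net_from(edges, nodes=nodes)
        table = pagerank_centrality(net, "directed")
        assert sum(table.values.values()) == pytest.approx(1.0, abs=1e-9)

    def test_directed_star_pagerank_closed_form(self):
        # leaves -> center; center is dangling. Solve the 2-class fixed point:
        # p_c = (1-d)/4 + d (3 p_l + p_c/4);  p_l = (1-d)/4 + d p_c / 4
        net = net_from([("x", "h"), ("y", "h"), ("z", "h")])
        d = 0.85
        a = np.array([[1 - d / 4, -3 * d], [-d / 4, 1]])
        b = np.array([(1 - d) / 4, (1 - d) / 4])
        p_c, p_l = np.linalg.solve(a, b)
        table = pagerank_centrality(net, "directed", damping=d, tol=1e-13)
        assert table["h"] == pytest.approx(p_c / (p_c + 3 * p_l), abs=1e-9)

    def test_triangle_radiality_one(self, triangle):
        table = radiality_centrality(triangle)
        assert all(v == pytest.approx(1.0) for v in table.values.values())

    def test_path3_radiality(self, path3):
        table = radiality_centrality(path3)
        assert table["b"] == pytest.approx(2.0)
        assert table["a"] == pytest.approx(1.5)

    def test_radiality_grows_with_diameter_at_equal_mean_distance(self):
        # path of 5 (diameter 4) vs star of 5 (diameter 2): center node of
        # each has mean distance 1.0 vs 1.0? No—use direct construction:
        # two graphs where node v has identical mean distance but the second
        # graph has the larger diameter, hence larger radiality for v.
        star = net_from([("c", f"x{i}") for i in range(4)], directed=False)
        r_star = radiality_centrality(star)["c"]
        path = net_from(
            [("c", "a"), ("c", "b"), ("a", "d"), ("b", "e")], directed=False
        )
        r_path = radiality_centrality(path)["c"]
        # both centers have mean distance 1.0 and 1.5; diameters 2 and 4
        assert r_path > r_star - 1.0  # larger diameter compensates distance


@pytest.mark.parametrize("directed", [False, True])
def test_metrics_match_brute_force_oracle(directed):
    """All ten metrics agree with the handwritten BFS/formula oracle."""
    rng = np.random.default_rng(7)
    mode = "directed" if directed else "undirected"
    for _ in range(25):
        nodes, edges = oracles.random_connected_graph(rng, n_max=10, directed=directed)
        net = net_from(edges, directed=directed, nodes=nodes)
        assert average_shortest_path_length(net, mode) == pytest.approx(
            oracles.aspl(nodes, edges, directed), abs=1e-9
        )
        assert global_efficiency(net, mode) == pytest.approx(
            oracles.global_efficiency(nodes, edges, directed), abs=1e-9
        )
        assert local_efficiency(net, mode) == pytest.approx(
            oracles.local_efficiency(nodes, edges, directed), abs=1e-9
        )
        assert degree_assortativity(net, mode) == pytest.approx(
            oracles.assortativity(nodes, edges, directed), abs=1e-9
        )
        assert degree_centralization(net, mode) == pytest.approx(
            oracles.centralization(nodes, edges, directed), abs=1e-9
        )
        assert global_clustering(net, mode) == pytest.approx(
            oracles.clustering(nodes, edges, directed), abs=1e-9
        )
        for name, expect in [
            ("degree", oracles.degree_centrality(nodes, edges, directed)),
            ("betweenness", oracles.betweenness(nodes, edges, directed)),
            ("radiality", oracles.radiality(nodes, edges, directed)),
        ]:
            got = CENTRALITY_METRICS[name](net, mode).values
            for v in nodes:
                assert got[v] == pytest.approx(expect[v], abs=1e-9), (name, v)
        got = pagerank_centrality(net, mode, tol=1e-13).values
        expect = oracles.pagerank(nodes, edges, directed)
        for v in nodes:
            assert got[v] == pytest.approx(expect[v], abs=1e-9)


def test_undirected_assortativity_matches_networkx():
    import networkx as nx

    rng = np.random.default_rng(11)
    for _ in range(20):
        nodes, edges = oracles.random_connected_graph(rng, n_max=10)
        g = nx.Graph(edges)
        degs = [d for _, d in g.degree()]
        if len(set(degs)) < 2:
            continue
        ours = degree_assortativity(GeneNetwork(g), "undirected")
        theirs = nx.degree_assortativity_coefficient(g)
        assert ours == pytest.approx(theirs, abs=1e-9)


def test_topology_profile_collects_all_metrics():
    rng = np.random.default_rng(3)
    nodes, edges = oracles.random_connected_graph(rng, n_max=8)
    net = net_from(edges, directed=False, nodes=nodes)
    profile = topology_profile(net, "undirected")
    d = profile.as_dict()
    assert set(d) == set(GRAPH_METRICS)
    assert 0 <= d["global_efficiency"] <= 1
    assert 0 <= d["local_efficiency"] <= 1
    assert -1 <= d["assortativity"] <= 1
    assert d["aspl"] >= 1
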