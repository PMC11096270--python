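"""Edge-prediction scores, signed errors, and hub-identification scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from grnbench import (
    EvaluationRecord,
    RankedEdgeList,
    auc_scores,
    early_precision,
    hub_identification_score,
    jaccard,
    jrand_approx,
    jrand_exact,
    mean_signed_error,
    preprocess_ground_truth,
    select_hubs,
)
from grnbench.errors import (
    AggregationError,
    ConsistencyError,
    InvalidConfigError,
)
from grnbench.metrics import CentralityTable

from conftest import net_from


def record(metric, truth, inferred, alg="a", net="n1", cls="ER"):
    return EvaluationRecord(
        network_id=net, network_class=cls, algorithm=alg,
        mode="undirected", metric=metric, truth=truth, inferred=inferred,
    )


class TestEarlyPrecision:
    def truth(self):
        return preprocess_ground_truth(
            net_from([("A", "B"), ("B", "C"), ("C", "A")]), "undirected"
        )

    def test_perfect_predictor(self):
        truth = self.truth()
        ranked = RankedEdgeList.from_network(truth)
        assert early_precision(ranked, truth) == 1.0

    def test_two_of_three(self):
        ranked = RankedEdgeList(
            [("A", "B", 0.9), ("B", "C", 0.8), ("A", "D", 0.7), ("C", "A", 0.1)],
            directed=True,
        )
        assert early_precision(ranked, self.truth()) == pytest.approx(2 / 3)

    def test_random_subset_expectation_is_density(self):
        # random top-k is a uniform k-subset of all pairs: hypergeometric mean
        rng = np.random.default_rng(0)
        n, k = 8, 10
        nodes = [f"g{i}" for i in range(n)]
        all_pairs = [
            (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
        ]
        truth_edges = [all_pairs[i] for i in rng.choice(len(all_pairs), 12, replace=False)]
        truth = preprocess_ground_truth(
            net_from(truth_edges, directed=False, nodes=nodes), "undirected"
        )
        density = truth.n_edges / (
            truth.n_nodes * (truth.n_nodes - 1) / 2
        )
        pairs_in_truth = [
            (a, b)
            for i, a in enumerate(sorted(truth.nodes))
            for b in sorted(truth.nodes)[i + 1:]
        ]
        k = truth.n_edges
        draws = 10_000
        eprs = np.empty(draws)
        for i in range(draws):
            idx = rng.choice(len(pairs_in_truth), size=k, replace=False)
            ranked = RankedEdgeList(
                [(*pairs_in_truth[j], 1.0) for j in idx], directed=False
            )
            eprs[i] = early_precision(ranked, truth)
        se = eprs.std() / np.sqrt(draws)
        assert abs(eprs.mean() - density) < 3 * se


class TestAucScores:
    def truth(self):
        return preprocess_ground_truth(
            net_from([("A", "B"), ("B", "C")]), "undirected"
        )

    def test_perfect_separation(self):
        ranked = RankedEdgeList([("A", "B", 0.9), ("B", "C", 0.8)], directed=False)
        auroc, auprc = auc_scores(ranked, self.truth())
        assert auroc == 1.0 and auprc == 1.0

    def test_constant_scores_give_half(self):
        ranked = RankedEdgeList(
            [("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.5)], directed=False
        )
        auroc, _ = auc_scores(ranked, self.truth())
        assert auroc == pytest.approx(0.5)

    def test_four_pair_toy(self):
        # labels (1,0,1,0) at scores (0.9,0.8,0.3,0.1): 3 of 4 label pairs ordered
        nodes = ["A", "B", "C", "D"]
        truth = preprocess_ground_truth(
            net_from([("A", "B"), ("A", "C"), ("A", "D")], directed=False),
            "undirected",
        )
        # candidate pairs: AB AC AD BC BD CD; make only 4 scored, rest zero
        ranked = RankedEdgeList(
            [
                ("A", "B", 0.9),   # true
                ("B", "C", 0.8),   # false
                ("A", "C", 0.3),   # true
                ("B", "D", 0.1),   # false
            ],
            directed=False,
        )
        # remaining pairs AD (true) and CD (false) both score 0
        auroc, _ = auc_scores(ranked, truth)
        # hand enumeration: true scores {0.9, 0.3, 0}, false {0.8, 0.1, 0, 0*}
        # pairs ordered correctly: count via midrank convention
        y = [1, 0, 1, 0, 1, 0]
        s = [0.9, 0.8, 0.3, 0.1, 0.0, 0.0]
        pos = [v for v, yy in zip(s, y) if yy]
        neg = [v for v, yy in zip(s, y) if not yy]
        wins = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert auroc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_labels_rejected(self):
        truth = preprocess_ground_truth(net_from([("A", "B")]), "undirected")
        ranked = RankedEdgeList([("A", "B", 0.9)], directed=False)
        with pytest.raises(AggregationError):
            auc_scores(ranked, truth)


class TestMeanSignedError:
    def test_overestimation_positive(self):
        records = [record("aspl", 0.5, 0.6), record("aspl", 0.5, 0.7)]
        assert mean_signed_error(records) == pytest.approx(0.15)

    def test_exact_inference_zero(self):
        records = [record("aspl", 0.4, 0.4), record("aspl", 1.2, 1.2)]
        assert mean_signed_error(records) == 0.0

    def test_underestimation_negative(self):
        assert mean_signed_error([record("aspl", 0.4, 0.1)]) == pytest.approx(-0.3)

    def test_mixed_metrics_rejected(self):
        with pytest.raises(AggregationError):
            mean_signed_error([record("aspl", 1, 1), record("clustering", 1, 1)])

    @given(
        st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(-10, 10, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetric_under_swap(self, pairs):
        fwd = [record("aspl", t, i) for t, i in pairs]
        rev = [record("aspl", i, t) for t, i in pairs]
        assert mean_signed_error(fwd) == pytest.approx(-mean_signed_error(rev))


class TestSelectHubs:
    def table(self, values):
        return CentralityTable("degree", values)

    def test_ten_percent_of_twenty(self):
        values = {f"g{i:02d}": i for i in range(20)}
        hubs = select_hubs(self.table(values), set(values), 0.1)
        assert hubs == {"g19", "g18"}

    def test_minimum_one_hub(self):
        values = {f"g{i}": i for i in range(5)}
        hubs = select_hubs(self.table(values), set(values), 0.1)
        assert hubs == {"g4"}

    def test_ties_break_lexicographically(self):
        values = {c: 1.0 for c in "abcdefghijklmnopqrst"}
        hubs = select_hubs(self.table(values), set(values), 0.1)
        assert hubs == {"a", "b"}

    def test_missing_common_node_rejected(self):
        with pytest.raises(ConsistencyError):
            select_hubs(self.table({"a": 1}), {"a", "b"}, 0.1)


class TestJaccard:
    def test_identical(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_single_overlap_of_two(self):
        # x=1, n0=2: J = x/(2 n0 - x) = 1/3
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(InvalidConfigError):
            jaccard(set(), set())


class TestJrand:
    def test_exact_small_case(self):
        assert jrand_exact(20, 2) == pytest.approx(13 / 190)

    def test_full_overlap_limit(self):
        assert jrand_exact(7, 7) == pytest.approx(1.0)
        assert jrand_approx(7, 7) == pytest.approx(1.0)

    def test_monte_carlo_oracle(self):
        n, n0, draws = 30, 3, 100_000
        vals = oracles.jrand_monte_carlo(n, n0, draws, seed=123)
        se = vals.std() / np.sqrt(draws)
        assert abs(vals.mean() - jrand_exact(n, n0)) < 3 * se

    def test_approximation_examples(self):
        assert jrand_approx(100, 10) == pytest.approx(1 / 19)
        exact = jrand_exact(1000, 100)
        approx = jrand_approx(1000, 100)
        assert abs(approx - exact) / exact < 0.02

    @given(st.integers(2, 60), st.data())
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_hypergeometric_probabilities_sum_to_one(self, n, data):
        from scipy import stats

        n0 = data.draw(st.integers(1, n))
        xs = np.arange(0, n0 + 1)
        assert stats.hypergeom.pmf(xs, n, n0, n0).sum() == pytest.approx(1.0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidConfigError):
            jrand_exact(5, 6)


class TestHubIdentificationScore:
    def ring_with_hub(self):
        edges = [(f"g{i}", f"g{(i + 1) % 12}") for i in range(12)]
        edges += [("g0", f"g{i}") for i in (2, 4, 6, 8)]
        return preprocess_ground_truth(net_from(edges), "undirected")

    def test_perfect_recovery(self):
        truth = self.ring_with_hub()
        ev = hub_identification_score(truth, truth, "degree")
        assert ev.jaccard == 1.0
        assert ev.ratio == pytest.approx(1.0 / ev.j_rand)

    def test_random_hub_sets_average_to_jrand(self):
        # definition check: mean J over random subsets ~ J_rand
        n, n0, draws = 14, 2, 1000
        rng = np.random.default_rng(5)
        truth_set = {0, 1}
        ratios = np.empty(draws)
        jr = jrand_exact(n, n0)
        for i in range(draws):
            pick = set(rng.choice(n, n0, replace=False).tolist())
            inter = len(truth_set & pick)
            ratios[i] = (inter / (2 * n0 - inter)) / jr
        se = ratios.std() / np.sqrt(draws)
        assert abs(ratios.mean() - 1.0) < 3 * se

    def test_star_center_always_a_hub(self):
        edges = [("hub", f"x{i}") for i in range(11)]
        truth = preprocess_ground_truth(net_from(edges), "undirected")
        ev = hub_identification_score(truth, truth, "degree")
        table = CentralityTable(
            "degree", {v: truth.graph.degree(v) for v in truth.nodes}
        )
        hubs = select_hubs(table, truth.nodes, 0.1)
        assert "hub" in hubs and ev.jaccard == 1.0

    def test_small_overlap_skipped_with_warning(self):
        a = preprocess_ground_truth(net_from([("A", "B"), ("B", "C")]), "undirected")
        b = preprocess_ground_truth(net_from([("X", "Y"), ("Y", "A"), ("A", "X")]), "undirected")
        assert hub_identification_score(a, b, "degree") is None
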