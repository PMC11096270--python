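"""Scoring inferred networks against their ground truth.

Three families of scores:

* **edge prediction** — early precision (fraction of true positives among
  the top-k ranked edges, k = ground-truth edge count), AUROC and AUPRC
  over all candidate gene pairs;
* **topological accuracy** — the signed error (inferred − truth) of each
  graph-level metric, averaged over networks as a mean signed error whose
  sign distinguishes over- from underestimation;
* **hub identification** — the Jaccard coefficient between the top-10%
  centrality hub sets of truth and inferred network, reported as a ratio to
  the exact random-predictor expectation J_rand (a hypergeometric sum), so
  that 1 means "no better than chance".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import AggregationError, ConsistencyError, InvalidConfigError
from .metrics import CENTRALITY_METRICS, CentralityTable
from .network import UNDIRECTED, GeneNetwork
from .ranking import RankedEdgeList

log = logging.getLogger(__name__)

#: fraction of common nodes labeled as hubs
HUB_FRACTION = 0.1
#: minimum node overlap for a meaningful hub comparison
MIN_COMMON_NODES = 10


@dataclass
class EdgePredictionScores:
    EPr: float
    AUROC: float
    AUPRC: float
    k: int


@dataclass
class EvaluationRecord:
    """One (network, algorithm, metric) comparison of truth vs inference."""

    network_id: str
    network_class: str
    algorithm: str
    mode: str
    metric: str
    truth: float
    inferred: float

    @property
    def signed_error(self) -> float:
        return self.inferred - self.truth


@dataclass
class HubEvaluation:
    """Hub-set overlap for one centrality metric on one network."""

    network_id: str
    network_class: str
    algorithm: str
    mode: str
    metric: str
    n_common: int
    n_hubs: int
    jaccard: float
    j_rand: float

    @property
    def ratio(self) -> float:
        return self.jaccard / self.j_rand


# ------------------------------------------------------------- edge scores
def _truth_pairs(truth: GeneNetwork, mode: str) -> tuple[list, set]:
    """All candidate non-self pairs among truth nodes and the true subset."""
    nodes = sorted(truth.nodes)
    if mode == UNDIRECTED:
        pairs = [
            (u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]
        ]
        true_set = {frozenset(p) for p in truth.edge_set()}
        keyfn = lambda p: frozenset(p)  # noqa: E731
    else:
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        true_set = set(truth.graph.edges())
        keyfn = lambda p: p  # noqa: E731
    return [(p, keyfn(p) in true_set) for p in pairs], true_set


def early_precision(
    ranked: RankedEdgeList, truth: GeneNetwork, mode: str = UNDIRECTED
) -> float:
    """Fraction of true positives among the top-k ranked edges, with k the
    number of edges of the processed ground truth."""
    k = truth.n_edges
    clean = ranked.clean()
    if mode == UNDIRECTED:
        clean = clean.symmetrized()
    if len(clean) < k:
        warnings.warn(
            f"only {len(clean)} ranked edges for k={k}; computing EPr over "
            "the available edges",
            stacklevel=2,
        )
    top = clean.top_k(k)
    truth_edges = truth.edge_set()
    hits = 0
    for rec in top.records():
        key = (
            frozenset((rec.source, rec.target))
            if mode == UNDIRECTED
            else (rec.source, rec.target)
        )
        if key in truth_edges:
            hits += 1
    return hits / k


def auc_scores(
    ranked: RankedEdgeList, truth: GeneNetwork, mode: str = UNDIRECTED
) -> tuple[float, float]:
    """(AUROC, AUPRC) over all candidate pairs of the truth's nodes.

    Scores are |weight| (0 for unranked pairs); labels are edge presence.
    Ties are handled by midranks, so a constant score gives AUROC 0.5.
    """
    clean = ranked.clean()
    if mode == UNDIRECTED:
        clean = clean.symmetrized()
    score_of = {}
    for rec in clean.records():
        key = (
            frozenset((rec.source, rec.target))
            if mode == UNDIRECTED
            else (rec.source, rec.target)
        )
        score_of[key] = abs(rec.weight)
    labeled, _ = _truth_pairs(truth, mode)
    y, s = [], []
    for pair, is_true in labeled:
        key = frozenset(pair) if mode == UNDIRECTED else pair
        y.append(1 if is_true else 0)
        s.append(score_of.get(key, 0.0))
    y = np.asarray(y)
    s = np.asarray(s)
    if y.sum() == 0 or y.sum() == len(y):
        raise AggregationError(
            "AUC undefined: ground truth labels are single-class"
        )
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def edge_prediction_scores(
    ranked: RankedEdgeList, truth: GeneNetwork, mode: str = UNDIRECTED
) -> EdgePredictionScores:
    auroc, auprc = auc_scores(ranked, truth, mode)
    return EdgePredictionScores(
        EPr=early_precision(ranked, truth, mode),
        AUROC=auroc,
        AUPRC=auprc,
        k=truth.n_edges,
    )


# ------------------------------------------------------------ signed errors
def mean_signed_error(records: list[EvaluationRecord]) -> float:
    """Mean over networks of (inferred − truth); positive = overestimation."""
    if not records:
        raise AggregationError("no records to average")
    metrics = {r.metric for r in records}
    if len(metrics) > 1:
        raise AggregationError(
            f"records mix metrics {sorted(metrics)}; average one at a time"
        )
    return float(np.mean([r.signed_error for r in records]))


# ------------------------------------------------------------------- hubs
def select_hubs(
    centrality: CentralityTable,
    common_nodes: set,
    fraction: float = HUB_FRACTION,
) -> set:
    """The n0 = max(1, round(fraction·|common|)) top-centrality common nodes,
    ties broken by node label ascending (half-up rounding)."""
    if not common_nodes:
        raise InvalidConfigError("common node set is empty")
    if not 0 < fraction < 1:
        raise InvalidConfigError("hub fraction must lie in (0, 1)")
    missing = common_nodes - set(centrality.values)
    if missing:
        raise ConsistencyError(
            f"centrality table lacks nodes {sorted(missing)[:5]}"
        )
    n0 = max(1, int(np.floor(fraction * len(common_nodes) + 0.5)))
    return set(centrality.top(common_nodes)[:n0])


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|."""
    if not a and not b:
        raise InvalidConfigError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(a | b)


def jrand_exact(n: int, n0: int) -> float:
    """Expected Jaccard overlap of a uniformly random size-n0 subset with a
    fixed size-n0 hub set among n nodes.

    J_rand = Σ_x [x / (2 n0 − x)] · P(x) with P the hypergeometric pmf of
    the intersection size x.
    """
    if not 1 <= n0 <= n:
        raise InvalidConfigError("need 1 <= n0 <= n")
    xs = np.arange(0, n0 + 1)
    pmf = stats.hypergeom.pmf(xs, n, n0, n0)
    jx = xs / (2 * n0 - xs)
    return float(np.sum(jx * pmf))


def jrand_approx(n: int, n0: int) -> float:
    """Large-n approximation (n0/n) / (2 − n0/n) of :func:`jrand_exact`."""
    if n0 > n:
        raise InvalidConfigError("n0 cannot exceed n")
    q = n0 / n
    return q / (2 - q)


def hub_identification_score(
    truth: GeneNetwork,
    inferred: GeneNetwork,
    metric: str,
    mode: str = UNDIRECTED,
    fraction: float = HUB_FRACTION,
    network_id: str = "",
    network_class: str = "",
    algorithm: str = "",
) -> HubEvaluation | None:
    """J / J_rand for one centrality metric; None (with a warning) when the
    networks share fewer than :data:`MIN_COMMON_NODES` nodes."""
    if metric not in CENTRALITY_METRICS:
        raise InvalidConfigError(f"unknown hub metric {metric!r}")
    common = truth.nodes & inferred.nodes
    if len(common) < MIN_COMMON_NODES:
        log.warning(
            "skipping hub metric %s: only %d common nodes", metric, len(common)
        )
        return None
    fn = CENTRALITY_METRICS[metric]
    hubs_true = select_hubs(fn(truth, mode), common, fraction)
    hubs_inf = select_hubs(fn(inferred, mode), common, fraction)
    n0 = len(hubs_true)
    return HubEvaluation(
        network_id=network_id,
        network_class=network_class,
        algorithm=algorithm,
        mode=mode,
        metric=metric,
        n_common=len(common),
        n_hubs=n0,
        jaccard=jaccard(hubs_true, hubs_inf),
        j_rand=jrand_exact(len(common), n0),
    )
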