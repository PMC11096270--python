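"""Gene-network container and the processing rules applied before evaluation.

A :class:`GeneNetwork` is a thin wrapper around a :mod:`networkx` graph whose
nodes are opaque, case-sensitive gene identifiers and whose edges optionally
carry a regulatory sign (activation / repression) and a real weight.

Ground-truth networks and inferred networks are brought onto a common footing
before any metric is computed:

* ground truths lose self-loops and duplicate edges and are reduced to their
  largest (weakly) connected component;
* inferred ranked edge lists are cleaned, cut to the top ``k`` edges by
  absolute weight (``k`` = the processed ground truth's edge count) and then
  likewise reduced to one connected component.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    DegenerateNetworkError,
    EmptyNetworkError,
    InvalidConfigError,
    ModeMismatchError,
    ParseError,
)

ACTIVATION = "activation"
REPRESSION = "repression"

_SIGN_ALIASES = {
    "+": ACTIVATION,
    "-": REPRESSION,
    "−": REPRESSION,  # unicode minus
    "activation": ACTIVATION,
    "repression": REPRESSION,
}

UNDIRECTED = "undirected"
DIRECTED = "directed"


def _check_mode(mode: str) -> str:
    if mode not in (UNDIRECTED, DIRECTED):
        raise ValueError(f"mode must be 'undirected' or 'directed', got {mode!r}")
    return mode


class GeneNetwork:
    """A directed or undirected regulatory network of gene nodes."""

    def __init__(self, graph: nx.Graph | nx.DiGraph):
        self.graph = graph

    # ------------------------------------------------------------------ build
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        directed: bool = True,
        nodes: Iterable[str] | None = None,
    ) -> "GeneNetwork":
        """Build from ``(source, target)`` or ``(source, target, attrs)`` tuples."""
        g = nx.DiGraph() if directed else nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                g.add_edge(u, v)
            else:
                u, v, attrs = edge
                g.add_edge(u, v, **attrs)
        return cls(g)

    # ------------------------------------------------------------- properties
    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self, data: bool = False) -> Iterator:
        return iter(self.graph.edges(data=data))

    def edge_set(self) -> set:
        """Edges as a set of tuples; unordered-pair frozensets when undirected."""
        if self.directed:
            return set(self.graph.edges())
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.graph.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return f"<GeneNetwork {kind} n={self.n_nodes} m={self.n_edges}>"

    # ------------------------------------------------------------ conversions
    def to_undirected(self) -> "GeneNetwork":
        """Drop edge direction; a reciprocal pair collapses to one edge.

        When both directions of a pair carry weights, the larger-|weight|
        record wins, so that undirected ranking stays faithful to the
        strongest prediction.
        """
        if not self.directed:
            return self.copy()
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, attrs in self.graph.edges(data=True):
            if g.has_edge(u, v):
                old = g[u][v]
                new_w = attrs.get("weight")
                old_w = old.get("weight")
                if new_w is not None and (
                    old_w is None or abs(new_w) > abs(old_w)
                ):
                    g[u][v].update(attrs)
            else:
                g.add_edge(u, v, **attrs)
        return GeneNetwork(g)

    def as_graph(self, mode: str | None = None) -> nx.Graph | nx.DiGraph:
        """The underlying networkx graph, converted to ``mode`` if requested."""
        if mode is None:
            return self.graph
        _check_mode(mode)
        if mode == UNDIRECTED:
            return self.to_undirected().graph
        if not self.directed:
            raise ModeMismatchError(
                "cannot evaluate an undirected network in directed mode"
            )
        return self.graph


@dataclass
class SamplerConfig:
    """Parameters of one ground-truth network sampler.

    ``network_class`` selects among Erdös–Renyi (``ER``), Scale-Free (``SF``),
    Semi-Scale-Free (``SSF``), Watts–Strogatz Small-World (``SW``) and
    ``curated`` (file-loaded) networks.  ``m`` is the target edge count, ``p``
    the ER connection / SW rewiring probability, ``alpha_in``/``alpha_out``
    the power-law exponents, and ``k`` the SW lattice degree.
    """

    network_class: str = "ER"
    n: int = 15
    m: int = 50
    p: float = 0.1
    alpha_in: float = 2.5
    alpha_out: float = 2.5
    k: int = 4
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> "SamplerConfig":
        if self.network_class not in ("ER", "SF", "SSF", "SW", "curated"):
            raise InvalidConfigError(
                f"unknown network class {self.network_class!r}"
            )
        if self.n < 2:
            raise InvalidConfigError("need at least 2 nodes")
        if self.network_class in ("ER", "SF", "SSF") and not (
            1 <= self.m <= self.n * (self.n - 1)
        ):
            raise InvalidConfigError(
                f"edge count m={self.m} outside [1, n(n-1)] for n={self.n}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise InvalidConfigError("p must lie in [0, 1]")
        if self.network_class == "SF" and (
            self.alpha_in <= 1 or self.alpha_out <= 1
        ):
            raise InvalidConfigError("power-law exponents must exceed 1")
        if self.network_class == "SW":
            if self.k % 2 != 0 or self.k >= self.n:
                raise InvalidConfigError("SW requires even k with k < n")
        return self


# ---------------------------------------------------------------------- files
def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def load_network(path: str | Path, fmt: str = "edge-list") -> GeneNetwork:
    """Load a directed network from a delimited edge-list file.

    ``fmt`` is ``"edge-list"`` (columns ``Gene1, Gene2[, Type, Weight]``) or
    ``"refNetwork"`` (the interchange dialect with ``Gene1,Gene2,Type`` and
    ``Type`` in ``{+, -}``).  Both are parsed identically; the name records
    intent.  Self-loops are retained at load time — they are removed only by
    :func:`preprocess_ground_truth`.
    """
    if fmt not in ("edge-list", "refNetwork"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyNetworkError(f"{path} is empty")
    return parse_edge_list(text, source=str(path))


def parse_edge_list(text: str, source: str = "<string>") -> GeneNetwork:
    """Parse edge-list text (header required) into a directed GeneNetwork."""
    lines = io.StringIO(text)
    header_line = lines.readline()
    delim = _sniff_delimiter(header_line)
    reader = csv.reader(lines, delimiter=delim)
    header = [h.strip() for h in header_line.strip().split(delim)]
    lower = [h.lower() for h in header]
    if "gene1" not in lower or "gene2" not in lower:
        raise ParseError(f"{source}: header must name Gene1 and Gene2", line=1)
    i_src, i_tgt = lower.index("gene1"), lower.index("gene2")
    i_type = lower.index("type") if "type" in lower else None
    i_w = lower.index("weight") if "weight" in lower else None

    g = nx.DiGraph()
    n_rows = 0
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) < max(i_src, i_tgt) + 1:
            raise ParseError(f"{source}: too few columns", line=lineno)
        u, v = row[i_src].strip(), row[i_tgt].strip()
        if not u or not v:
            raise ParseError(f"{source}: empty gene identifier", line=lineno)
        attrs = {}
        if i_type is not None and len(row) > i_type and row[i_type].strip():
            raw = row[i_type].strip()
            sign = _SIGN_ALIASES.get(raw.lower(), _SIGN_ALIASES.get(raw))
            if sign is None:
                raise ParseError(
                    f"{source}: unknown sign {raw!r}", line=lineno
                )
            attrs["sign"] = sign
        if i_w is not None and len(row) > i_w and row[i_w].strip():
            try:
                attrs["weight"] = float(row[i_w])
            except ValueError as exc:
                raise ParseError(
                    f"{source}: non-numeric weight {row[i_w]!r}", line=lineno
                ) from exc
        g.add_edge(u, v, **attrs)
        n_rows += 1
    if n_rows == 0:
        raise EmptyNetworkError(f"{source} contains a header but no edges")
    return GeneNetwork(g)


# ----------------------------------------------------------------- processing
def subset_to_genes(net: GeneNetwork, genes: set) -> GeneNetwork:
    """Restrict ``net`` to nodes that appear in ``genes``.

    Silver-standard reference networks are subset to the genes present in the
    matching expression dataset before evaluation.
    """
    if not genes:
        raise InvalidConfigError("gene set must be non-empty")
    keep = net.nodes & set(genes)
    if not keep:
        raise EmptyNetworkError("no network gene appears in the given set")
    return GeneNetwork(net.graph.subgraph(keep).copy())


def _largest_component(g: nx.Graph | nx.DiGraph) -> nx.Graph | nx.DiGraph:
    if g.number_of_nodes() == 0:
        return g
    if g.is_directed():
        comps = nx.weakly_connected_components(g)
    else:
        comps = nx.connected_components(g)
    largest = max(comps, key=lambda c: (len(c), sorted(c)[0]))
    return g.subgraph(largest).copy()


def preprocess_ground_truth(net: GeneNetwork, mode: str = UNDIRECTED) -> GeneNetwork:
    """Apply the ground-truth processing rules.

    Self-loops (and, implicitly, duplicate edges) are removed.  In directed
    mode the largest weakly connected subgraph is kept; in undirected mode
    edge directions are dropped first (reciprocal pairs merge) and the largest
    connected subgraph is extracted.
    """
    _check_mode(mode)
    if net.n_edges < 1:
        raise EmptyNetworkError("ground truth has no edges")
    g = net.graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    work = GeneNetwork(g)
    if mode == UNDIRECTED:
        work = work.to_undirected()
    out = _largest_component(work.graph)
    if out.number_of_nodes() < 2:
        raise DegenerateNetworkError(
            "processed ground truth has fewer than 2 nodes"
        )
    return GeneNetwork(out)


def preprocess_inferred(ranked, k: int, mode: str = UNDIRECTED) -> GeneNetwork:
    """Build the evaluation graph from a ranked edge list.

    Self-loops and duplicate records are dropped first; in undirected mode a
    directed list is symmetrized, the larger-|weight| record of a reciprocal
    pair winning.  The top ``k`` edges by absolute weight are then kept (ties
    broken by |weight| descending, then source and target ascending) and, if
    the result is disconnected, the largest (weakly) connected subgraph is
    extracted.
    """
    from .ranking import RankedEdgeList  # local import avoids a cycle

    _check_mode(mode)
    if not isinstance(ranked, RankedEdgeList):
        raise TypeError("preprocess_inferred expects a RankedEdgeList")
    if k < 1:
        raise InvalidConfigError("k must be a positive integer")
    if mode == DIRECTED and not ranked.directed:
        raise ModeMismatchError(
            "an undirected ranked list cannot be evaluated in directed mode"
        )
    clean = ranked.clean()
    if mode == UNDIRECTED:
        clean = clean.symmetrized()
    if len(clean) == 0:
        raise EmptyNetworkError("ranked list has no usable records")
    if len(clean) < k:
        warnings.warn(
            f"ranked list holds {len(clean)} usable edges, fewer than k={k}; "
            "using all of them",
            stacklevel=2,
        )
    top = clean.top_k(k)
    directed = mode == DIRECTED
    g = nx.DiGraph() if directed else nx.Graph()
    for rec in top.records():
        g.add_edge(rec.source, rec.target, weight=rec.weight)
    out = _largest_component(g)
    if out.number_of_nodes() < 2:
        raise DegenerateNetworkError("processed inferred network is degenerate")
    return GeneNetwork(out)
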