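"""Ranked edge lists — the interchange substrate of GRN inference output.

Every inference algorithm, built-in or external, is reduced to a list of
``(source, target, weight)`` records ranked by absolute weight.  The on-disk
dialect is the ``rankedEdges`` format used across the single-cell GRN
benchmarking ecosystem: a delimited file with header
``Gene1  Gene2  EdgeWeight`` (tab or comma).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import ParseError

#: default directedness of well-known algorithms' outputs; overridable.
ALGORITHM_DIRECTEDNESS = {
    "GRNBoost2": True,
    "SINCERITIES": True,
    "PIDC": False,
    "PPCOR": False,
    "correlation": False,
    "partial_correlation": False,
}


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    weight: float


class RankedEdgeList:
    """An algorithm's predicted edges, ranked by ``|weight|``."""

    def __init__(
        self,
        records: Iterable[tuple],
        algorithm: str = "unknown",
        directed: bool = True,
    ):
        self._records = [
            rec if isinstance(rec, EdgeRecord) else EdgeRecord(*rec)
            for rec in records
        ]
        self.algorithm = algorithm
        self.directed = directed

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> Iterator[EdgeRecord]:
        return iter(self._records)

    def _replace(self, records) -> "RankedEdgeList":
        return RankedEdgeList(records, algorithm=self.algorithm, directed=self.directed)

    # -------------------------------------------------------------- cleaning
    def clean(self) -> "RankedEdgeList":
        """Drop self-loops and collapse duplicate ordered pairs, keeping the
        maximum-|weight| record of each pair."""
        best: dict[tuple, EdgeRecord] = {}
        for rec in self._records:
            if rec.source == rec.target:
                continue
            key = (rec.source, rec.target)
            old = best.get(key)
            if old is None or abs(rec.weight) > abs(old.weight):
                best[key] = rec
        return self._replace(best.values())

    def symmetrized(self) -> "RankedEdgeList":
        """Collapse reciprocal ordered pairs to one undirected record, keeping
        the larger |weight|; record stored with source ≤ target."""
        best: dict[frozenset, EdgeRecord] = {}
        for rec in self.clean().records():
            key = frozenset((rec.source, rec.target))
            u, v = sorted((rec.source, rec.target))
            cand = EdgeRecord(u, v, rec.weight)
            old = best.get(key)
            if old is None or abs(cand.weight) > abs(old.weight):
                best[key] = cand
        out = self._replace(best.values())
        out.directed = False
        return out

    def sorted(self) -> "RankedEdgeList":
        """Deterministic ranking: |weight| descending, then source, target."""
        recs = sorted(
            self._records,
            key=lambda r: (-abs(r.weight), r.source, r.target),
        )
        return self._replace(recs)

    def top_k(self, k: int) -> "RankedEdgeList":
        return self._replace(self.sorted()._records[:k])

    # ------------------------------------------------------------------- I/O
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.source, r.target, r.weight) for r in self.sorted().records()],
            columns=["Gene1", "Gene2", "EdgeWeight"],
        )

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_network(cls, net, algorithm: str = "network") -> "RankedEdgeList":
        """Turn a (possibly weighted) network back into a ranked list;
        unweighted edges get weight 1."""
        recs = [
            EdgeRecord(u, v, attrs.get("weight", 1.0))
            for u, v, attrs in net.graph.edges(data=True)
        ]
        return cls(recs, algorithm=algorithm, directed=net.directed)


def read_ranked_edges(
    path: str | Path,
    algorithm: str | None = None,
    directed: bool | None = None,
) -> RankedEdgeList:
    """Read a ``rankedEdges`` file (header ``Gene1, Gene2, EdgeWeight``).

    Duplicate ordered pairs collapse keeping the maximum |weight|.  The
    directedness is looked up in :data:`ALGORITHM_DIRECTEDNESS` by algorithm
    name unless overridden; unknown algorithms default to directed.
    """
    path = Path(path)
    if algorithm is None:
        algorithm = path.stem
    header = path.open().readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse ({exc})") from exc
    cols = {c.lower(): c for c in df.columns}
    for needed in ("gene1", "gene2", "edgeweight"):
        if needed not in cols:
            raise ParseError(f"{path}: missing column {needed!r}", line=1)
    weights = pd.to_numeric(df[cols["edgeweight"]], errors="coerce")
    bad = weights.isna() & df[cols["edgeweight"]].notna()
    if bad.any() or weights.isna().any():
        lineno = int(weights.isna().idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: non-numeric or missing EdgeWeight", line=lineno)
    if directed is None:
        directed = ALGORITHM_DIRECTEDNESS.get(algorithm, True)
    recs = [
        EdgeRecord(str(s), str(t), float(w))
        for s, t, w in zip(df[cols["gene1"]], df[cols["gene2"]], weights)
    ]
    return RankedEdgeList(recs, algorithm=algorithm, directed=directed).clean()
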