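"""Built-in baseline GRN inference.

Two correlation-based predictors ship with the package:

* :func:`infer_correlation` — Pearson correlation across cells for every
  unordered gene pair;
* :func:`infer_partial_correlation` — partial correlation from the
  (pseudo-)inverse of the gene–gene correlation matrix,
  w(i, j) = −P_ij / sqrt(P_ii · P_jj), the classical Gaussian graphical
  estimate also produced by the PPCOR family of tools.

Both return undirected :class:`~grnbench.ranking.RankedEdgeList`s ranked by
absolute weight.  External algorithms (GRNBoost2, PIDC, SINCERITIES, ...)
enter the pipeline through :func:`~grnbench.ranking.read_ranked_edges`.
Inference is deterministic: no randomness is involved.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .errors import InsufficientDataError
from .ranking import EdgeRecord, RankedEdgeList
from .simulate import ExpressionDataset

# re-exported for convenience: the adapter for external algorithms
from .ranking import ALGORITHM_DIRECTEDNESS, read_ranked_edges  # noqa: F401

log = logging.getLogger(__name__)


def _check_dataset(ds: ExpressionDataset) -> None:
    if ds.n_cells < 3:
        raise InsufficientDataError("need at least 3 cells")
    if ds.n_genes < 2:
        raise InsufficientDataError("need at least 2 genes")


def _correlation_matrix(ds: ExpressionDataset) -> np.ndarray:
    """Gene–gene Pearson correlations; constant genes get zero correlation
    to every other gene (and unit self-correlation) rather than NaN."""
    x = ds.values
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.atleast_2d(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def infer_correlation(ds: ExpressionDataset) -> RankedEdgeList:
    """Rank every unordered gene pair by Pearson correlation."""
    _check_dataset(ds)
    corr = _correlation_matrix(ds)
    recs = [
        EdgeRecord(ds.genes[i], ds.genes[j], float(corr[i, j]))
        for i, j in combinations(range(ds.n_genes), 2)
    ]
    return RankedEdgeList(recs, algorithm="correlation", directed=False)


def infer_partial_correlation(ds: ExpressionDataset) -> RankedEdgeList:
    """Rank every unordered gene pair by partial correlation.

    The partial correlation of genes i and j given all remaining genes is
    −P_ij / sqrt(P_ii · P_jj) with P the inverse correlation matrix; a
    singular correlation matrix falls back to the Moore–Penrose
    pseudo-inverse with a logged warning.
    """
    _check_dataset(ds)
    corr = _correlation_matrix(ds)
    singular = False
    try:
        if np.linalg.cond(corr) > 1e12:
            singular = True
        else:
            prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        log.warning(
            "correlation matrix is singular or ill-conditioned; using the "
            "Moore-Penrose pseudo-inverse"
        )
        prec = np.linalg.pinv(corr, hermitian=True)
    if not np.isfinite(prec).all():
        prec = np.linalg.pinv(corr, hermitian=True)
    diag = np.diag(prec).copy()
    # genes decoupled from the rest (e.g. constant) have P_ii = 1 and zero
    # off-diagonals, which already yields zero weights
    safe = np.where(np.abs(diag) > 0, np.abs(diag), 1.0)
    denom = np.sqrt(np.outer(safe, safe))
    pc = -prec / denom
    recs = [
        EdgeRecord(ds.genes[i], ds.genes[j], float(pc[i, j]))
        for i, j in combinations(range(ds.n_genes), 2)
    ]
    return RankedEdgeList(recs, algorithm="partial_correlation", directed=False)


BUILTIN_ALGORITHMS = {
    "correlation": infer_correlation,
    "partial_correlation": infer_partial_correlation,
}
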