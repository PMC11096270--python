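"""Aggregated algorithm ranking and cross-metric correlation analysis.

Per-network evaluation records are condensed into one final score per
(metric, algorithm) and one overall score per metric group:

* graph-level metrics: per-type mean signed error S1 → per-type max-scaled
  magnitude S2 = |S1| / max_a |S1| → S3 = 1 − mean over types of S2 →
  final F = S3 / max_a S3 (so the best algorithm per metric scores 1);
* hub metrics: per-type mean of (J/J_rand − 1), max-scaled per type, averaged
  over types, clipped at 0 (random-level performance maps to 0) and
  max-scaled into F;
* groups: T1 = Σ F over the group's metrics; T2 = T1 / max_a T1.

The correlation analysis pools per-network performance scores (−|signed
error| for graph metrics, J/J_rand for hub metrics, EPr/AUROC/AUPRC for edge
prediction) and reports Spearman's ρ with two-sided p-values for every score
pair, flagged at the 0.01 level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AggregationError
from .evaluate import EvaluationRecord, HubEvaluation
from .metrics import (
    CENTRALITY_METRIC_NAMES,
    GRAPH_METRIC_NAMES,
    HUB_TOPOLOGY_METRICS,
    INFORMATION_EXCHANGE_METRICS,
)

log = logging.getLogger(__name__)

DEFAULT_GROUPS = {
    "information_exchange": INFORMATION_EXCHANGE_METRICS,
    "hub_topology": HUB_TOPOLOGY_METRICS,
    "hub_identification": CENTRALITY_METRIC_NAMES,
    "overall": GRAPH_METRIC_NAMES + CENTRALITY_METRIC_NAMES,
}


def _pivot(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    """(algorithm, type, value) rows → algorithms × types mean table."""
    df = pd.DataFrame(rows, columns=["algorithm", "type", "value"])
    return df.pivot_table(
        index="algorithm", columns="type", values="value", aggfunc="mean"
    )


def score_mse_metric(
    records: list[EvaluationRecord], metric: str
) -> dict[str, pd.DataFrame | pd.Series]:
    """S1, S2 (algorithms × types) and S3, F (per algorithm) for one
    graph-level metric."""
    rows = [
        (r.algorithm, r.network_class, r.signed_error)
        for r in records
        if r.metric == metric
    ]
    if not rows:
        raise AggregationError(f"no records for metric {metric!r}")
    s1 = _pivot(rows)
    if s1.isna().any().any():
        raise AggregationError(
            f"metric {metric!r}: missing (algorithm, type) combinations"
        )
    abs_s1 = s1.abs()
    col_max = abs_s1.max(axis=0)
    s2 = abs_s1.divide(col_max.where(col_max > 0, 1.0), axis=1)
    s2.loc[:, col_max == 0] = 0.0  # all algorithms exact: no error to scale
    s3 = 1.0 - s2.mean(axis=1)
    f_max = s3.max()
    f = s3 / f_max if f_max > 0 else pd.Series(1.0, index=s3.index)
    return {"S1": s1, "S2": s2, "S3": s3, "F": f}


def score_hub_metric(
    hub_evals: list[HubEvaluation], metric: str
) -> dict[str, pd.DataFrame | pd.Series]:
    """J1, J2 (algorithms × types) and J3, F (per algorithm) for one hub
    identification metric."""
    rows = [
        (h.algorithm, h.network_class, h.ratio - 1.0)
        for h in hub_evals
        if h.metric == metric
    ]
    if not rows:
        raise AggregationError(f"no hub evaluations for metric {metric!r}")
    j1 = _pivot(rows)
    if j1.isna().any().any():
        raise AggregationError(
            f"hub metric {metric!r}: missing (algorithm, type) combinations"
        )
    col_max = j1.max(axis=0)
    j2 = j1.divide(col_max.where(col_max > 0, 1.0), axis=1)
    dead = col_max <= 0
    if dead.any():
        log.warning(
            "hub metric %s: no algorithm beats random for type(s) %s; "
            "their scaled scores are set to 0",
            metric,
            list(col_max.index[dead]),
        )
        j2.loc[:, dead] = 0.0
    j3 = j2.mean(axis=1).clip(lower=0.0)
    f_max = j3.max()
    f = j3 / f_max if f_max > 0 else pd.Series(0.0, index=j3.index)
    return {"J1": j1, "J2": j2, "J3": j3, "F": f}


def overall_scores(
    f_by_metric: dict[str, pd.Series],
    groups: dict[str, tuple] | None = None,
) -> dict[str, pd.DataFrame]:
    """T1 (sum of final scores per group) and T2 (max-scaled T1)."""
    groups = dict(groups or DEFAULT_GROUPS)
    t1 = {}
    for group, metric_names in groups.items():
        missing = [m for m in metric_names if m not in f_by_metric]
        if missing:
            raise AggregationError(
                f"group {group!r} lacks final scores for {missing}"
            )
        t1[group] = sum(f_by_metric[m] for m in metric_names)
    t1 = pd.DataFrame(t1)
    col_max = t1.max(axis=0)
    t2 = t1.divide(col_max.where(col_max > 0, 1.0), axis=1)
    return {"T1": t1, "T2": t2}


def ranking_table(
    f_by_metric: dict[str, pd.Series],
    groups: dict[str, tuple] | None = None,
) -> pd.DataFrame:
    """Algorithms × (per-metric F, per-group T2, per-group rank) table —
    the machine-readable summary of the benchmark."""
    overall = overall_scores(f_by_metric, groups)
    out = pd.DataFrame({f"F_{m}": s for m, s in f_by_metric.items()})
    for group in overall["T2"].columns:
        out[f"T2_{group}"] = overall["T2"][group]
    for group in overall["T2"].columns:
        out[f"rank_{group}"] = (
            overall["T2"][group].rank(ascending=False, method="min").astype(int)
        )
    return out.sort_values("rank_overall") if "rank_overall" in out else out


# ----------------------------------------------------------- correlations
@dataclass
class CorrelationReport:
    rho: pd.DataFrame
    p_value: pd.DataFrame
    significant: pd.DataFrame  # boolean mask, p <= alpha
    alpha: float = 0.01


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n ≤ 10)."""
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count, total = 0, 0
    perm_iter = permutations(range(n))
    while True:
        batch = list(islice(perm_iter, 50_000))
        if not batch:
            break
        idx = np.array(batch)
        rhos = (rx[idx] * ry).mean(axis=1)
        count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(batch)
    return count / total


def spearman_rho_p(x, y) -> tuple[float, float]:
    """Spearman's ρ with a two-sided p-value (exact permutation for n ≤ 10,
    t-approximation otherwise).  Returns (nan, nan) for constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        return rho, _spearman_exact_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def performance_correlation(
    records: list[EvaluationRecord] | None = None,
    hub_evals: list[HubEvaluation] | None = None,
    edge_scores: pd.DataFrame | None = None,
    alpha: float = 0.01,
    min_pairs: int = 5,
) -> CorrelationReport:
    """Spearman correlations between all per-network performance scores.

    Observations are (network, algorithm) pairs; the score columns are
    −|signed error| per graph metric, J/J_rand per hub metric, and
    EPr/AUROC/AUPRC when an ``edge_scores`` table (columns network_id,
    algorithm, EPr, AUROC, AUPRC) is given.
    """
    frames = []
    if records:
        df = pd.DataFrame(
            [
                (r.network_id, r.algorithm, r.metric, -abs(r.signed_error))
                for r in records
            ],
            columns=["network_id", "algorithm", "metric", "score"],
        )
        frames.append(df)
    if hub_evals:
        df = pd.DataFrame(
            [
                (h.network_id, h.algorithm, h.metric, h.ratio)
                for h in hub_evals
            ],
            columns=["network_id", "algorithm", "metric", "score"],
        )
        frames.append(df)
    if edge_scores is not None and len(edge_scores):
        melted = edge_scores.melt(
            id_vars=["network_id", "algorithm"],
            value_vars=[c for c in ("EPr", "AUROC", "AUPRC") if c in edge_scores],
            var_name="metric",
            value_name="score",
        )
        frames.append(melted)
    if not frames:
        raise AggregationError("nothing to correlate")
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(
        index=["network_id", "algorithm"], columns="metric", values="score"
    )
    cols = list(wide.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            sub = wide[[a, b]].dropna() if a != b else wide[[a]].dropna()
            if a == b:
                ok = len(sub) >= min_pairs and sub[a].std() > 0
                r, p = (1.0, 0.0) if ok else (np.nan, np.nan)
            elif len(sub) < min_pairs:
                r, p = np.nan, np.nan
            else:
                r, p = spearman_rho_p(sub[a].to_numpy(), sub[b].to_numpy())
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return CorrelationReport(
        rho=rho, p_value=pval, significant=pval <= alpha, alpha=alpha
    )
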