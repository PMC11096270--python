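"""End-to-end orchestration: sample → simulate → infer → evaluate → aggregate.

:func:`run_benchmark` drives the whole benchmark from a
:class:`BenchmarkConfig`, writing per-network artifacts (ground truth,
expression dataset, ranked edge lists) and global evaluation tables into a
run directory.  Per-network seeds are derived from the global seed with a
counter-based scheme, so adding networks or classes never perturbs the
networks already defined.  Stage failures skip the affected network (with a
logged reason) rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    DEFAULT_GROUPS,
    performance_correlation,
    ranking_table,
    score_hub_metric,
    score_mse_metric,
)
from .errors import GrnBenchError, InvalidConfigError
from .evaluate import (
    EvaluationRecord,
    HubEvaluation,
    edge_prediction_scores,
    hub_identification_score,
)
from .infer import BUILTIN_ALGORITHMS
from .metrics import CENTRALITY_METRIC_NAMES, GRAPH_METRICS
from .network import (
    DIRECTED,
    UNDIRECTED,
    GeneNetwork,
    SamplerConfig,
    preprocess_ground_truth,
    preprocess_inferred,
)
from .ranking import RankedEdgeList, read_ranked_edges
from .samplers import sample
from .simulate import (
    KineticParams,
    assign_edge_signs,
    network_to_boolean_rules,
    simulate_cells,
    write_dataset,
)

log = logging.getLogger(__name__)

#: per-class parameter grids cycled over replicates (alpha exponents for the
#: power-law classes; lattice degree and rewiring probability for SW)
CLASS_GRIDS: dict[str, list[dict]] = {
    "ER": [{}],
    "SF": [
        {"alpha_in": ai, "alpha_out": ao}
        for ai in (2.0, 2.5, 3.0)
        for ao in (2.0, 2.5, 3.0)
    ],
    "SSF": [{"alpha_out": ao} for ao in (2.0, 2.5, 3.0)],
    "SW": [
        {"k": k, "p": p} for k in (4, 6) for p in (0.1, 0.3, 0.5)
    ],
}


@dataclass
class ExternalAlgorithm:
    """A directory of pre-computed rankedEdges files, one per network id."""

    name: str
    path: str
    directed: bool

    def ranked_for(self, network_id: str) -> RankedEdgeList | None:
        base = Path(self.path)
        for cand in (
            base / f"{network_id}.tsv",
            base / f"{network_id}.csv",
            base / network_id / "rankedEdges.csv",
        ):
            if cand.exists():
                return read_ranked_edges(
                    cand, algorithm=self.name, directed=self.directed
                )
        return None


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run."""

    classes: tuple = ("ER", "SF", "SSF", "SW")
    n: int = 15
    m: int = 50
    replicates: int = 10
    num_cells: int = 100
    t_max: float = 5.0
    dt: float = 0.01
    kinetics: KineticParams = field(default_factory=KineticParams)
    activator_prob: float = 1.0
    algorithms: tuple = ("correlation", "partial_correlation")
    external: list[ExternalAlgorithm] = field(default_factory=list)
    modes: tuple = (UNDIRECTED,)
    hub_fraction: float = 0.1
    seed: int = 0
    out_dir: str = "benchmark_out"

    def validate(self) -> "BenchmarkConfig":
        if self.replicates < 1:
            raise InvalidConfigError("replicates must be >= 1")
        if not 0 < self.hub_fraction <= 0.5:
            raise InvalidConfigError("hub fraction must lie in (0, 0.5]")
        for mode in self.modes:
            if mode not in (UNDIRECTED, DIRECTED):
                raise InvalidConfigError(f"unknown mode {mode!r}")
        for alg in self.algorithms:
            if alg not in BUILTIN_ALGORITHMS:
                raise InvalidConfigError(f"unknown built-in algorithm {alg!r}")
        for ext in self.external:
            if ext.directed is None:
                raise InvalidConfigError(
                    f"external algorithm {ext.name!r} must declare directedness"
                )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kin = KineticParams(**raw.pop("kinetics", {}))
        ext = [ExternalAlgorithm(**e) for e in raw.pop("external", [])]
        for key in ("classes", "algorithms", "modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(kinetics=kin, external=ext, **raw).validate()


def _stable_id(name: str) -> int:
    """Process-independent small integer id for a string label."""
    return zlib.crc32(name.encode()) % (2**20)


def _derived_seed(global_seed: int, *counters: int) -> int:
    """Counter-based child seed, stable under adding later networks."""
    ss = np.random.SeedSequence([int(global_seed), *map(int, counters)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sampler_config_for(
    config: BenchmarkConfig, network_class: str, replicate: int
) -> SamplerConfig:
    """The sampler settings of one replicate: grid entry + derived seed.

    SW cannot hit an arbitrary edge target (m = n·k/2 by construction), so
    its nominal m is ignored in favor of the lattice parameters.
    """
    grid = CLASS_GRIDS[network_class]
    params = dict(grid[replicate % len(grid)])
    seed = _derived_seed(config.seed, _stable_id(network_class), replicate)
    return SamplerConfig(
        network_class=network_class,
        n=config.n,
        m=config.m,
        seed=seed,
        **params,
    )


def _evaluate_network(
    config: BenchmarkConfig,
    network_id: str,
    network_class: str,
    truth_signed: GeneNetwork,
    ranked_lists: dict[str, RankedEdgeList],
    mode: str,
    records: list,
    hub_evals: list,
    edge_rows: list,
    skips: list,
) -> None:
    truth_p = preprocess_ground_truth(truth_signed, mode)
    k = truth_p.n_edges
    for alg, ranked in ranked_lists.items():
        if mode == DIRECTED and not ranked.directed:
            skips.append(
                {"network_id": network_id, "algorithm": alg, "mode": mode,
                 "reason": "undirected output cannot be scored in directed mode"}
            )
            continue
        try:
            inferred_p = preprocess_inferred(ranked, k, mode)
            scores = edge_prediction_scores(ranked, truth_p, mode)
            edge_rows.append(
                {
                    "network_id": network_id,
                    "class": network_class,
                    "algorithm": alg,
                    "mode": mode,
                    "EPr": scores.EPr,
                    "AUROC": scores.AUROC,
                    "AUPRC": scores.AUPRC,
                    "k": scores.k,
                }
            )
            for metric, fn in GRAPH_METRICS.items():
                records.append(
                    EvaluationRecord(
                        network_id=network_id,
                        network_class=network_class,
                        algorithm=alg,
                        mode=mode,
                        metric=metric,
                        truth=fn(truth_p, mode),
                        inferred=fn(inferred_p, mode),
                    )
                )
            for metric in CENTRALITY_METRIC_NAMES:
                ev = hub_identification_score(
                    truth_p,
                    inferred_p,
                    metric,
                    mode,
                    fraction=config.hub_fraction,
                    network_id=network_id,
                    network_class=network_class,
                    algorithm=alg,
                )
                if ev is not None:
                    hub_evals.append(ev)
        except GrnBenchError as exc:
            log.warning("skipping %s/%s/%s: %s", network_id, alg, mode, exc)
            skips.append(
                {"network_id": network_id, "algorithm": alg, "mode": mode,
                 "reason": str(exc)}
            )


def _records_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "network_id": r.network_id,
                "class": r.network_class,
                "algorithm": r.algorithm,
                "mode": r.mode,
                "metric": r.metric,
                "truth": r.truth,
                "inferred": r.inferred,
                "signed_error": r.signed_error,
            }
            for r in records
        ]
    )


def _hubs_frame(hub_evals: list[HubEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "network_id": h.network_id,
                "class": h.network_class,
                "algorithm": h.algorithm,
                "mode": h.mode,
                "metric": h.metric,
                "n_common": h.n_common,
                "n_hubs": h.n_hubs,
                "J": h.jaccard,
                "J_rand": h.j_rand,
                "ratio": h.ratio,
            }
            for h in hub_evals
        ]
    )


def run_benchmark(config: BenchmarkConfig) -> Path:
    """Run the full three-step benchmark; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[EvaluationRecord] = []
    hub_evals: list[HubEvaluation] = []
    edge_rows: list[dict] = []
    skips: list[dict] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "networks": [],
    }

    for network_class in config.classes:
        for rep in range(config.replicates):
            network_id = f"{network_class}_{rep + 1}"
            net_dir = out / "networks" / network_id
            try:
                scfg = sampler_config_for(config, network_class, rep)
                truth = sample(scfg)
                signed = assign_edge_signs(
                    truth,
                    config.activator_prob,
                    seed=_derived_seed(config.seed, 1, _stable_id(network_id)),
                )
                model = network_to_boolean_rules(signed, config.kinetics)
                ds = simulate_cells(
                    model,
                    num_cells=config.num_cells,
                    t_max=config.t_max,
                    dt=config.dt,
                    seed=_derived_seed(config.seed, 2, _stable_id(network_id)),
                )
                write_dataset(ds, signed, net_dir)
            except GrnBenchError as exc:
                log.warning("skipping network %s: %s", network_id, exc)
                skips.append(
                    {"network_id": network_id, "algorithm": "", "mode": "",
                     "reason": str(exc)}
                )
                continue

            ranked_lists: dict[str, RankedEdgeList] = {}
            for alg in config.algorithms:
                ranked = BUILTIN_ALGORITHMS[alg](ds)
                ranked.write(net_dir / f"rankedEdges_{alg}.tsv")
                ranked_lists[alg] = ranked
            for ext in config.external:
                ranked = ext.ranked_for(network_id)
                if ranked is None:
                    skips.append(
                        {"network_id": network_id, "algorithm": ext.name,
                         "mode": "", "reason": "no rankedEdges file"}
                    )
                else:
                    ranked_lists[ext.name] = ranked

            for mode in config.modes:
                _evaluate_network(
                    config, network_id, network_class, signed, ranked_lists,
                    mode, records, hub_evals, edge_rows, skips,
                )
            manifest["networks"].append(
                {"id": network_id, "class": network_class,
                 "sampler_seed": scfg.seed, "n": truth.n_nodes,
                 "m": truth.n_edges}
            )

    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    rec_df = _records_frame(records)
    hub_df = _hubs_frame(hub_evals)
    edge_df = pd.DataFrame(edge_rows)
    rec_df.to_csv(tables / "evaluation_records.csv", index=False)
    hub_df.to_csv(tables / "hub_evaluations.csv", index=False)
    edge_df.to_csv(tables / "edge_scores.csv", index=False)
    pd.DataFrame(skips).to_csv(tables / "skipped.csv", index=False)

    for mode in config.modes:
        mode_records = [r for r in records if r.mode == mode]
        mode_hubs = [h for h in hub_evals if h.mode == mode]
        if not mode_records:
            continue
        f_by_metric = {}
        for metric in GRAPH_METRICS:
            try:
                f_by_metric[metric] = score_mse_metric(mode_records, metric)["F"]
            except GrnBenchError as exc:
                log.warning("no aggregate for %s (%s): %s", metric, mode, exc)
        for metric in CENTRALITY_METRIC_NAMES:
            try:
                f_by_metric[metric] = score_hub_metric(mode_hubs, metric)["F"]
            except GrnBenchError as exc:
                log.warning("no aggregate for %s (%s): %s", metric, mode, exc)
        if all(m in f_by_metric for g in DEFAULT_GROUPS.values() for m in g):
            ranking_table(f_by_metric).to_csv(tables / f"ranking_{mode}.csv")
        try:
            mode_edges = (
                edge_df[edge_df["mode"] == mode] if len(edge_df) else None
            )
            report = performance_correlation(
                mode_records, mode_hubs, mode_edges
            )
            report.rho.to_csv(tables / f"correlation_rho_{mode}.csv")
            report.p_value.to_csv(tables / f"correlation_p_{mode}.csv")
            report.significant.to_csv(
                tables / f"correlation_significant_{mode}.csv"
            )
        except GrnBenchError as exc:
            log.warning("correlation analysis skipped (%s): %s", mode, exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _config_dict(config: BenchmarkConfig) -> dict:
    d = dataclasses.asdict(config)
    d["kinetics"] = dataclasses.asdict(config.kinetics)
    d["external"] = [dataclasses.asdict(e) for e in config.external]
    return d


# ------------------------------------------------------------------ fixtures
def generate_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Write small, fully determined test fixtures.

    One n=10 network per class, one simulated dataset, a hand-built ranked
    edge list scoring EPr = 2/3 against its triangle truth, and the worked
    aggregation example (two algorithms, one network type).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = {
        "ER": SamplerConfig("ER", n=10, m=20, seed=_derived_seed(seed, 10)),
        "SF": SamplerConfig("SF", n=10, m=20, seed=_derived_seed(seed, 11)),
        "SSF": SamplerConfig("SSF", n=10, m=20, seed=_derived_seed(seed, 12)),
        "SW": SamplerConfig("SW", n=10, k=4, p=0.1, seed=_derived_seed(seed, 13)),
    }
    nets = {}
    for cls_name, scfg in specs.items():
        net = sample(scfg)
        nets[cls_name] = net
        RankedEdgeList.from_network(net, algorithm=cls_name).write(
            out / f"network_{cls_name}.tsv"
        )
    signed = assign_edge_signs(nets["ER"], 1.0, seed=_derived_seed(seed, 20))
    ds = simulate_cells(
        network_to_boolean_rules(signed),
        num_cells=20,
        seed=_derived_seed(seed, 21),
    )
    write_dataset(ds, signed, out / "dataset_ER")

    # triangle truth + ranked list whose top-3 holds 2 true edges
    (out / "truth_triangle.csv").write_text(
        "Gene1,Gene2,Type\nA,B,+\nB,C,+\nC,A,+\n"
    )
    (out / "ranked_epr23.tsv").write_text(
        "Gene1\tGene2\tEdgeWeight\n"
        "A\tB\t0.9\nB\tC\t0.8\nA\tD\t0.7\nC\tA\t0.1\n"
    )
    # worked aggregation example: one type, S1 = {algA: 0.2, algB: 0.1}
    pd.DataFrame(
        {
            "network_id": ["t1_1", "t1_1"],
            "class": ["t1", "t1"],
            "algorithm": ["algA", "algB"],
            "mode": [UNDIRECTED, UNDIRECTED],
            "metric": ["global_efficiency", "global_efficiency"],
            "truth": [0.5, 0.5],
            "inferred": [0.7, 0.6],
            "signed_error": [0.2, 0.1],
        }
    ).to_csv(out / "aggregation_example.csv", index=False)
    return out
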