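"""Single-cell expression simulation from a signed regulatory network.

The simulator follows the Boolean-rules-to-stochastic-ODE scheme used to
generate synthetic single-cell data in GRN benchmarking: each gene's Boolean
rule is the disjunction of its activators AND the negated disjunction of its
repressors; the rule is relaxed to continuous dynamics with shifted Hill
functions and integrated by Euler–Maruyama with multiplicative square-root
noise (birth–death-like, keeps states near non-negative; negatives are
clipped to 0).  One cell is drawn from each independent trajectory at a
uniformly random time point, and that sampling time is the cell's pseudotime.

dx_i/dt = prod · f_i(x) − deg · x_i + noise · sqrt(x_i) · dW

with  f_i = basal + (1 − basal) · OR(activators) · (1 − OR(repressors)),
OR computed as a noisy-OR of per-regulator Hill activations
H(x) = x^h / (x^h + θ^h).  Genes with no regulators are constitutive:
f_i = basal, so their mean expression relaxes to basal · prod / deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    IntegrationError,
    InvalidConfigError,
    MissingSignError,
)
from .network import ACTIVATION, REPRESSION, GeneNetwork, parse_edge_list


@dataclass
class KineticParams:
    """Kinetic constants of the Hill-ODE relaxation (all per-gene-uniform).

    production and degradation are rates (1/time); hill_threshold defaults to
    half the steady-state scale production/degradation; noise_amplitude
    multiplies the sqrt-expression diffusion term; basal_fraction sets the
    leaky production floor.
    """

    production: float = 20.0
    degradation: float = 10.0
    hill_coefficient: float = 10.0
    hill_threshold: float | None = None
    noise_amplitude: float = 0.1
    basal_fraction: float = 0.01

    def resolved_threshold(self) -> float:
        if self.hill_threshold is not None:
            return self.hill_threshold
        return 0.5 * self.production / self.degradation

    def validate(self) -> "KineticParams":
        if self.production <= 0 or self.degradation <= 0:
            raise InvalidConfigError("rates must be positive")
        if self.hill_coefficient <= 0 or self.resolved_threshold() <= 0:
            raise InvalidConfigError("Hill parameters must be positive")
        if self.noise_amplitude < 0:
            raise InvalidConfigError("noise amplitude must be >= 0")
        if not 0 <= self.basal_fraction <= 1:
            raise InvalidConfigError("basal fraction must lie in [0, 1]")
        return self


@dataclass
class BooleanModel:
    """Per-gene activator/repressor sets plus kinetic constants."""

    genes: list[str]
    activators: dict[str, list[str]]
    repressors: dict[str, list[str]]
    kinetics: KineticParams = field(default_factory=KineticParams)

    def rule(self, gene: str) -> str:
        """Human-readable Boolean rule for one gene."""
        acts, reps = self.activators[gene], self.repressors[gene]
        if not acts and not reps:
            return "basal"
        parts = []
        if acts:
            parts.append("(" + " or ".join(acts) + ")")
        if reps:
            prefix = "not " if not acts else "and not "
            parts.append(prefix + "(" + " or ".join(reps) + ")")
        return " ".join(parts)


@dataclass
class ExpressionDataset:
    """Genes × cells expression matrix with per-cell pseudotime."""

    values: np.ndarray  # shape (n_genes, n_cells), non-negative
    genes: list[str]
    cells: list[str]
    pseudotime: np.ndarray  # shape (n_cells,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ConsistencyError("matrix shape does not match gene/cell names")
        if len(self.pseudotime) != len(self.cells):
            raise ConsistencyError("pseudotime length does not match cells")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


def assign_edge_signs(
    net: GeneNetwork, activator_prob: float = 1.0, seed: int = 0
) -> GeneNetwork:
    """Give every edge a regulatory sign: activation with probability
    ``activator_prob``, else repression.  Seeded and reproducible; edges
    already carrying a sign are re-signed."""
    if not net.directed:
        raise InvalidConfigError("edge signs require a directed network")
    if not 0 <= activator_prob <= 1:
        raise InvalidConfigError("activator_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = net.copy()
    for u, v in sorted(out.graph.edges()):
        sign = ACTIVATION if rng.random() < activator_prob else REPRESSION
        out.graph[u][v]["sign"] = sign
    return out


def network_to_boolean_rules(
    net: GeneNetwork, kinetics: KineticParams | None = None
) -> BooleanModel:
    """Convert a fully signed network into a Boolean model.

    Each gene's rule is OR(activators) AND NOT OR(repressors); genes without
    regulators become constitutive at the basal fraction.
    """
    genes = sorted(net.nodes)
    activators: dict[str, list[str]] = {g: [] for g in genes}
    repressors: dict[str, list[str]] = {g: [] for g in genes}
    for u, v, attrs in net.graph.edges(data=True):
        sign = attrs.get("sign")
        if sign == ACTIVATION:
            activators[v].append(u)
        elif sign == REPRESSION:
            repressors[v].append(u)
        else:
            raise MissingSignError(f"edge {u}->{v} carries no sign")
    for g in genes:
        activators[g].sort()
        repressors[g].sort()
    return BooleanModel(
        genes=genes,
        activators=activators,
        repressors=repressors,
        kinetics=(kinetics or KineticParams()).validate(),
    )


def _regulator_matrices(model: BooleanModel):
    """Boolean (gene × gene) masks marking activators and repressors."""
    idx = {g: i for i, g in enumerate(model.genes)}
    n = len(model.genes)
    act = np.zeros((n, n), dtype=bool)
    rep = np.zeros((n, n), dtype=bool)
    for g in model.genes:
        for a in model.activators[g]:
            act[idx[g], idx[a]] = True
        for r in model.repressors[g]:
            rep[idx[g], idx[r]] = True
    return act, rep


def simulate_cells(
    model: BooleanModel,
    num_cells: int = 100,
    t_max: float = 5.0,
    dt: float = 0.01,
    seed: int = 0,
    x0: float | np.ndarray | None = None,
) -> ExpressionDataset:
    """Euler–Maruyama simulation; one cell sampled per trajectory.

    ``num_cells`` independent trajectories are integrated over [0, t_max];
    from each, the state at one uniformly random grid time is recorded as one
    cell, with that time as the cell's pseudotime.  Initial expression is
    uniform on [0, production/degradation] per gene and cell unless ``x0``
    (scalar or gene × cell array) is given.
    """
    if num_cells < 1:
        raise InvalidConfigError("num_cells must be >= 1")
    if t_max <= 0 or dt <= 0 or dt > t_max:
        raise InvalidConfigError("need 0 < dt <= t_max")
    kin = model.kinetics.validate()
    rng = np.random.default_rng(seed)
    act, rep = _regulator_matrices(model)
    n = len(model.genes)
    scale = kin.production / kin.degradation
    theta = kin.resolved_threshold()
    h = kin.hill_coefficient
    basal = kin.basal_fraction
    has_reg = act.any(axis=1) | rep.any(axis=1)

    n_steps = int(round(t_max / dt))
    sample_step = rng.integers(0, n_steps + 1, size=num_cells)
    if x0 is None:
        x = rng.uniform(0.0, scale, size=(n, num_cells))
    else:
        x = np.broadcast_to(np.asarray(x0, dtype=float), (n, num_cells)).copy()
    out = np.empty((n, num_cells))
    taken = sample_step == 0
    out[:, taken] = x[:, taken]

    sqrt_dt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            hill = x**h / (x**h + theta**h)
        hill = np.nan_to_num(hill, nan=0.0)
        # noisy-OR over regulator sets: 1 - prod(1 - H) restricted to the set
        log_off = np.log1p(-np.clip(hill, 0.0, 1.0 - 1e-12))
        or_act = 1.0 - np.exp(act @ log_off)
        or_rep = 1.0 - np.exp(rep @ log_off)
        logic = np.where(act.any(axis=1)[:, None], or_act, 1.0) * (1.0 - or_rep)
        f = np.where(has_reg[:, None], basal + (1 - basal) * logic, basal)
        drift = kin.production * f - kin.degradation * x
        noise = kin.noise_amplitude * np.sqrt(np.maximum(x, 0.0))
        x = x + drift * dt + noise * sqrt_dt * rng.standard_normal(x.shape)
        x = np.maximum(x, 0.0)
        if not np.isfinite(x).all():
            bad_gene, bad_cell = np.argwhere(~np.isfinite(x))[0]
            raise IntegrationError(
                f"non-finite expression for gene {model.genes[bad_gene]} "
                f"at step {step} (cell {bad_cell})"
            )
        taken = sample_step == step
        out[:, taken] = x[:, taken]

    cells = [f"C{i + 1}" for i in range(num_cells)]
    pseudotime = sample_step * dt
    return ExpressionDataset(
        values=out, genes=list(model.genes), cells=cells, pseudotime=pseudotime
    )


# --------------------------------------------------------------------- files
def write_dataset(
    ds: ExpressionDataset, net: GeneNetwork, out_dir: str | Path
) -> None:
    """Write the interchange triplet: ExpressionData.csv (genes × cells),
    PseudoTime.csv and refNetwork.csv."""
    if ds.n_genes == 0 or ds.n_cells == 0:
        raise InvalidConfigError("refusing to write an empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds.to_dataframe().to_csv(
        out_dir / "ExpressionData.csv", float_format="%.12g", index_label=""
    )
    pd.DataFrame({"": ds.cells, "PseudoTime": ds.pseudotime}).to_csv(
        out_dir / "PseudoTime.csv", float_format="%.12g", index=False
    )
    rows = []
    for u, v, attrs in sorted(net.graph.edges(data=True)):
        sign = attrs.get("sign", ACTIVATION)
        rows.append((u, v, "+" if sign == ACTIVATION else "-"))
    pd.DataFrame(rows, columns=["Gene1", "Gene2", "Type"]).to_csv(
        out_dir / "refNetwork.csv", index=False
    )


def read_dataset(in_dir: str | Path) -> tuple[ExpressionDataset, GeneNetwork]:
    """Inverse of :func:`write_dataset`."""
    in_dir = Path(in_dir)
    expr = pd.read_csv(in_dir / "ExpressionData.csv", index_col=0)
    pt = pd.read_csv(in_dir / "PseudoTime.csv")
    pt_cells = [str(c) for c in pt.iloc[:, 0]]
    cells = [str(c) for c in expr.columns]
    if set(pt_cells) != set(cells) or len(pt_cells) != len(cells):
        raise ConsistencyError(
            "PseudoTime cells do not match ExpressionData columns"
        )
    times = dict(zip(pt_cells, pt["PseudoTime"].astype(float)))
    ds = ExpressionDataset(
        values=expr.to_numpy(dtype=float),
        genes=[str(g) for g in expr.index],
        cells=cells,
        pseudotime=np.array([times[c] for c in cells]),
    )
    net = parse_edge_list(
        (in_dir / "refNetwork.csv").read_text(), source=str(in_dir / "refNetwork.csv")
    )
    return ds, net
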