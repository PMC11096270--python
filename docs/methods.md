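# Methods

This note documents the models, conventions and numerical choices behind
`grnbench`, in the order of the pipeline's three steps.

## 1. Ground-truth network samplers

All samplers emit directed graphs over gene labels `G1..Gn`, are
deterministic given `SamplerConfig.seed`, and never produce self-loops or
duplicate edges. The study sizes are 15 nodes / 50 edges and 25 nodes /
100 edges; parameter grids cycled over replicates default to
α ∈ {2, 2.5, 3} for the power-law classes and (k, p) ∈ {4, 6} × {0.1, 0.3,
0.5} for Small-World, all overridable.

* **ER.** Every ordered non-self pair is included independently with
  p = m / (n(n−1)), so the edge count is Binomial(n(n−1), p) with mean m.
* **SF.** Out- and in-degree sequences are drawn from a truncated discrete
  power law P(d) ∝ d^(−α) on d ∈ [1, n−1] and rescaled to sum exactly to m
  (floor + largest-fractional-part residual distribution). Stubs are paired
  uniformly; self-loops and duplicate edges are then removed by
  degree-preserving target swaps (the standard configuration-model repair),
  falling back to full resampling when the repair stalls (100 retries).
  Whole-sample rejection without repair is hopeless at the study densities —
  with mean degree > 3 and heavy-tailed out-degrees a collision is almost
  certain — whereas swaps preserve both marginal degree laws and the exact
  edge count.
* **SSF.** Exactly ⌊n/2⌋ regulator nodes are chosen uniformly; their
  out-degrees follow the truncated power law (minimum 1, so the 50%
  regulator fraction is exact), rescaled to sum to m; each regulator draws
  its targets uniformly without replacement from all other nodes, making
  in-degrees uniform in expectation.
* **SW.** A Watts–Strogatz graph (n nodes, lattice degree k, rewiring
  probability p) supplies the undirected skeleton of n·k/2 edges; each edge
  is then oriented in a uniformly random single direction. The model cannot
  hit an arbitrary edge target (m = n·k/2 by construction), so at the
  15-node size the preset uses k = 6 (45 edges); nothing downstream depends
  on the nominal m because the evaluation cutoff k always tracks the
  processed ground truth.

Curated or silver-standard networks enter through delimited edge lists
(`Gene1, Gene2[, Type, Weight]`, `Type ∈ {+, −}`); gene identifiers are
case-sensitive opaque strings, and silver standards are subset to the genes
of the paired expression dataset before processing.

## 2. Expression simulation

Each signed network becomes a Boolean model: gene i's rule is
`OR(activators) AND NOT OR(repressors)`; genes without regulators are
constitutive. The rule is relaxed to continuous dynamics

dx_i = [ m·f_i(x) − γ·x_i ] dt + σ·sqrt(x_i) dW,

where f_i = b + (1−b)·[1 − Π_a (1−H(x_a))]·Π_r (1−H(x_r)) (noisy-OR over
activators a, noisy-NOR over repressors r) and H(x) = x^h / (x^h + θ^h) is
the Hill activation. Defaults: production m = 20, degradation γ = 10 (so
the expression scale is m/γ = 2), Hill coefficient h = 10, threshold
θ = 0.5·m/γ, basal fraction b = 0.01, noise amplitude σ = 0.1, Euler step
dt = 0.01, horizon t_max = 5. The square-root (birth–death-like)
multiplicative noise keeps states near non-negative; residual negative
excursions are clipped at 0. A constitutive gene relaxes to b·m/γ along the
closed-form exponential, which the tests verify against the integrator.

Per dataset, `num_cells` (default 100) independent trajectories start from
per-gene uniform initial conditions on [0, m/γ]; each trajectory
contributes exactly one cell, recorded at a uniformly random grid time that
becomes the cell's pseudotime. Edge signs are assigned by
`assign_edge_signs` with activator probability 1 by default (all-activating
rules), configurable.

What this emulates — and what it does not: the generator produces
heterogeneous, pseudotime-annotated single-cell snapshots whose covariance
reflects the wiring of a known network. It is mRNA-only (no protein layer),
has no technical dropout or library-size variation, and no branching
lineages. Passing tests therefore demonstrate correct recovery behavior
under idealized kinetics, not performance on real scRNA-seq data. One
consequence worth knowing: without a slow protein layer the cross-cell
signal available to inference is modest, so the built-in predictors beat
the random-predictor baseline only narrowly at the default density
(50 directed edges over 15 genes is ~40% of undirected pairs).

## 3. Inference and interchange

The built-in baselines are Pearson correlation and partial correlation
(−P_ij/√(P_ii·P_jj), P the inverse gene–gene correlation matrix;
Moore–Penrose pseudo-inverse with a logged warning when the matrix is
singular or has condition number above 1e12). Both rank unordered pairs by
absolute weight and are deterministic. Zero-variance genes are retained
with zero weights so gene sets stay aligned with the ground truth.
Semi-partial correlations and edge signs are not used for ranking. External
algorithms are ingested as `rankedEdges` files (`Gene1 Gene2 EdgeWeight`);
duplicate ordered pairs collapse keeping the maximum-|weight| record, and a
per-algorithm registry supplies directedness (GRNBoost2, SINCERITIES
directed; PIDC, PPCOR undirected), overridable per file.

## 4. Processing rules

Ground truths lose self-loops and duplicates; directed evaluation keeps the
largest weakly connected component, undirected evaluation drops direction
first (reciprocal pairs merge) and keeps the largest connected component.
Inferred lists are cleaned the same way, symmetrized in undirected mode
(larger |weight| of a reciprocal pair wins), cut to the top k = (processed
ground-truth edge count) by |weight| with a deterministic tie-break
(|weight| descending, then source, target ascending), and reduced to one
component if disconnected. Processing is idempotent at fixed k. Networks
that end with fewer than two nodes abort that network's evaluation with a
logged skip rather than crashing the run.

## 5. Metrics: modes and degenerate-input conventions

Undirected variants use total degrees; directed variants use in-degrees for
assortativity and centralization (H_max = (n−1)(n−2) undirected,
(n−1)² directed), out-degrees for degree centrality, parents ∪ children as
the neighborhood for clustering and local efficiency, and
p_v = (n−1)(n−2)/2 vs (n−1)(n−2) for betweenness normalization. PageRank
uses damping 0.85, tolerance 1e−9, at most 1e5 power iterations, uniform
redistribution of dangling mass, and treats undirected graphs as
bidirected. Radiality is (diameter + 1) minus the mean distance to other
nodes, with the diameter the largest finite ordered distance.

Conventions for degenerate inputs (chosen as the natural limits of the
defining formulas, and mirrored by the brute-force oracle in the tests):
efficiency of a graph with < 2 nodes is 0; local clustering and local
efficiency of nodes with < 2 neighbors are 0; assortativity with zero
degree variance is 0; in directed mode, ordered pairs with no directed path
are excluded from path-length and radiality means (a node reaching no other
node gets radiality 0) and contribute 0 to global efficiency. Directed
clustering counts a neighbor pair as linked if an edge exists in either
direction, keeping CC_glob within [0, 1].

## 6. Scoring and aggregation

The mean signed error of metric P is mean over networks of
P(G_inferred) − P(G); the sign distinguishes over- from underestimation and
is deliberately not squared. Hub sets are the top
n₀ = max(1, round(0.1·|common nodes|)) common nodes by centrality
(half-up rounding, ties by label); the random baseline
J_rand = Σ_x [x/(2n₀−x)]·Hypergeom(x; n, n₀, n₀) is always computed exactly
(the (n₀/n)/(2−n₀/n) approximation is provided for cross-checking only).
Hub comparison requires at least 10 common nodes.

Aggregation follows the max-scaling ladder: S1 (per-type mean signed
error) → S2 = |S1| / max over algorithms (per type) → S3 = 1 − mean over
types → F = S3 / max; for hub metrics J1 = mean(J/J_rand − 1) → J2 per-type
max-scaled → J3 = max(0, mean over types) → F = J3 / max. Degenerate
conventions, taken from the scheme's intent that F rank algorithms: if all
algorithms tie exactly on a metric (max S3 = 0) every algorithm gets F = 1;
if no algorithm beats random on any type (max J3 = 0) every algorithm gets
F = 0; if a type's best J1 is ≤ 0 that type's scaled scores are 0 with a
warning. Group scores T1 sum F over the group's metrics
(information exchange: aspl, global and local efficiency; hub topology:
assortativity, centralization, clustering; hub identification: the four
centralities; overall: all ten) and T2 max-scales T1.

The correlation analysis pools per-network scores — −|signed error| for
graph metrics, J/J_rand for hub metrics, EPr/AUROC/AUPRC for edge
prediction — over (network, algorithm) observations and reports Spearman's
ρ with two-sided p-values (exact permutation enumeration for n ≤ 10, the
t-approximation above), flagged at p ≤ 0.01. Synthetic and experimental
pools are kept separate.

## 7. Pipeline, determinism and problem sizes

Per-network seeds derive from the global seed through
`SeedSequence([seed, stage, crc32(network_id)])`, so runs are bit-stable
and adding networks or classes never perturbs earlier ones. Every stage
reads and writes files in the run directory; skipped networks are recorded
with reasons. The default run — four classes × 10 replicates at the small
size, 100 cells each, built-in inference, undirected evaluation — completes
in seconds on one CPU; the test suite and the acceptance script use these
sizes. The AUROC/AUPRC computations use midrank tie handling, so constant
scores give exactly 0.5.

## Known limitations

* Simulation is mRNA-only and not bit-compatible with two-layer
  Boolean-ODE simulators; kinetic constants are order-of-magnitude choices.
* The SW class cannot match the nominal edge counts of the other classes
  exactly (see §1).
* External algorithms are consumed as ranked files only; the package never
  executes them.
* Directed-mode path-length and radiality require an unreachable-pair
  convention that is a package decision, not a property of the defining
  formulas.
* Weighted-edge metric variants, sign-aware evaluation and motif analysis
  are out of scope.
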