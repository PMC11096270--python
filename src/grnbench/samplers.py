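"""Samplers for the four parameter-controlled topology classes.

Ground-truth regulatory networks are drawn from four classes with distinct
structural signatures:

* **ER** — directed Erdös–Renyi G(n, p) with p chosen so the expected edge
  count equals the target m;
* **SF** — scale-free: in- and out-degree sequences drawn from discrete power
  laws P(d) ∝ d^(−α) and wired by a configuration model with exactly m edges;
* **SSF** — semi-scale-free: only half the nodes regulate, their out-degrees
  follow a power law, targets are uniform over all nodes;
* **SW** — Watts–Strogatz small-world skeleton, each undirected edge oriented
  in a uniformly random direction.

All samplers are deterministic given ``SamplerConfig.seed`` and never emit
self-loops or duplicate edges (ER draws pairs independently, so its edge
count — not its cleanliness — is random).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidConfigError, SamplingError
from .network import GeneNetwork, SamplerConfig

_MAX_RETRIES = 100


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def _build(edges, n) -> GeneNetwork:
    return GeneNetwork.from_edges(edges, directed=True, nodes=_gene_names(n))


def sample_er(config: SamplerConfig) -> GeneNetwork:
    """Directed Erdös–Renyi network with E[#edges] = m.

    Every ordered non-self pair (u, v) is included independently with
    probability p = m / (n·(n−1)).
    """
    config.validate()
    n, m = config.n, config.m
    if m > n * (n - 1):
        raise InvalidConfigError("m exceeds n(n-1)")
    rng = np.random.default_rng(config.seed)
    p = m / (n * (n - 1))
    names = _gene_names(n)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(names[i], names[j]) for i, j in zip(*np.nonzero(mask))]
    return _build(edges, n)


def _powerlaw_degree_sequence(
    n: int,
    alpha: float,
    m: int,
    rng: np.random.Generator,
    min_deg: int = 0,
    max_deg: int | None = None,
) -> np.ndarray:
    """Degree sequence of length n from a truncated discrete power law on
    [1, max_deg], rescaled to sum exactly to m (entries clipped to
    [min_deg, max_deg]); max_deg defaults to n−1."""
    if max_deg is None:
        max_deg = n - 1
    support = np.arange(1, max_deg + 1)
    probs = support.astype(float) ** (-alpha)
    probs /= probs.sum()
    raw = rng.choice(support, size=n, p=probs).astype(float)
    scaled = raw * (m / raw.sum())
    deg = np.floor(scaled).astype(int)
    deg = np.clip(deg, min_deg, max_deg)
    # distribute the residual, largest fractional parts first (ties by index)
    frac = scaled - np.floor(scaled)
    order = np.lexsort((np.arange(n), -frac))
    i = 0
    guard = 0
    while deg.sum() != m:
        guard += 1
        if guard > 10 * n * n:
            raise SamplingError("degree-sequence rescaling did not converge")
        idx = order[i % n]
        if deg.sum() < m and deg[idx] < max_deg:
            deg[idx] += 1
        elif deg.sum() > m and deg[idx] > min_deg:
            deg[idx] -= 1
        i += 1
    return deg


def _pair_stubs(
    out_deg: np.ndarray, in_deg: np.ndarray, rng: np.random.Generator
) -> set[tuple[int, int]] | None:
    """Configuration-model pairing with degree-preserving repair of
    self-loops and duplicates; returns None if repair stalls."""
    out_stubs = np.repeat(np.arange(len(out_deg)), out_deg)
    in_stubs = np.repeat(np.arange(len(in_deg)), in_deg)
    rng.shuffle(in_stubs)
    edges = list(zip(out_stubs.tolist(), in_stubs.tolist()))
    for _ in range(200):
        seen: dict[tuple[int, int], int] = {}
        bad: list[int] = []
        for idx, (u, v) in enumerate(edges):
            if u == v or (u, v) in seen:
                bad.append(idx)
            else:
                seen[(u, v)] = idx
        if not bad:
            return set(edges)
        # swap each bad edge's target with a random partner edge's target
        for idx in bad:
            jdx = int(rng.integers(len(edges)))
            u1, v1 = edges[idx]
            u2, v2 = edges[jdx]
            edges[idx] = (u1, v2)
            edges[jdx] = (u2, v1)
    return None


def sample_scale_free(config: SamplerConfig) -> GeneNetwork:
    """Directed scale-free network with exactly m edges.

    Out-degrees follow P(d) ∝ d^(−α_out) and in-degrees P(d) ∝ d^(−α_in);
    stubs are paired uniformly at random and self-loops/duplicates are
    removed by degree-preserving swaps, resampling the sequences when the
    repair stalls.
    """
    config.validate()
    n, m = config.n, config.m
    rng = np.random.default_rng(config.seed)
    names = _gene_names(n)
    for _ in range(_MAX_RETRIES):
        out_deg = _powerlaw_degree_sequence(n, config.alpha_out, m, rng)
        in_deg = _powerlaw_degree_sequence(n, config.alpha_in, m, rng)
        pairs = _pair_stubs(out_deg, in_deg, rng)
        if pairs is not None and len(pairs) == m:
            return _build([(names[u], names[v]) for u, v in pairs], n)
    raise SamplingError(
        f"could not realize a scale-free graph with n={n}, m={m} "
        f"after {_MAX_RETRIES} attempts"
    )


def sample_semi_scale_free(config: SamplerConfig) -> GeneNetwork:
    """Semi-scale-free network: ⌊n/2⌋ regulator nodes carry all outgoing
    edges with power-law out-degrees; targets are uniform over all nodes."""
    config.validate()
    n, m = config.n, config.m
    n_reg = n // 2
    if m > n_reg * (n - 1):
        raise InvalidConfigError(
            f"m={m} exceeds the {n_reg * (n - 1)} distinct edges available "
            f"from {n_reg} regulators"
        )
    rng = np.random.default_rng(config.seed)
    names = _gene_names(n)
    regulators = rng.choice(n, size=n_reg, replace=False)
    for _ in range(_MAX_RETRIES):
        out_deg = _powerlaw_degree_sequence(
            n_reg, config.alpha_out, m, rng, min_deg=1, max_deg=n - 1
        )
        edges: set[tuple[int, int]] = set()
        ok = True
        for reg_idx, d in zip(regulators, out_deg):
            candidates = np.delete(np.arange(n), reg_idx)
            targets = rng.choice(candidates, size=int(d), replace=False)
            for t in targets:
                edges.add((int(reg_idx), int(t)))
        if len(edges) != m:
            ok = False
        if ok:
            # every regulator must actually regulate (50% rule is exact)
            sources = {u for u, _ in edges}
            if sources == set(int(r) for r in regulators):
                return _build([(names[u], names[v]) for u, v in edges], n)
    raise SamplingError(
        f"could not realize a semi-scale-free graph with n={n}, m={m}"
    )


def sample_small_world(config: SamplerConfig) -> GeneNetwork:
    """Watts–Strogatz small-world skeleton (n·k/2 undirected edges), each
    edge oriented in a uniformly random single direction."""
    import networkx as nx

    config.validate()
    if config.network_class == "SW" and (config.k % 2 or config.k >= config.n):
        raise InvalidConfigError("SW requires even k with k < n")
    rng = np.random.default_rng(config.seed)
    skeleton = nx.watts_strogatz_graph(
        config.n, config.k, config.p, seed=int(rng.integers(2**31))
    )
    names = _gene_names(config.n)
    edges = []
    for u, v in sorted(skeleton.edges()):
        if rng.random() < 0.5:
            u, v = v, u
        edges.append((names[u], names[v]))
    return _build(edges, config.n)


_SAMPLERS = {
    "ER": sample_er,
    "SF": sample_scale_free,
    "SSF": sample_semi_scale_free,
    "SW": sample_small_world,
}


def sample(config: SamplerConfig) -> GeneNetwork:
    """Dispatch to the sampler named by ``config.network_class``."""
    try:
        fn = _SAMPLERS[config.network_class]
    except KeyError:
        raise InvalidConfigError(
            f"no sampler for class {config.network_class!r}"
        ) from None
    return fn(config)
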