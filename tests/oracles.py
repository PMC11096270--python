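"""Independent brute-force reference implementations for the graph metrics.

Everything here is written from the metric definitions directly — hand-rolled
BFS over adjacency dicts, explicit pair enumeration, dense linear algebra for
PageRank — deliberately avoiding the library code paths used by the package,
so these serve as an independent oracle in equivalence tests.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def adjacency(nodes, edges, directed):
    out = {v: set() for v in nodes}
    inc = {v: set() for v in nodes}
    for u, v in edges:
        out[u].add(v)
        inc[v].add(u)
        if not directed:
            out[v].add(u)
            inc[u].add(v)
    return out, inc


def bfs_dist(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def all_dists(nodes, edges, directed):
    adj, _ = adjacency(nodes, edges, directed)
    return {v: bfs_dist(adj, v) for v in nodes}


def aspl(nodes, edges, directed):
    dist = all_dists(nodes, edges, directed)
    vals = [
        dist[v][w]
        for v in nodes
        for w in nodes
        if v != w and w in dist[v]
    ]
    return sum(vals) / len(vals)


def global_efficiency(nodes, edges, directed):
    n = len(nodes)
    if n < 2:
        return 0.0
    dist = all_dists(nodes, edges, directed)
    total = sum(
        1.0 / dist[v][w]
        for v in nodes
        for w in nodes
        if v != w and w in dist[v]
    )
    return total / (n * (n - 1))


def _neighbors(nodes, edges, directed, v):
    nbrs = set()
    for a, b in edges:
        if a == v:
            nbrs.add(b)
        if b == v:
            nbrs.add(a)
    nbrs.discard(v)
    return nbrs


def local_efficiency(nodes, edges, directed):
    acc = 0.0
    for v in nodes:
        nbrs = _neighbors(nodes, edges, directed, v)
        sub_edges = [
            (a, b) for a, b in edges if a in nbrs and b in nbrs
        ]
        acc += global_efficiency(sorted(nbrs), sub_edges, directed)
    return acc / len(nodes)


def degrees(nodes, edges, directed, kind="total"):
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        if kind == "total":
            deg[u] += 1
            deg[v] += 1
        elif kind == "in":
            deg[v] += 1
        elif kind == "out":
            deg[u] += 1
    return deg


def assortativity(nodes, edges, directed):
    if directed:
        deg = degrees(nodes, edges, True, "in")
        xs = [deg[u] for u, _ in edges]
        ys = [deg[v] for _, v in edges]
    else:
        deg = degrees(nodes, edges, False, "total")
        xs, ys = [], []
        for u, v in edges:
            xs += [deg[u], deg[v]]
            ys += [deg[v], deg[u]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (xs.std() * ys.std()))


def centralization(nodes, edges, directed):
    n = len(nodes)
    if directed:
        deg = degrees(nodes, edges, True, "in")
        h_max = (n - 1) ** 2
    else:
        deg = degrees(nodes, edges, False, "total")
        h_max = (n - 1) * (n - 2)
    dmax = max(deg.values())
    return sum(dmax - d for d in deg.values()) / h_max


def clustering(nodes, edges, directed):
    pair_connected = set()
    for u, v in edges:
        pair_connected.add(frozenset((u, v)))
    acc = 0.0
    for v in nodes:
        nbrs = sorted(_neighbors(nodes, edges, directed, v))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a, b in itertools.combinations(nbrs, 2)
            if frozenset((a, b)) in pair_connected
        )
        acc += 2.0 * links / (k * (k - 1))
    return acc / len(nodes)


def degree_centrality(nodes, edges, directed):
    n = len(nodes)
    kind = "out" if directed else "total"
    deg = degrees(nodes, edges, directed, kind)
    return {v: deg[v] / (n - 1) for v in nodes}


def _path_counts(adj, source):
    """(distance, number-of-shortest-paths) from source to every node."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    order = []
    while q:
        u = q.popleft()
        order.append(u)
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def betweenness(nodes, edges, directed):
    n = len(nodes)
    adj, _ = adjacency(nodes, edges, directed)
    dist = {v: None for v in nodes}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _path_counts(adj, s)
    raw = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    raw[v] += sigma[s][v] * sigma[v][t] / dist_sigma(sigma, s, t)
    if directed:
        p_v = (n - 1) * (n - 2)
        return {v: raw[v] / p_v for v in nodes}
    p_v = (n - 1) * (n - 2) / 2
    return {v: raw[v] / 2 / p_v for v in nodes}


def dist_sigma(sigma, s, t):
    return sigma[s][t]


def pagerank(nodes, edges, directed, damping=0.85):
    """Dense linear-system PageRank: p = (1−d)/n + d Mᵀ p with dangling rows
    replaced by 1/n."""
    nodes = sorted(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    out = degrees(nodes, edges, True, "out") if directed else degrees(
        nodes, edges, False, "total"
    )
    es = list(edges)
    if not directed:
        es = es + [(v, u) for u, v in edges]
    for u, v in es:
        M[idx[u], idx[v]] = 1.0 / out[u]
    for v in nodes:
        if out[v] == 0:
            M[idx[v], :] = 1.0 / n
    A = np.eye(n) - damping * M.T
    b = np.full(n, (1 - damping) / n)
    p = np.linalg.solve(A, b)
    p = p / p.sum()
    return dict(zip(nodes, p.tolist()))


def radiality(nodes, edges, directed):
    dist = all_dists(nodes, edges, directed)
    diam = max(
        d for v in nodes for w, d in dist[v].items() if w != v
    )
    vals = {}
    for v in nodes:
        ds = [d for w, d in dist[v].items() if w != v]
        vals[v] = (diam + 1 - sum(ds) / len(ds)) if ds else 0.0
    return vals


def jrand_monte_carlo(n, n0, draws, seed):
    """Sampling oracle for the expected random-predictor Jaccard index."""
    rng = np.random.default_rng(seed)
    truth = set(range(n0))
    vals = np.empty(draws)
    for i in range(draws):
        pick = set(rng.choice(n, size=n0, replace=False).tolist())
        inter = len(truth & pick)
        vals[i] = inter / (2 * n0 - inter)
    return vals


def random_connected_graph(rng, n_max=12, directed=False):
    """Random (weakly) connected graph as (nodes, edges) with string labels."""
    import string

    while True:
        n = int(rng.integers(4, n_max + 1))
        p = rng.uniform(0.25, 0.7)
        nodes = list(string.ascii_lowercase[:n])
        edges = []
        for u, v in itertools.permutations(nodes, 2):
            if not directed and u > v:
                continue
            if rng.random() < p:
                edges.append((u, v))
        if not edges:
            continue
        # connectivity check on the undirected collapse
        adj, _ = adjacency(nodes, [tuple(e) for e in edges], False)
        if len(bfs_dist(adj, nodes[0])) == n:
            return nodes, edges
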