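"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is written from first principles — hand-rolled BFS,
explicit shortest-path counting by layer DP, dense eigendecomposition,
exact combinatorial tail sums — deliberately sharing no code with the
implementation under test.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Plain BFS distances over an adjacency mapping {node: iterable of nodes}."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_to_adj(g) -> dict:
    return {v: sorted(g[v], key=str) for v in g}


def brute_shortest_path_counts(adj: dict, source) -> tuple[dict, dict]:
    """(distances, number of shortest paths) from source, by layer DP."""
    dist = bfs_distances(adj, source)
    sigma = {v: 0 for v in dist}
    sigma[source] = 1
    for v in sorted(dist, key=lambda x: dist[x]):
        if v == source:
            continue
        sigma[v] = sum(sigma[u] for u in adj[v] if u in dist and dist[u] == dist[v] - 1)
    return dist, sigma


def brute_betweenness(g) -> dict:
    """B(v) = sum over unordered pairs {s,t} of sigma_st(v)/sigma_st."""
    adj = graph_to_adj(g)
    nodes = list(g)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = brute_shortest_path_counts(adj, s)
    btw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            total = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    btw[v] += sigma[s][v] * sigma[t][v] / total
    return btw


def brute_closeness(g) -> dict:
    adj = graph_to_adj(g)
    out = {}
    for v in g:
        total = sum(bfs_distances(adj, v).values())
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def brute_eccentricity(g) -> dict:
    adj = graph_to_adj(g)
    out = {}
    for v in g:
        m = max(bfs_distances(adj, v).values())
        out[v] = 1.0 / m if m > 0 else 0.0
    return out


def brute_centroid(g) -> dict:
    """min_w [gamma_v(w) - gamma_w(v)] by direct triple loop (strictly-closer counts)."""
    adj = graph_to_adj(g)
    dist = {v: bfs_distances(adj, v) for v in g}
    out = {}
    for v in g:
        comp = dist[v]
        if len(comp) < 2:
            out[v] = 0
            continue
        best = None
        for w in comp:
            if w == v:
                continue
            gamma_vw = sum(
                1 for u in comp if dist[u][v] < dist[u][w]
            )
            gamma_wv = sum(
                1 for u in comp if dist[u][w] < dist[u][v]
            )
            diff = gamma_vw - gamma_wv
            best = diff if best is None else min(best, diff)
        out[v] = best
    return out


def brute_bridging(g) -> dict:
    btw = brute_betweenness(g)
    deg = {v: len(list(g[v])) for v in g}
    out = {}
    for v in g:
        if deg[v] == 0:
            out[v] = 0.0
            continue
        denom = sum(1.0 / deg[u] for u in g[v])
        out[v] = btw[v] * (1.0 / deg[v]) / denom
    return out


def brute_eigenvector(g) -> dict:
    """Dense eigendecomposition on the largest component (ties: smallest label)."""
    adj = graph_to_adj(g)
    seen: set = set()
    components = []
    for v in sorted(g, key=str):
        if v not in seen:
            comp = set(bfs_distances(adj, v))
            seen |= comp
            components.append(comp)
    # largest component; ties broken by smallest node label
    comp = None
    for c in components:
        if (
            comp is None
            or len(c) > len(comp)
            or (len(c) == len(comp) and min(map(str, c)) < min(map(str, comp)))
        ):
            comp = c
    nodes = sorted(comp, key=str)
    n = len(nodes)
    A = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        for u in adj[v]:
            A[idx[v], idx[u]] = 1.0
    vals, vecs = np.linalg.eigh(A)
    principal = vecs[:, np.argmax(vals)]
    principal = np.abs(principal)
    principal /= np.linalg.norm(principal)
    out = {v: 0.0 for v in g}
    for v in nodes:
        out[v] = float(principal[idx[v]])
    return out


def brute_clustering(g) -> dict:
    out = {}
    for v in g:
        neigh = list(g[v])
        k = len(neigh)
        if k < 2:
            out[v] = 0.0
            continue
        edges = 0
        for i, a in enumerate(neigh):
            for b in neigh[i + 1 :]:
                if b in g[a]:
                    edges += 1
        out[v] = 2.0 * edges / (k * (k - 1))
    return out


def brute_degree(g) -> dict:
    return {v: len(list(g[v])) for v in g}


BRUTE_ORACLES = {
    "degree": brute_degree,
    "betweenness": brute_betweenness,
    "closeness": brute_closeness,
    "eccentricity": brute_eccentricity,
    "centroid": brute_centroid,
    "bridging": brute_bridging,
    "eigenvector": brute_eigenvector,
    "clustering_coefficient": brute_clustering,
}


def exact_hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) by explicit summation of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    total = 0
    for k in range(x, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom


def brute_composite_order(rank_vectors: dict) -> list:
    """Final node order by mean rank, ties by node symbol (string order)."""
    nodes = list(next(iter(rank_vectors.values())).keys())
    mean_rank = {
        v: sum(rv[v] for rv in rank_vectors.values()) / len(rank_vectors)
        for v in nodes
    }
    return sorted(nodes, key=lambda v: (mean_rank[v], str(v)))
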