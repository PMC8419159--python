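"""Seven node-centrality indices plus the local clustering coefficient.

These are the topological importance measures used for hub identification on
protein-protein interaction networks:

* degree — number of interaction partners;
* betweenness — how often a node lies on shortest paths between others
  (unnormalized, unordered pairs counted once);
* closeness — reciprocal of the summed geodesic distances to reachable nodes;
* eccentricity — reciprocal of the longest geodesic from the node;
* centroid value — min over opponents w of (#nodes closer to v) − (#nodes
  closer to w); high values mark cluster-organizing nodes;
* bridging — betweenness × bridging coefficient, high for nodes linking
  densely connected regions;
* eigenvector — principal adjacency eigenvector of the largest connected
  component, high for nodes attached to other well-connected nodes;
* clustering coefficient C_i = 2n / (k_i (k_i − 1)) with n the number of
  edges among the k_i neighbours of i.

All indices treat the graph as simple, undirected and unweighted. Distances
on disconnected graphs are restricted to each node's component; the
eigenvector is computed on the largest component (zero elsewhere) and a
warning is logged whenever the input is disconnected. Ranking, the only
downstream consumer, is invariant to the positive scalings chosen here.
"""

from __future__ import annotations

import logging
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("hubnet")

#: Fixed column order of the per-node centrality table.
CENTRALITY_COLUMNS = [
    "degree",
    "betweenness",
    "closeness",
    "eccentricity",
    "centroid",
    "bridging",
    "eigenvector",
    "clustering_coefficient",
]

#: The seven indices that enter rank aggregation (clustering coefficient is
#: descriptive only).
CENTRALITY_INDICES = CENTRALITY_COLUMNS[:-1]


def clustering_coefficient(net: nx.Graph, v: Hashable) -> float:
    """C_i = 2 * (edges among neighbours of v) / (k_i * (k_i - 1)); 0 if k_i < 2."""
    if v not in net:
        raise KeyError(f"node {v!r} not in network")
    neigh = list(net[v])
    k = len(neigh)
    if k < 2:
        return 0.0
    n_edges = sum(1 for i, a in enumerate(neigh) for b in neigh[i + 1 :] if net.has_edge(a, b))
    return 2.0 * n_edges / (k * (k - 1))


def clustering_coefficients(net: nx.Graph) -> dict:
    return {v: clustering_coefficient(net, v) for v in net}


def degree_centrality(net: nx.Graph) -> dict:
    """Plain degree: deg(v) = |N(v)|."""
    return {v: d for v, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness over unordered node pairs.

    B(v) = sum over pairs {s,t}, s != v != t, of sigma_st(v) / sigma_st, with
    exact shortest-path counting (Brandes accumulation), never sampled.
    """
    return nx.betweenness_centrality(net, normalized=False)


def closeness_centrality(net: nx.Graph) -> dict:
    """Clo(v) = 1 / sum of geodesic distances to nodes reachable from v.

    Isolated nodes (nothing reachable) score 0. On disconnected graphs the
    sum runs over v's component only.
    """
    out = {}
    for v in net:
        dist = nx.single_source_shortest_path_length(net, v)
        total = sum(dist.values())  # d(v,v)=0 contributes nothing
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def eccentricity_centrality(net: nx.Graph) -> dict:
    """Ecc(v) = 1 / max geodesic distance from v to any reachable node; isolated -> 0."""
    out = {}
    for v in net:
        dist = nx.single_source_shortest_path_length(net, v)
        m = max(dist.values())
        out[v] = 1.0 / m if m > 0 else 0.0
    return out


def centroid_value(net: nx.Graph) -> dict:
    """Centroid(v) = min over opponents w of gamma_v(w) - gamma_w(v).

    gamma_v(w) counts the nodes strictly closer to v than to w (equidistant
    nodes count for neither side; v itself counts for v, w for w). Opponents
    range over v's connected component; nodes in singleton components get 0.
    A positive value means v "wins" against every opponent — it organizes its
    cluster; peripheral nodes go negative.
    """
    out = {v: 0 for v in net}
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        idx = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        dist = np.full((n, n), np.inf)
        for v in nodes:
            for w, d in nx.single_source_shortest_path_length(net, v).items():
                dist[idx[v], idx[w]] = d
        # gamma[i, j] = #{u : d(u, i) < d(u, j)}
        gamma = (dist[:, None, :] < dist[None, :, :]).sum(axis=2)
        diff = gamma - gamma.T
        np.fill_diagonal(diff, np.iinfo(np.int64).max)
        for v in nodes:
            out[v] = int(diff[idx[v]].min())
    return out


def bridging_coefficient(net: nx.Graph) -> dict:
    """BC(v) = (1/deg(v)) / sum_{i in N(v)} 1/deg(i); 0 for isolated nodes.

    High values mark nodes of modest degree whose neighbours are highly
    connected — the signature of a bridge between dense regions.
    """
    deg = dict(net.degree())
    out = {}
    for v in net:
        if deg[v] == 0:
            out[v] = 0.0
        else:
            denom = sum(1.0 / deg[u] for u in net[v])
            out[v] = (1.0 / deg[v]) / denom
    return out


def bridging_centrality(net: nx.Graph) -> dict:
    """Br(v) = betweenness(v) * bridging_coefficient(v)."""
    btw = betweenness_centrality(net)
    bc = bridging_coefficient(net)
    return {v: btw[v] * bc[v] for v in net}


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 10000
) -> dict:
    """Principal adjacency eigenvector of the largest connected component.

    Power iteration on A + I (the unit shift makes the iteration matrix
    primitive, so it converges on bipartite components too) from a uniform
    start vector; entirely deterministic. The result is non-negative and
    L2-normalized over the analyzed component; nodes outside it get 0.
    Components tie-break by size then by smallest node label.

    Raises ``RuntimeError`` if the residual has not dropped below ``tol``
    after ``max_iter`` sweeps.
    """
    out = {v: 0.0 for v in net}
    if net.number_of_edges() == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    comp = min(nx.connected_components(net), key=lambda c: (-len(c), min(map(str, c))))
    nodes = sorted(comp)
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = A @ x + x
        y /= np.linalg.norm(y)
        residual = np.linalg.norm(y - x)
        x = y
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > tol {tol:.1e})"
        )
    x = np.abs(x)
    x /= np.linalg.norm(x)
    for v, val in zip(nodes, x):
        out[v] = float(val)
    return out


def compute_all(net: nx.Graph, tol: float = 1e-10, max_iter: int = 10000) -> pd.DataFrame:
    """All seven indices plus the clustering coefficient, one row per node.

    Rows are sorted by node label; columns follow :data:`CENTRALITY_COLUMNS`.
    Deterministic for a fixed input.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        logger.warning(
            "network is disconnected (%d components); distance-based indices "
            "are component-restricted and eigenvector covers the largest component only",
            nx.number_connected_components(net),
        )
    if net.number_of_edges() > 0:
        eig = eigenvector_centrality(net, tol=tol, max_iter=max_iter)
    else:
        eig = {v: 0.0 for v in net}
    columns = {
        "degree": degree_centrality(net),
        "betweenness": betweenness_centrality(net),
        "closeness": closeness_centrality(net),
        "eccentricity": eccentricity_centrality(net),
        "centroid": centroid_value(net),
        "bridging": bridging_centrality(net),
        "eigenvector": eig,
        "clustering_coefficient": clustering_coefficients(net),
    }
    nodes = sorted(net.nodes())
    table = pd.DataFrame(
        {name: [col[v] for v in nodes] for name, col in columns.items()},
        index=pd.Index(nodes, name="node"),
    )
    return table[CENTRALITY_COLUMNS]
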