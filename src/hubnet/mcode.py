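"""Molecular Complex Detection (MCODE): greedy dense-subgraph finding.

The algorithm runs in three stages on a simple undirected graph:

1. **Vertex weighting.** Each node v is scored by the local density of its
   closed neighbourhood N[v]: find the highest k-core of the subgraph induced
   by N[v] and set ``weight(v) = k_max * density(core)``, where density is the
   loop-free 2E/(n(n-1)). Nodes whose degree falls below ``degree_cutoff``
   get weight 0.
2. **Complex prediction.** Seeds are taken in decreasing weight order from
   nodes not yet assigned to a complex; from a seed, neighbours are included
   breadth-first when their weight is at least ``(1 - vwp) * seed_weight``
   (vertex weight percentage), down to ``max_depth`` hops. A node joins at
   most one complex. Single-node results are discarded.
3. **Post-processing.** Candidate complexes whose induced subgraph contains
   no 2-core are discarded; with ``haircut`` the members with exactly one
   intra-complex edge are peeled off iteratively; with ``fluff`` outside
   neighbours whose closed-neighbourhood density exceeds
   ``fluff_density_threshold`` are pulled in (fluffed nodes may be shared
   between complexes).

A complex scores ``density * size`` on its induced subgraph; denser, larger
complexes rank higher. Defaults follow the published algorithm (vwp 0.2,
degree cutoff 2, haircut on, fluff off).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class McodeParams:
    """Tuning knobs of the three MCODE stages (published defaults)."""

    vwp: float = 0.2
    degree_cutoff: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_threshold: float = 0.5
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError(f"vwp must be in [0, 1), got {self.vwp}")
        if self.degree_cutoff < 2:
            raise ValueError(f"degree_cutoff must be >= 2, got {self.degree_cutoff}")
        if not 0.0 <= self.fluff_density_threshold <= 1.0:
            raise ValueError("fluff_density_threshold must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class Complex:
    """A detected molecular complex (node set with density-based score)."""

    members: frozenset
    density: float = 0.0
    score: float = 0.0
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list:
        return sorted(self.members)


def graph_density(g: nx.Graph) -> float:
    """Loop-free density 2E/(n(n-1)); 0 for graphs with fewer than 2 nodes."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _closed_neighbourhood_density(net: nx.Graph, v: Hashable) -> float:
    return graph_density(net.subgraph([v, *net[v]]))


def weight_vertices(net: nx.Graph, params: McodeParams | None = None) -> dict:
    """Stage 1: k-core-based local-density weight for every node."""
    params = params or McodeParams()
    weights: dict = {}
    for v in net:
        if net.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.subgraph([v, *net[v]])
        core_numbers = nx.core_number(closed)
        k_max = max(core_numbers.values())
        core = closed.subgraph([u for u, k in core_numbers.items() if k >= k_max])
        weights[v] = k_max * graph_density(core)
    return weights


def predict_complexes(
    net: nx.Graph,
    weights: Mapping,
    params: McodeParams | None = None,
) -> list[Complex]:
    """Stage 2: greedy seeded expansion into unscored candidate complexes.

    Deterministic regardless of node insertion order: seeds are taken by
    (descending weight, node label) and neighbour expansion visits sorted
    neighbour lists.
    """
    params = params or McodeParams()
    missing = [v for v in net if v not in weights]
    if missing:
        raise ValueError(f"weights missing for nodes {missing[:5]}")
    visited: set = set()
    complexes: list[Complex] = []
    for seed in sorted(net.nodes(), key=lambda v: (-weights[v], str(v))):
        if seed in visited:
            continue
        threshold = (1.0 - params.vwp) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(net[u], key=str):
                    if w in visited:
                        continue
                    if weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        if len(members) > 1:
            complexes.append(Complex(members=frozenset(members)))
    return complexes


def _haircut(sub: nx.Graph) -> nx.Graph:
    """Iteratively strip members with exactly one intra-complex edge."""
    sub = nx.Graph(sub)
    while True:
        singly = [v for v in sub if sub.degree(v) == 1]
        if not singly:
            return sub
        sub.remove_nodes_from(singly)


def postprocess(
    net: nx.Graph,
    complexes: Iterable[Complex],
    params: McodeParams | None = None,
) -> list[Complex]:
    """Stage 3: 2-core filter, optional haircut, optional fluff."""
    params = params or McodeParams()
    out: list[Complex] = []
    for cx in complexes:
        sub = net.subgraph(cx.members)
        if nx.k_core(sub, 2).number_of_nodes() == 0:
            continue
        if params.haircut:
            sub = _haircut(sub)
            if sub.number_of_nodes() == 0:
                continue
        members = set(sub.nodes())
        if params.fluff:
            boundary = {u for v in members for u in net[v] if u not in members}
            for u in sorted(boundary, key=str):
                if _closed_neighbourhood_density(net, u) > params.fluff_density_threshold:
                    members.add(u)
        out.append(Complex(members=frozenset(members)))
    return out


def score_and_rank(net: nx.Graph, complexes: Iterable[Complex]) -> list[Complex]:
    """Score each complex as density * size and rank 1..K by descending score.

    Ties break by larger size, then by the lexicographically smallest sorted
    member tuple, so the output is independent of input order.
    """
    scored = []
    for cx in complexes:
        if not cx.members:
            raise ValueError("cannot score an empty complex")
        sub = net.subgraph(cx.members)
        density = graph_density(sub)
        scored.append(replace(cx, density=density, score=density * len(cx.members)))
    scored.sort(key=lambda c: (-c.score, -c.size, tuple(map(str, c.sorted_members()))))
    return [replace(c, rank=i) for i, c in enumerate(scored, start=1)]


def find_complexes(net: nx.Graph, params: McodeParams | None = None) -> list[Complex]:
    """Run all three MCODE stages and return ranked complexes."""
    params = params or McodeParams()
    weights = weight_vertices(net, params)
    candidates = predict_complexes(net, weights, params)
    return score_and_rank(net, postprocess(net, candidates, params))


def complexes_to_frame(complexes: Iterable[Complex]) -> pd.DataFrame:
    """Tabular view: rank, score, density, size, comma-joined members."""
    rows = [
        {
            "rank": c.rank,
            "score": c.score,
            "density": c.density,
            "size": c.size,
            "members": ",".join(map(str, c.sorted_members())),
        }
        for c in complexes
    ]
    return pd.DataFrame(rows, columns=["rank", "score", "density", "size", "members"])
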