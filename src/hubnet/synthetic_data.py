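"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Two families of generators:

* **Graphs** — a sparse Erdos-Renyi background (Barabasi-Albert optional, for
  PPI-like degree heterogeneity) with planted dense modules: clique-like node
  blocks whose internal edges are resampled at a stated density well above
  the background. These emulate the statistical structure that dense-complex
  detection assumes — protein complexes as locally dense regions in an
  otherwise sparse interaction network.
* **Ct tables** — qPCR plates over control/treated conditions at 6 and 24 h
  with a stable reference gene, per-gene log2 fold shifts applied to the
  treated condition and Gaussian technical noise on every measurement; three
  independent experiments with duplicate technical replicates by default.

Every generator is a pure function of its arguments including the seed, and
the truth objects record the seed alongside the generated data. A small set
of canonical reference graphs (cliques, paths, stars, cycles, a barbell)
carries analytically known centrality values for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import CT_COLUMNS, DEFAULT_REFERENCE_GENE

DEFAULT_TIMEPOINTS = (6.0, 24.0)
DEFAULT_N_EXPERIMENTS = 3
DEFAULT_REPLICATES = 2
#: Default technical noise on a single Ct measurement, in cycles.
DEFAULT_SIGMA = 0.2
BASELINE_CT_RANGE = (18.0, 30.0)


@dataclass
class GraphTruth:
    """A generated network plus the planted structure that produced it."""

    graph: nx.Graph
    modules: list[set]
    background: str
    params: dict
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "background": self.background,
            "params": self.params,
            "seed": self.seed,
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "modules": [sorted(m) for m in self.modules],
        }


@dataclass
class CtTruth:
    """A generated Ct table plus the true fold changes behind it."""

    records: pd.DataFrame
    true_log2_fold: dict
    reference_gene: str
    sigma: float
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "reference_gene": self.reference_gene,
            "sigma": self.sigma,
            "seed": self.seed,
            "true_log2_fold": {
                g: {f"{tp:g}": lf for tp, lf in folds.items()}
                for g, folds in self.true_log2_fold.items()
            },
        }


def _node_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def gen_planted_module_graph(
    n: int,
    p_background: float,
    modules: Sequence[tuple[int, float]] = (),
    seed: int = 0,
    background: str = "erdos_renyi",
    ba_attachment: int = 2,
) -> GraphTruth:
    """Sparse background graph with planted dense modules.

    Module ``(size, density)`` blocks claim disjoint consecutive nodes; their
    internal edges are removed and resampled independently at ``density``
    (density 1.0 plants an exact clique). Densities must exceed the
    background edge probability so the planted structure is denser than
    chance. Reproducible: the same arguments give the same edge set.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not 0.0 <= p_background <= 1.0:
        raise ValueError("p_background must be in [0, 1]")
    sizes = [m[0] for m in modules]
    if sum(sizes) > n:
        raise ValueError(f"module sizes sum to {sum(sizes)} > n = {n}")
    for size, density in modules:
        if size < 2:
            raise ValueError("module size must be >= 2")
        if not (p_background < density <= 1.0):
            raise ValueError(
                f"module density {density} must lie in (p_background={p_background}, 1]"
            )
    rng = np.random.default_rng(seed)
    if background == "erdos_renyi":
        g = nx.gnp_random_graph(n, p_background, seed=rng)
    elif background == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, ba_attachment, seed=rng)
    else:
        raise ValueError(f"unknown background model {background!r}")

    names = _node_names(n)
    module_nodes: list[set] = []
    offset = 0
    for size, density in modules:
        block = list(range(offset, offset + size))
        offset += size
        for i_pos, u in enumerate(block):
            for v in block[i_pos + 1 :]:
                if g.has_edge(u, v):
                    g.remove_edge(u, v)
                if rng.random() < density:
                    g.add_edge(u, v)
        module_nodes.append({names[u] for u in block})
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    for u, v in g.edges():
        g[u][v]["weight"] = 1.0
    return GraphTruth(
        graph=g,
        modules=module_nodes,
        background=background,
        params={
            "n": n,
            "p_background": p_background,
            "modules": [list(m) for m in modules],
            **({"ba_attachment": ba_attachment} if background == "barabasi_albert" else {}),
        },
        seed=seed,
    )


def gen_reference_graphs() -> dict:
    """Canonical small graphs with analytically known centrality values.

    Returns ``{name: (graph, truth)}`` where ``truth`` maps a centrality
    column name to ``{node: exact value}`` for the hand-derivable entries.
    """
    out: dict = {}

    k3 = nx.complete_graph(["A", "B", "C"])
    out["triangle"] = (k3, {
        "clustering_coefficient": {v: 1.0 for v in k3},
        "degree": {v: 2 for v in k3},
        "betweenness": {v: 0.0 for v in k3},
    })

    k4 = nx.complete_graph(["A", "B", "C", "D"])
    out["k4"] = (k4, {
        "eigenvector": {v: 0.5 for v in k4},
        "closeness": {v: 1.0 / 3.0 for v in k4},
        "centroid": {v: 0 for v in k4},
        "eccentricity": {v: 1.0 for v in k4},
    })

    k5 = nx.complete_graph(["A", "B", "C", "D", "E"])
    out["k5"] = (k5, {"degree": {v: 4 for v in k5}})

    p3 = nx.path_graph(["A", "B", "C"])
    out["path3"] = (p3, {
        "betweenness": {"A": 0.0, "B": 1.0, "C": 0.0},
        "closeness": {"A": 1.0 / 3.0, "B": 0.5, "C": 1.0 / 3.0},
        "bridging": {"A": 0.0, "B": 0.25, "C": 0.0},
        "clustering_coefficient": {"B": 0.0},
        "centroid": {"A": -1, "B": 1, "C": -1},
    })

    p5 = nx.path_graph(["A", "B", "C", "D", "E"])
    out["path5"] = (p5, {"eccentricity": {"A": 0.25, "C": 0.5, "E": 0.25}})

    star = nx.star_graph(["hub", "L1", "L2", "L3"])
    out["star4"] = (star, {
        "degree": {"hub": 3, "L1": 1, "L2": 1, "L3": 1},
        "eccentricity": {"hub": 1.0, "L1": 0.5},
        "centroid": {"hub": 2, "L1": -2, "L2": -2, "L3": -2},
        "eigenvector": {"hub": 1.0 / np.sqrt(2.0), "L1": 1.0 / np.sqrt(6.0)},
        "bridging": {"L1": 0.0, "L2": 0.0, "L3": 0.0},
    })

    c4 = nx.cycle_graph(["A", "B", "C", "D"])
    out["cycle4"] = (c4, {"betweenness": {v: 0.5 for v in c4}})

    # two K4s joined by a 3-node path: bridging peaks on the path
    barbell = nx.union(
        nx.complete_graph(["A1", "A2", "A3", "A4"]),
        nx.complete_graph(["B1", "B2", "B3", "B4"]),
    )
    barbell.add_edges_from([("A4", "P1"), ("P1", "P2"), ("P2", "P3"), ("P3", "B1")])
    out["barbell"] = (barbell, {})

    two_comp = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")])
    out["two_component"] = (two_comp, {
        "closeness": {"A": 0.5, "X": 1.0},
        "eccentricity": {"A": 1.0, "X": 1.0},
    })
    return out


def _fold_map(
    true_log2_folds: Mapping, timepoints: Sequence[float], reference_gene: str
) -> dict:
    folds: dict = {}
    for gene, spec in true_log2_folds.items():
        if isinstance(spec, Mapping):
            folds[gene] = {float(tp): float(spec.get(tp, 0.0)) for tp in timepoints}
        else:
            folds[gene] = {float(tp): float(spec) for tp in timepoints}
    ref = folds.setdefault(reference_gene, {float(tp): 0.0 for tp in timepoints})
    if any(v != 0.0 for v in ref.values()):
        raise ValueError(f"reference gene {reference_gene!r} must have log2 fold 0")
    return folds


def gen_ct_table(
    true_log2_folds: Mapping,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    n_experiments: int = DEFAULT_N_EXPERIMENTS,
    replicates: int = DEFAULT_REPLICATES,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> CtTruth:
    """Simulate a qPCR Ct table with known per-gene log2 fold changes.

    ``true_log2_folds`` maps gene symbol to either a scalar log2 fold (applied
    at every timepoint) or a ``{timepoint: log2 fold}`` mapping; the fold is
    the treated-vs-control expression ratio on the log2 scale, so the
    comparative-Ct analysis should recover RQ = 2**fold. The reference gene
    is added automatically with fold 0 (stable across conditions).

    Per gene, a baseline Ct is drawn once uniformly from [18, 30] cycles;
    control measurements scatter around the baseline and treated measurements
    around ``baseline - fold`` (one cycle earlier per doubling), both with
    Gaussian noise ``sigma``. Samples are laid out as ``n_experiments``
    independent experiments per condition and timepoint, each measured in
    ``replicates`` technical replicates.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_experiments < 1 or replicates < 1:
        raise ValueError("n_experiments and replicates must be positive")
    rng = np.random.default_rng(seed)
    folds = _fold_map(true_log2_folds, timepoints, reference_gene)
    genes = list(folds)
    baseline = {g: rng.uniform(*BASELINE_CT_RANGE) for g in genes}

    rows = []
    for tp in timepoints:
        for condition in ("control", "treated"):
            for exp in range(1, n_experiments + 1):
                sample = f"t{tp:g}_{condition}_exp{exp}"
                for gene in genes:
                    shift = folds[gene][float(tp)] if condition == "treated" else 0.0
                    for rep in range(1, replicates + 1):
                        ct = baseline[gene] - shift + rng.normal(0.0, sigma)
                        rows.append(
                            {
                                "sample": sample,
                                "condition": condition,
                                "timepoint": float(tp),
                                "gene": gene,
                                "replicate": rep,
                                "ct": ct,
                            }
                        )
    records = pd.DataFrame(rows, columns=CT_COLUMNS)
    return CtTruth(
        records=records,
        true_log2_fold=folds,
        reference_gene=reference_gene,
        sigma=float(sigma),
        seed=seed,
    )
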