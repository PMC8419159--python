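"""Over-representation analysis of gene lists against gene-set collections.

Given a query list (a cluster, the hub set), a GMT collection and a gene
universe, each set is tested for overlap enrichment with the one-sided
hypergeometric tail P(X >= x), or its conservative EASE variant, which
removes one overlapping gene before taking the tail (the jackknifed score
popularized by DAVID: ``P(X >= x-1)``, identically 1 when x <= 1).
Benjamini-Hochberg q-values are reported alongside the raw p-values;
significance is called on raw p at ``alpha`` by default, mirroring
common practice in the source analyses, with the FDR column available for
stricter readings.

The universe should be the background actually analyzed — for network
stages, the network's node set — not the genome.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_io import GeneSetCollection

logger = logging.getLogger("hubnet")

DEFAULT_ALPHA = 0.05
MIN_SET_SIZE = 2
MAX_SET_FRACTION = 0.5

RESULT_COLUMNS = [
    "set_name",
    "overlap",
    "query_size",
    "set_size",
    "universe_size",
    "p_value",
    "q_value",
    "significant",
    "overlap_genes",
]


def _check_counts(universe: int, set_size: int, query: int, overlap: int) -> None:
    if min(universe, set_size, query, overlap) < 0:
        raise ValueError("counts must be non-negative")
    if set_size > universe or query > universe:
        raise ValueError(
            f"set size ({set_size}) and query size ({query}) must not exceed "
            f"the universe ({universe})"
        )
    if overlap > min(set_size, query):
        raise ValueError(
            f"overlap {overlap} exceeds min(set size {set_size}, query size {query})"
        )


def hypergeom_pvalue(universe: int, set_size: int, query: int, overlap: int) -> float:
    """Upper tail P(X >= overlap) for X ~ Hypergeometric(universe, set, query)."""
    _check_counts(universe, set_size, query, overlap)
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def ease_pvalue(universe: int, set_size: int, query: int, overlap: int) -> float:
    """EASE score: the hypergeometric tail with one overlapping gene removed.

    P(X >= overlap - 1); equals 1 whenever overlap <= 1. Always at least the
    plain hypergeometric p for the same counts.
    """
    _check_counts(universe, set_size, query, overlap)
    return hypergeom_pvalue(universe, set_size, query, max(overlap - 1, 0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving and idempotent."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    method: str = "hypergeom",
    alpha: float = DEFAULT_ALPHA,
    min_set_size: int = MIN_SET_SIZE,
    max_set_fraction: float = MAX_SET_FRACTION,
    keep_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Test every gene set for over-representation in ``query``.

    Query genes outside the universe are dropped with a warning; set members
    outside the universe do not count. Sets smaller than ``min_set_size`` or
    covering more than ``max_set_fraction`` of the universe are skipped.
    Results are BH-adjusted across all tested sets and sorted by ascending
    p-value (set name breaking ties).
    """
    if method not in ("hypergeom", "ease"):
        raise ValueError(f"unknown method {method!r}; expected 'hypergeom' or 'ease'")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_list = list(dict.fromkeys(query))
    outside = [g for g in query_list if g not in universe_set]
    if outside:
        logger.warning(
            "dropping %d query gene(s) outside the universe: %s",
            len(outside), ", ".join(map(str, outside[:10])),
        )
    query_set = set(query_list) & universe_set
    n_universe, n_query = len(universe_set), len(query_set)
    test = hypergeom_pvalue if method == "hypergeom" else ease_pvalue

    rows = []
    for gs in collection:
        members = set(gs.genes) & universe_set
        if len(members) < min_set_size or len(members) > max_set_fraction * n_universe:
            logger.info(
                "skipping gene set %r (effective size %d outside [%d, %.0f])",
                gs.name, len(members), min_set_size, max_set_fraction * n_universe,
            )
            continue
        overlap = sorted(query_set & members)
        if not overlap and not keep_zero_overlap:
            continue
        rows.append(
            {
                "set_name": gs.name,
                "overlap": len(overlap),
                "query_size": n_query,
                "set_size": len(members),
                "universe_size": n_universe,
                "p_value": test(n_universe, len(members), n_query, len(overlap)),
                "overlap_genes": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c not in ("q_value", "significant")])
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
        result["significant"] = result["p_value"] < alpha
        result = result.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result[RESULT_COLUMNS]
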