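"""Composite rank aggregation for hub-gene selection.

Each of the seven centrality indices orders the nodes from best (highest
value) to worst; ties receive the average of the spanned positions. The
composite score of a node is the unweighted arithmetic mean of its seven
per-centrality ranks — no index is given preference — and the final ordering
sorts by ascending composite with lexicographic node-symbol tie-breaking, so
the final ranks are always a permutation of 1..N. Nodes whose final rank is
at or above the cutoff (default 25) are flagged as hubs.

A node's *criteria profile* records the subset of centralities in whose
top-k it appears, rendered as "all", "all except {...}" or the explicit
subset — the grouping used to describe which importance criteria a gene
satisfies.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .centrality import CENTRALITY_INDICES

DEFAULT_CUTOFF = 25


def rank_by_centrality(table: pd.DataFrame, index: str) -> pd.Series:
    """Descending-value ranks (1 = best) for one centrality; ties averaged."""
    if index not in table.columns:
        raise KeyError(
            f"unknown centrality index {index!r}; expected one of {list(table.columns)}"
        )
    return table[index].rank(ascending=False, method="average")


def criteria_label(profile: Mapping[str, bool]) -> str:
    """Render a 7-flag profile as 'all' / 'all except ...' / explicit subset / 'none'."""
    present = [c for c in CENTRALITY_INDICES if profile.get(c, False)]
    absent = [c for c in CENTRALITY_INDICES if not profile.get(c, False)]
    if not absent:
        return "all"
    if not present:
        return "none"
    if len(absent) <= 2:
        return "all except " + " and ".join(absent)
    return ", ".join(present)


def aggregate_ranks(
    ranks: pd.DataFrame,
    cutoff: int = DEFAULT_CUTOFF,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Combine per-centrality ranks into the composite hub ranking.

    Parameters
    ----------
    ranks
        One row per node, one column per centrality index (values are the
        per-centrality ranks, 1 = best). All seven indices must be present.
    cutoff
        Final rank at or below which a node is flagged a hub.
    top_k
        Per-centrality rank bound defining the criteria profile; defaults to
        ``cutoff``.

    Returns a table with the seven rank columns (prefixed ``rank_``), the
    composite score, the final rank, the hub flag and the criteria label,
    sorted by final rank.
    """
    missing = [c for c in CENTRALITY_INDICES if c not in ranks.columns]
    if missing:
        raise ValueError(f"missing per-centrality rank columns: {missing}")
    if ranks.isna().any().any():
        raise ValueError("per-centrality ranks contain missing values")
    if top_k is None:
        top_k = cutoff
    ranks = ranks[CENTRALITY_INDICES]

    composite = ranks.mean(axis=1)
    order = sorted(ranks.index, key=lambda v: (composite[v], str(v)))
    final_rank = pd.Series(range(1, len(order) + 1), index=order, dtype=int)

    out = ranks.rename(columns={c: f"rank_{c}" for c in CENTRALITY_INDICES}).copy()
    out["composite"] = composite
    out["final_rank"] = final_rank
    out["is_hub"] = out["final_rank"] <= cutoff
    profiles = (ranks <= top_k)
    out["criteria_label"] = [
        criteria_label(profiles.loc[v].to_dict()) for v in out.index
    ]
    out = out.sort_values("final_rank")
    out.index.name = "node"
    return out


def rank_nodes(
    centrality_table: pd.DataFrame,
    cutoff: int = DEFAULT_CUTOFF,
    top_k: int | None = None,
    seeds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full ranking stage: per-centrality ranks -> composite -> hubs.

    ``centrality_table`` is the per-node table from
    :func:`hubnet.centrality.compute_all`; only the seven aggregation indices
    are used. If ``seeds`` is given, an ``is_seed`` column annotates nodes
    present in the seed list.
    """
    per_index = pd.DataFrame(
        {c: rank_by_centrality(centrality_table, c) for c in CENTRALITY_INDICES}
    )
    table = aggregate_ranks(per_index, cutoff=cutoff, top_k=top_k)
    if seeds is not None:
        table["is_seed"] = table.index.isin(set(seeds))
    return table


def hubs(rank_table: pd.DataFrame) -> list:
    """Node symbols flagged as hubs, in final-rank order."""
    return list(rank_table.index[rank_table["is_hub"]])
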