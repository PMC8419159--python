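"""Readers and writers for the text formats the pipeline consumes and produces.

Networks are held in :class:`networkx.Graph` objects over gene-symbol node
labels (simple, undirected, loop-free; optional ``weight`` edge attribute kept
for provenance only — every downstream stage is purely topological). Seed
lists, GMT gene-set collections and qPCR Ct tables map onto plain Python
containers and :class:`pandas.DataFrame`.

Two fixtures transcribed from the source study are packaged with the module:
the 34 curated seed genes and the four MCODE cluster memberships, loadable via
:func:`load_seed_fixture` and :func:`load_cluster_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("hubnet")

#: Reference gene used for Ct normalization unless overridden.
DEFAULT_REFERENCE_GENE = "GAPDH"

CT_COLUMNS = ["sample", "condition", "timepoint", "gene", "replicate", "ct"]
CT_CONDITIONS = ("control", "treated")


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for gs in self.sets:
            if gs.name == name:
                return gs
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [gs.name for gs in self.sets]

    def add(self, name: str, description: str, genes: Sequence[str]) -> None:
        if name in self.names:
            raise FormatError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets.append(GeneSet(name, description, list(genes)))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _add_edge(net: nx.Graph, u: str, v: str, weight: float, lineno: int, path) -> None:
    if not u or not v:
        raise FormatError(f"{path}:{lineno}: empty node symbol")
    if weight < 0:
        raise FormatError(f"{path}:{lineno}: negative edge weight {weight}")
    if u == v:
        logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
        net.add_node(u)
        return
    if net.has_edge(u, v):
        # parallel edges collapse, keeping the maximum weight
        net[u][v]["weight"] = max(net[u][v]["weight"], weight)
    else:
        net.add_edge(u, v, weight=weight)


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    normalize_case: bool = False,
) -> nx.Graph:
    """Read an undirected network from a TSV edge list or a SIF file.

    TSV rows are ``source<TAB>target[<TAB>weight]``; a single-field row
    declares an isolated node. SIF rows are ``source relation target...``
    (multi-target rows expand pairwise; the relation string is ignored), a
    lone symbol again declaring an isolated node. ``#`` starts a comment.
    Duplicate edges collapse (max weight wins) and self-loops are dropped
    with a warning. With ``normalize_case`` all symbols are upper-cased.
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'sif'")
    net = nx.Graph()
    n_rows = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            # canonical SIF: tab-delimited if any tab present, else whitespace
            if dialect == "sif":
                fields = line.split("\t") if "\t" in line else line.split()
            else:
                fields = line.split("\t")
            fields = [f.strip() for f in fields]
            if normalize_case:
                fields = [f.upper() for f in fields]
            n_rows += 1
            if dialect == "tsv":
                if len(fields) == 1:
                    net.add_node(fields[0])
                    continue
                if len(fields) > 3:
                    raise FormatError(f"{path}:{lineno}: expected 2-3 columns, got {len(fields)}")
                weight = 1.0
                if len(fields) == 3:
                    try:
                        weight = float(fields[2])
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                        ) from exc
                _add_edge(net, fields[0], fields[1], weight, lineno, path)
            else:
                if len(fields) == 1:
                    net.add_node(fields[0])
                    continue
                if len(fields) == 2:
                    raise FormatError(
                        f"{path}:{lineno}: SIF row needs source, relation and >=1 target"
                    )
                source = fields[0]
                for target in fields[2:]:
                    _add_edge(net, source, target, 1.0, lineno, path)
    if n_rows == 0:
        raise FormatError(f"{path}: no rows (empty file or comments only)")
    return net


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a TSV edge list (isolated nodes as one-field rows).

    Rows are emitted in sorted order so identical networks produce
    byte-identical files.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# source\ttarget\tweight\n")
        for u, v, data in sorted(net.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")
        for node in sorted(nx.isolates(net)):
            fh.write(f"{node}\n")


# ---------------------------------------------------------------------------
# seed lists
# ---------------------------------------------------------------------------

def read_seed_list(path: str | Path, normalize_case: bool = False) -> list[str]:
    """Read a one-symbol-per-line seed-gene list ('#' comments allowed).

    Returns an ordered list, deduplicated keeping first occurrence.
    """
    path = Path(path)
    seeds: list[str] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            symbol = line.upper() if normalize_case else line
            if symbol not in seen:
                seen.add(symbol)
                seeds.append(symbol)
    if not seeds:
        raise FormatError(f"{path}: no gene symbols after comment/blank filtering")
    return seeds


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, normalize_case: bool = False) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...), preserving order."""
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT row needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1].strip()
            genes = [f.strip() for f in fields[2:] if f.strip()]
            if normalize_case:
                genes = [g.upper() for g in genes]
            try:
                collection.add(name, description, genes)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not len(collection):
        raise FormatError(f"{path}: no gene sets")
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(
    path: str | Path,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> pd.DataFrame:
    """Read and validate a qPCR Ct table.

    Expects a CSV with header ``sample,condition,timepoint,gene,replicate,ct``.
    Validation: conditions limited to control/treated; finite numeric Ct;
    (sample, gene, replicate) unique; every (condition, timepoint) block must
    contain the reference gene (pass ``reference_gene=None`` to skip that
    check).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample": str, "condition": str, "gene": str})
    return validate_ct_table(df, reference_gene=reference_gene, source=str(path))


def validate_ct_table(
    df: pd.DataFrame,
    reference_gene: str | None = DEFAULT_REFERENCE_GENE,
    source: str = "<ct table>",
) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    bad_cond = sorted(set(df["condition"]) - set(CT_CONDITIONS))
    if bad_cond:
        raise FormatError(f"{source}: unknown conditions {bad_cond}; expected {CT_CONDITIONS}")
    for col in ("timepoint", "ct"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{source}: non-numeric value in column {col!r}") from exc
    if not df["ct"].map(lambda x: pd.notna(x) and abs(x) != float("inf")).all():
        raise FormatError(f"{source}: Ct values must be finite")
    if (df["timepoint"] < 0).any():
        raise FormatError(f"{source}: negative timepoint")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (df["replicate"] < 1).any():
        raise FormatError(f"{source}: replicate indices must be positive")
    dup = df.duplicated(subset=["sample", "gene", "replicate"], keep=False)
    if dup.any():
        first = df.loc[dup, ["sample", "gene", "replicate"]].iloc[0].tolist()
        raise FormatError(f"{source}: duplicate (sample, gene, replicate) key {first}")
    if reference_gene is not None:
        blocks_missing = []
        for (cond, tp), block in df.groupby(["condition", "timepoint"], sort=True):
            if reference_gene not in set(block["gene"]):
                blocks_missing.append((cond, tp))
        if blocks_missing:
            raise FormatError(
                f"{source}: reference gene {reference_gene!r} absent from "
                f"(condition, timepoint) blocks {blocks_missing}"
            )
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generic result-table output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a result table as TSV with a header row (the pipeline's output format)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("hubnet.fixtures").joinpath(name)


def load_seed_fixture() -> list[str]:
    """The packaged 34-gene curated seed list."""
    with resources.as_file(_fixture_path("table1_seed_genes.txt")) as p:
        return read_seed_list(p)


def load_cluster_fixture() -> GeneSetCollection:
    """The packaged four MCODE cluster memberships (sizes 15, 10, 11, 8)."""
    with resources.as_file(_fixture_path("table3_mcode_clusters.gmt")) as p:
        return read_gmt(p)
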