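"""Readers/writers: format handling, validation and the packaged fixtures."""

import itertools

import networkx as nx
import pandas as pd
import pytest

from hubnet import graph_io
from hubnet.graph_io import (
    FormatError,
    load_cluster_fixture,
    load_seed_fixture,
    read_ct_table,
    read_edge_list,
    read_gmt,
    read_seed_list,
    write_edge_list,
)


class TestEdgeList:
    def test_tsv_basic(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tC\n")
        net = read_edge_list(p)
        assert set(net.nodes()) == {"A", "B", "C"}
        assert {frozenset(e) for e in net.edges()} == {frozenset("AB"), frozenset("BC")}

    def test_undirected_dedup(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\n")
        net = read_edge_list(p)
        assert net.number_of_edges() == 1

    def test_parallel_edges_keep_max_weight(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t0.4\nB\tA\t0.9\n")
        net = read_edge_list(p)
        assert net["A"]["B"]["weight"] == 0.9

    def test_self_loop_dropped_node_kept(self, tmp_path, caplog):
        p = tmp_path / "net.tsv"
        p.write_text("A\tA\nA\tB\n")
        with caplog.at_level("WARNING", logger="hubnet"):
            net = read_edge_list(p)
        assert "self-loop" in caplog.text
        assert net.number_of_edges() == 1 and "A" in net

    def test_sif_multi_target_expands_pairwise(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A pp B C\n")
        net = read_edge_list(p, dialect="sif")
        assert {frozenset(e) for e in net.edges()} == {frozenset("AB"), frozenset("AC")}

    def test_sif_lone_node_and_relation_ignored(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A anything B\nZ\n")
        net = read_edge_list(p, dialect="sif")
        assert net.has_edge("A", "B") and "Z" in net and net.degree("Z") == 0

    @pytest.mark.parametrize(
        "content,fragment",
        [
            ("A\tB\tC\tD\n", ":1"),          # too many columns
            ("A\tB\nA\tB\tx\n", ":2"),       # non-numeric weight, line named
            ("", "no rows"),
            ("# only comments\n", "no rows"),
            ("A\tB\t-1\n", "negative"),
        ],
    )
    def test_malformed_tsv(self, tmp_path, content, fragment):
        p = tmp_path / "net.tsv"
        p.write_text(content)
        with pytest.raises(FormatError, match=fragment):
            read_edge_list(p)

    def test_sif_two_fields_is_error(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A pp\n")
        with pytest.raises(FormatError, match=":1"):
            read_edge_list(p, dialect="sif")

    def test_normalize_case(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("il-6\tStat3\n")
        net = read_edge_list(p, normalize_case=True)
        assert set(net.nodes()) == {"IL-6", "STAT3"}

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip(self, tmp_path, seed):
        g = nx.gnp_random_graph(12, 0.25, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g})
        g.add_node("ISOLATED")
        out = tmp_path / "rt.tsv"
        write_edge_list(g, out)
        back = read_edge_list(out)
        assert set(back.nodes()) == set(g.nodes())
        assert {frozenset(e) for e in back.edges()} == {frozenset(e) for e in g.edges()}

    def test_row_order_insensitive(self, tmp_path):
        rows = ["A\tB", "B\tC", "C\tD", "D\tA"]
        nets = []
        for i, perm in enumerate(itertools.permutations(rows)):
            p = tmp_path / f"p{i}.tsv"
            p.write_text("\n".join(perm) + "\n")
            nets.append(read_edge_list(p))
        first = nets[0]
        for net in nets[1:]:
            assert set(net.nodes()) == set(first.nodes())
            assert set(map(frozenset, net.edges())) == set(map(frozenset, first.edges()))


class TestSeedList:
    def test_dedup_keeps_first(self, tmp_path):
        p = tmp_path / "seeds.txt"
        p.write_text("A\nA\nB\n")
        assert read_seed_list(p) == ["A", "B"]

    def test_comments_only_is_error(self, tmp_path):
        p = tmp_path / "seeds.txt"
        p.write_text("# nothing\n#here\n\n")
        with pytest.raises(FormatError):
            read_seed_list(p)

    def test_inline_comments_stripped(self, tmp_path):
        p = tmp_path / "seeds.txt"
        p.write_text("MMP9  # matrix gene\nVEGFC\n")
        assert read_seed_list(p) == ["MMP9", "VEGFC"]


class TestGmt:
    def test_basic(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tA\tB\n")
        coll = read_gmt(p)
        assert coll["S1"].genes == ["A", "B"]

    def test_duplicate_name_error(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_gmt(p)

    def test_short_row_error_names_line(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tA\nS2\tonly-two-fields\n")
        with pytest.raises(FormatError, match=":2"):
            read_gmt(p)

    def test_preserves_order(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("Z\td\tA\tB\nA\td\tC\tD\n")
        assert read_gmt(p).names == ["Z", "A"]


class TestFixtures:
    def test_seed_fixture_has_34_unique_genes(self):
        seeds = load_seed_fixture()
        assert len(seeds) == 34
        assert len(set(seeds)) == 34

    def test_cluster_fixture_sizes(self):
        coll = load_cluster_fixture()
        assert [len(gs.genes) for gs in coll] == [15, 10, 11, 8]


class TestCtTable:
    def _write(self, tmp_path, df):
        p = tmp_path / "ct.csv"
        df.to_csv(p, index=False)
        return p

    def test_valid_table(self, tmp_path, small_ct_table):
        df = read_ct_table(self._write(tmp_path, small_ct_table))
        assert len(df) == 8
        assert set(df["gene"]) == {"GAPDH", "MMP9"}

    def test_block_without_reference_is_error(self, tmp_path, small_ct_table):
        broken = small_ct_table[
            ~((small_ct_table["gene"] == "GAPDH") & (small_ct_table["condition"] == "treated"))
        ]
        with pytest.raises(FormatError, match="GAPDH"):
            read_ct_table(self._write(tmp_path, broken))

    def test_non_numeric_ct_is_error(self, tmp_path, small_ct_table):
        bad = small_ct_table.copy()
        bad["ct"] = bad["ct"].astype(object)
        bad.loc[0, "ct"] = "oops"
        with pytest.raises(FormatError, match="ct"):
            read_ct_table(self._write(tmp_path, bad))

    def test_duplicate_key_is_error(self, tmp_path, small_ct_table):
        dup = pd.concat([small_ct_table, small_ct_table.iloc[[0]]])
        with pytest.raises(FormatError, match="duplicate"):
            read_ct_table(self._write(tmp_path, dup))

    def test_timepoints_carried_through(self, tmp_path, small_ct_table):
        late = small_ct_table.copy()
        late["timepoint"] = 24.0
        late["sample"] = late["sample"] + "_24"
        both = pd.concat([small_ct_table, late])
        df = read_ct_table(self._write(tmp_path, both))
        assert sorted(set(df["timepoint"])) == [6.0, 24.0]

    def test_unknown_condition_is_error(self, tmp_path, small_ct_table):
        bad = small_ct_table.copy()
        bad.loc[0, "condition"] = "mock"
        with pytest.raises(FormatError, match="mock"):
            read_ct_table(self._write(tmp_path, bad))
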