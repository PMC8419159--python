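import networkx as nx
import numpy as np
import pytest

from hubnet.synthetic_data import gen_reference_graphs


@pytest.fixture(scope="session")
def reference_graphs():
    """Canonical graphs with analytically known centrality values."""
    return gen_reference_graphs()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_graph(n: int, p: float, seed: int, gene_labels: bool = True) -> nx.Graph:
    """Seeded Erdos-Renyi test graph with string labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    if gene_labels:
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})
    return g


@pytest.fixture
def small_ct_table():
    """Minimal valid Ct table: 2 conditions x 2 genes x 2 replicates at one timepoint."""
    import pandas as pd

    rows = []
    for cond, samp in (("control", "c1"), ("treated", "t1")):
        for gene, ct in (("GAPDH", 20.0), ("MMP9", 25.0 if cond == "control" else 26.0)):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample": samp,
                        "condition": cond,
                        "timepoint": 6.0,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows)
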