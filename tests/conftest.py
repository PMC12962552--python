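import pandas as pd
import pytest

from hetens.graphs import Edge, HetGraph, Node
from hetens.synth import DegModel, PlantedConfig, SynthConfig, generate_dataset


def make_graph(node_specs, edge_specs):
    """node_specs: (id, type[, name]); edge_specs: (source, type, target)."""
    nodes = [Node(s[0], s[1], s[2] if len(s) > 2 else s[0]) for s in node_specs]
    edges = [Edge(s, t, et) for s, et, t in edge_specs]
    return HetGraph(nodes, edges)


@pytest.fixture
def chain_graph():
    """a - b - c, single edge type."""
    return make_graph(
        [("a", "Gene"), ("b", "Gene"), ("c", "Gene")],
        [("a", "t", "b"), ("b", "t", "c")],
    )


@pytest.fixture
def k4_graph():
    """Complete graph on {a, b, c, d}, single edge type."""
    ids = ["a", "b", "c", "d"]
    edges = [
        (u, "t", v) for i, u in enumerate(ids) for v in ids[i + 1:]
    ]
    return make_graph([(i, "Gene") for i in ids], edges)


@pytest.fixture
def entries_one(chain_graph):
    return pd.DataFrame({"gene": ["a"], "cluster": ["c0"], "log2fc": [1.0]})


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic recipe for fast end-to-end tests."""
    return SynthConfig(
        seed=11,
        node_type_counts={"Gene": 60, "Disease": 10, "Pathway": 12, "Anatomy": 8},
        deg=DegModel(clusters=("c0", "c1"), n_genes_tested=30, n_true_up=8),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def planted_small_dataset():
    cfg = SynthConfig(
        seed=5,
        node_type_counts={"Gene": 60, "Disease": 10, "Pathway": 12, "Anatomy": 8},
        deg=DegModel(clusters=("c0",), n_genes_tested=30, n_true_up=8),
        planted=PlantedConfig(gene_set_size=5, extra_edges=10),
    )
    return generate_dataset(cfg)
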