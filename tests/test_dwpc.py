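import numpy as np
import pandas as pd
import pytest

from hetens.dwpc import (
    DwpcParams,
    Path,
    compute_pair_scores,
    dwpc_from,
    enumerate_paths,
    path_degree_product,
)
from hetens.errors import ConfigurationError, GraphLookupError
from hetens.graphs import Edge, HetGraph, Node

from _oracles import brute_force_pair_scores, random_het_graph
from conftest import make_graph


def entries_for(genes, cluster="c0", lfc=1.0):
    return pd.DataFrame({"gene": list(genes), "cluster": cluster, "log2fc": lfc})


class TestEnumeratePaths:
    def test_chain_paths(self, chain_graph):
        paths = {p.nodes for p in enumerate_paths(chain_graph, "a", 3)}
        assert paths == {("a", "b"), ("a", "b", "c")}

    def test_k4_path_census(self, k4_graph):
        paths = list(enumerate_paths(k4_graph, "a", 3))
        by_len = {}
        for p in paths:
            by_len[p.length] = by_len.get(p.length, 0) + 1
        assert by_len == {1: 3, 2: 6, 3: 6}
        assert len({(p.nodes, p.edge_types) for p in paths}) == 15  # each exactly once

    def test_isolated_source_yields_nothing(self):
        g = make_graph([("a", "Gene"), ("b", "Gene")], [])
        assert list(enumerate_paths(g, "a", 3)) == []

    def test_unknown_source_raises(self, chain_graph):
        with pytest.raises(GraphLookupError):
            list(enumerate_paths(chain_graph, "nope", 3))

    def test_parallel_edge_types_give_distinct_paths(self):
        g = make_graph(
            [("a", "Gene"), ("b", "Gene")], [("a", "t1", "b"), ("a", "t2", "b")]
        )
        assert len(list(enumerate_paths(g, "a", 1))) == 2

    def test_directed_mode_blocks_reverse_traversal(self):
        g = HetGraph(
            [Node("a", "Gene"), Node("b", "Gene")],
            [Edge("a", "b", "t", directed=True)],
        )
        assert len(list(enumerate_paths(g, "a", 2, directed=True))) == 1
        assert list(enumerate_paths(g, "b", 2, directed=True)) == []
        assert len(list(enumerate_paths(g, "b", 2, directed=False))) == 1


class TestPathDegreeProduct:
    def test_unit_degrees_give_one(self):
        g = make_graph([("g", "Gene"), ("e", "Disease")], [("g", "t", "e")])
        p = Path(("g", "e"), ("t",))
        assert path_degree_product(p, g, DwpcParams(damping=0.7)) == 1.0

    def test_chain_arithmetic(self, chain_graph):
        p = Path(("a", "b", "c"), ("t", "t"))
        got = path_degree_product(p, chain_graph, DwpcParams(damping=0.4))
        assert got == pytest.approx(2 ** -0.8)
        assert got == pytest.approx(0.5743, abs=1e-4)

    def test_zero_damping_gives_one(self, k4_graph):
        p = Path(("a", "b", "c"), ("t", "t"))
        assert path_degree_product(p, k4_graph, DwpcParams(damping=0.0)) == 1.0

    def test_non_simple_path_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            Path(("a", "b", "a"), ("t", "t"))


class TestPairScores:
    def test_chain_unweighted_counts(self, chain_graph):
        out = compute_pair_scores(
            chain_graph, entries_for(["a"]), DwpcParams(damping=0.0)
        )
        scores = dict(zip(out["end"], out["dwpc_pair"]))
        assert scores == {"b": 1.0, "c": 1.0}

    def test_k4_unweighted_pair_count_is_five(self, k4_graph):
        out = compute_pair_scores(k4_graph, entries_for(["a"]), DwpcParams(damping=0.0))
        scores = dict(zip(out["end"], out["dwpc_pair"]))
        assert scores["b"] == 5.0  # 1 direct + 2 two-step + 2 three-step

    def test_zero_damping_scores_are_integer_path_counts(self):
        g = random_het_graph(np.random.default_rng(7), max_nodes=15)
        src = g.node_ids()[0]
        out = dwpc_from(g, src, DwpcParams(damping=0.0))
        assert all(float(v).is_integer() for v in out["dwpc_pair"])

    def test_entry_never_its_own_end(self, k4_graph):
        out = compute_pair_scores(k4_graph, entries_for(["a"]))
        assert "a" not in set(out["end"])

    def test_unmapped_entries_dropped_with_warning(self, chain_graph, caplog):
        with caplog.at_level("WARNING"):
            out = compute_pair_scores(chain_graph, entries_for(["a", "ghost"]))
        assert set(out["entry"]) == {"a"}
        assert "not mapped" in caplog.text

    def test_length_breakdown_sums_to_total(self, k4_graph):
        out = compute_pair_scores(k4_graph, entries_for(["a"]), lengths=True)
        total = out[["len1", "len2", "len3"]].sum(axis=1)
        assert np.allclose(total, out["dwpc_pair"])

    def test_empty_entries_give_empty_frame(self, chain_graph):
        out = compute_pair_scores(chain_graph, entries_for([]))
        assert out.empty and "dwpc_pair" in out.columns

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            DwpcParams(max_len=0)
        with pytest.raises(ConfigurationError):
            DwpcParams(damping=-1)
        with pytest.raises(ConfigurationError):
            DwpcParams(degree_mode="nope")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("damping", [0.0, 0.4])
    @pytest.mark.parametrize("degree_mode", ["per_edge_type", "total"])
    def test_matches_brute_force(self, seed, damping, degree_mode):
        g = random_het_graph(np.random.default_rng(seed), max_nodes=15)
        src = g.node_ids()[int(seed) % g.n_nodes]
        params = DwpcParams(damping=damping, degree_mode=degree_mode)
        got = dict(zip(*(lambda d: (d["end"], d["dwpc_pair"]))(dwpc_from(g, src, params))))
        want = brute_force_pair_scores(g, src, 3, damping, degree_mode)
        assert set(got) == set(want)
        for end in want:
            assert got[end] == pytest.approx(want[end], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_in_undirected_mode(self, seed):
        g = random_het_graph(np.random.default_rng(100 + seed), max_nodes=12)
        params = DwpcParams()
        ids = g.node_ids()[:6]
        for u in ids:
            fwd = dict(zip(*(lambda d: (d["end"], d["dwpc_pair"]))(dwpc_from(g, u, params))))
            for v, s in fwd.items():
                back = dict(
                    zip(*(lambda d: (d["end"], d["dwpc_pair"]))(dwpc_from(g, v, params)))
                )
                assert back[u] == pytest.approx(s, rel=1e-12)

    def test_adding_edge_never_decreases_path_count(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            g = random_het_graph(rng, max_nodes=10)
            ids = g.node_ids()
            u, v = ids[0], ids[1]
            extra = None
            for a in ids:
                for b in ids:
                    if a != b and Edge(a, b, "extra").dedup_key() not in {
                        e.dedup_key() for e in g.edges
                    }:
                        extra = Edge(a, b, "extra")
                        break
                if extra:
                    break
            g2 = HetGraph(g.nodes, [*g.edges, extra])
            params = DwpcParams(damping=0.0)
            before = dict(zip(*(lambda d: (d["end"], d["dwpc_pair"]))(dwpc_from(g, u, params))))
            after = dict(zip(*(lambda d: (d["end"], d["dwpc_pair"]))(dwpc_from(g2, u, params))))
            for end, cnt in before.items():
                assert after.get(end, 0) >= cnt
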