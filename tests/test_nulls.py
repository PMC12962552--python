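import numpy as np
import pandas as pd
import pytest

from hetens.dwpc import DwpcParams
from hetens.errors import ConfigurationError, ConsistencyError
from hetens.nulls import NullEnsemble, build_null, normalize, permute_entries

from conftest import make_graph


def entries_frame(genes_lfc, cluster="c0"):
    return pd.DataFrame(
        {"gene": list(genes_lfc), "cluster": cluster, "log2fc": list(genes_lfc.values())}
    )


@pytest.fixture
def star_graph():
    """Two genes attached to one disease; universe of exactly two genes."""
    return make_graph(
        [("g1", "Gene"), ("g2", "Gene"), ("d", "Disease")],
        [("g1", "assoc", "d"), ("g2", "assoc", "d")],
    )


class TestPermuteEntries:
    def test_preserves_size_and_lfc_multiset(self, small_dataset):
        graph = small_dataset.graph
        entries = entries_frame({f"Gene:{i:04d}": 1.0 + i for i in range(5)})
        rng = np.random.default_rng(0)
        perm = permute_entries(graph, entries, rng)
        assert len(perm) == 5
        assert sorted(perm["log2fc"]) == pytest.approx(sorted(entries["log2fc"]))
        assert set(perm["gene"]) <= set(graph.nodes_of_type("Gene"))

    def test_universe_equal_to_entry_set_forces_full_universe(self, star_graph):
        entries = entries_frame({"g1": 1.0, "g2": 2.0})
        perm = permute_entries(star_graph, entries, np.random.default_rng(1))
        assert set(perm["gene"]) == {"g1", "g2"}

    def test_universe_smaller_than_entries_rejected(self, star_graph):
        entries = entries_frame({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        with pytest.raises(ConfigurationError):
            permute_entries(star_graph, entries, np.random.default_rng(0), universe=["g1"])

    def test_same_seed_same_permutation(self, small_dataset):
        entries = entries_frame({f"Gene:{i:04d}": 1.0 for i in range(4)})
        p1 = permute_entries(small_dataset.graph, entries, np.random.default_rng(42))
        p2 = permute_entries(small_dataset.graph, entries, np.random.default_rng(42))
        pd.testing.assert_frame_equal(p1, p2)


class TestBuildNull:
    def test_single_replicate_deterministic(self, star_graph):
        entries = entries_frame({"g1": 1.0, "g2": 2.0})
        n1 = build_null(star_graph, entries, n_perm=1, seed=9)
        n2 = build_null(star_graph, entries, n_perm=1, seed=9)
        for end in n1.values["c0"]:
            assert np.array_equal(n1.values["c0"][end], n2.values["c0"][end])

    def test_degenerate_universe_gives_zero_variance(self, star_graph):
        # universe == entry set and equal weights: every permutation scores
        # the symmetric end node identically
        entries = entries_frame({"g1": 1.0, "g2": 1.0})
        null = build_null(star_graph, entries, n_perm=20, seed=0)
        arr = null.null_for("c0", "d")
        # identical up to summation-order float noise
        assert arr.std() == pytest.approx(0.0, abs=1e-12) and arr[0] > 0

    def test_extending_n_perm_preserves_prefix(self, small_dataset):
        entries = entries_frame({f"Gene:{i:04d}": 1.0 + i for i in range(4)})
        short = build_null(small_dataset.graph, entries, n_perm=4, seed=3)
        long = build_null(small_dataset.graph, entries, n_perm=8, seed=3)
        ends = set(short.values["c0"]) | set(long.values["c0"])
        for end in ends:
            a = short.null_for("c0", end)
            b = long.null_for("c0", end)[:4]
            assert np.array_equal(a, b)

    def test_n_perm_zero_rejected(self, star_graph):
        with pytest.raises(ConfigurationError):
            build_null(star_graph, entries_frame({"g1": 1.0}), n_perm=0)


class TestNormalize:
    def make_null(self, arr, cluster="c0", end="x"):
        arr = np.asarray(arr, dtype=float)
        return NullEnsemble(
            n_perm=len(arr), seed=0,
            values={cluster: {end: arr}}, end_types={end: "Disease"},
        )

    def observed(self, ens, cluster="c0", end="x"):
        return pd.DataFrame(
            {"cluster": [cluster], "end": [end], "end_type": ["Disease"], "ens": [ens]}
        )

    def test_z_arithmetic(self):
        # null with mean 4 and sd 2 (ddof=1)
        arr = np.array([2.0, 6.0, 2.0, 6.0, 2.0, 6.0])
        arr = (arr - arr.mean()) / arr.std(ddof=1) * 2 + 4
        out = normalize(self.observed(10.0), self.make_null(arr))
        assert out.loc[0, "z"] == pytest.approx(3.0)

    def test_p_emp_extremes(self):
        null500 = np.linspace(0.1, 0.9, 500)
        out = normalize(self.observed(2.0), self.make_null(null500))
        assert out.loc[0, "p_emp"] == pytest.approx(1 / 501)
        tied = np.full(500, 2.0)
        out2 = normalize(self.observed(2.0), self.make_null(tied))
        assert out2.loc[0, "p_emp"] == 1.0

    def test_zero_variance_null_flags_z_missing(self):
        out = normalize(self.observed(5.0), self.make_null(np.full(10, 5.0)))
        assert np.isnan(out.loc[0, "z"]) and out.loc[0, "p_emp"] == 1.0

    def test_end_absent_from_null_gets_zero_background(self):
        null = NullEnsemble(n_perm=10, seed=0, values={"c0": {}}, end_types={})
        out = normalize(self.observed(1.0), null)
        assert out.loc[0, "p_emp"] == pytest.approx(1 / 11)
        assert np.isnan(out.loc[0, "z"])

    def test_cluster_mismatch_raises(self):
        null = self.make_null(np.arange(5.0))
        with pytest.raises(ConsistencyError):
            normalize(self.observed(1.0, cluster="other"), null)

    def test_p_monotone_in_observed_score(self):
        null = self.make_null(np.random.default_rng(0).uniform(size=100))
        ps = [
            normalize(self.observed(v), null).loc[0, "p_emp"]
            for v in np.linspace(0, 1.2, 15)
        ]
        assert all(b <= a for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_p_uniform_across_independent_datasets(self, small_config):
        """Per-end empirical p is uniform when each dataset contributes one
        value (valid calibration check: independent draws across datasets)."""
        from hetens.pipeline import run_scoring
        from hetens.synth import generate_dataset
        from scipy import stats

        ps = []
        for seed in range(30):
            ds = generate_dataset(small_config.with_seed(200 + seed))
            res = run_scoring(
                ds.graph, ds.deg_table, n_perm=20, seed=300 + seed,
                frac=1.0, with_subgraphs=False,
            )
            rec = res.records
            rec = rec[rec["cluster"] == "c0"].sort_values("end")
            if len(rec):
                ps.append(float(rec.iloc[0]["p_emp"]))  # one end per dataset
        assert len(ps) >= 25
        # 20 permutations -> p on {1/21..21/21}; KS against uniform is lenient
        assert stats.kstest(ps, "uniform").pvalue > 0.01
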