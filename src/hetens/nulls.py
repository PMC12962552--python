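"""Permutation null for End Node Scores and score normalization.

The background distribution answers "how large an ENS would this end node
get from a random gene signature of the same size and the same log2fc
weights?".  For each cluster, every permutation resamples the entry-gene
identities uniformly without replacement from the Gene universe, reassigns
the observed multiset of log2fc weights in random order, and reruns the
*entire* scoring pipeline — pair scores, top-fraction filter, weighting,
aggregation.  End nodes that a permutation never reaches (or whose pairs are
filtered out) contribute an ENS of 0 to that replicate.

Observed scores are then normalized two ways:

    z     = (ENS_obs - mean(null)) / sd(null)          (sd with ddof=1)
    p_emp = (1 + #{null >= ENS_obs}) / (1 + n_perm)    (add-one empirical p)

``z`` is reported missing when the null is degenerate (sd = 0).  Replicate
RNG streams are spawned deterministically from (seed, cluster index,
replicate index), so results are reproducible and extending n_perm leaves
earlier replicates unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwpc import DwpcParams, compute_pair_scores
from .ens import filter_top_fraction, weight_and_aggregate
from .errors import ConfigurationError, ConsistencyError
from .graphs import HetGraph

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "cluster", "end", "end_type", "ens_raw", "z", "p_emp", "n_perm", "seed",
)


@dataclass
class NullEnsemble:
    """Per-cluster arrays of null ENS values, one entry per permutation."""

    n_perm: int
    seed: int
    values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    end_types: dict[str, str] = field(default_factory=dict)

    def null_for(self, cluster: str, end: str) -> np.ndarray:
        """Null ENS vector for (cluster, end); zeros if never scored."""
        if cluster not in self.values:
            raise ConsistencyError(f"null ensemble does not cover cluster {cluster!r}")
        arr = self.values[cluster].get(end)
        if arr is None:
            arr = np.zeros(self.n_perm)
        return arr


def permute_entries(
    graph: HetGraph,
    entries: pd.DataFrame,
    rng: np.random.Generator,
    universe: list[str] | None = None,
    gene_type: str = "Gene",
) -> pd.DataFrame:
    """One permutation of a single cluster's entry genes.

    Samples ``len(entries)`` gene ids without replacement from ``universe``
    (default: all Gene-type nodes, sorted) and assigns the observed log2fc
    multiset to them in random order.  Cluster label is preserved.
    """
    clusters = entries["cluster"].unique()
    if len(clusters) != 1:
        raise ConsistencyError("permute_entries expects entries from exactly one cluster")
    if universe is None:
        universe = graph.nodes_of_type(gene_type)
    k = len(entries)
    if len(universe) < k:
        raise ConfigurationError(
            f"gene universe ({len(universe)}) smaller than entry set ({k})"
        )
    genes = rng.choice(np.asarray(universe, dtype=object), size=k, replace=False)
    lfc = rng.permutation(entries["log2fc"].to_numpy())
    return pd.DataFrame(
        {"gene": genes, "cluster": clusters[0], "log2fc": lfc}
    )


def _replicate_rng(seed: int, cluster_index: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cluster_index, replicate))
    return np.random.default_rng(ss)


def build_null(
    graph: HetGraph,
    entries: pd.DataFrame,
    params: DwpcParams = DwpcParams(),
    frac: float = 0.05,
    scope: str = "per_cluster",
    n_perm: int = 500,
    seed: int = 0,
    universe: list[str] | None = None,
    gene_type: str = "Gene",
) -> NullEnsemble:
    """Build the permutation background, per cluster independently.

    Each replicate runs the identical scoring pipeline on a permuted entry
    set.  The default of 500 permutations matches the study setting; scale
    down for quick runs.
    """
    if n_perm < 1:
        raise ConfigurationError(f"n_perm must be >= 1, got {n_perm}")
    null = NullEnsemble(n_perm=n_perm, seed=seed)
    clusters = sorted(entries["cluster"].unique())
    for ci, cl in enumerate(clusters):
        cluster_entries = entries.loc[entries["cluster"] == cl]
        per_end: dict[str, np.ndarray] = {}
        for rep in range(n_perm):
            rng = _replicate_rng(seed, ci, rep)
            perm = permute_entries(graph, cluster_entries, rng, universe, gene_type)
            pairs = compute_pair_scores(graph, perm, params, gene_type=gene_type)
            kept = filter_top_fraction(pairs, frac, scope)
            scores = weight_and_aggregate(kept, perm)
            for end, end_type, val in zip(
                scores["end"], scores["end_type"], scores["ens"]
            ):
                arr = per_end.get(end)
                if arr is None:
                    arr = per_end[end] = np.zeros(n_perm)
                    null.end_types.setdefault(end, end_type)
                arr[rep] = val
        null.values[cl] = per_end
    return null


def normalize(observed: pd.DataFrame, null: NullEnsemble) -> pd.DataFrame:
    """Normalize observed ENS values against the permutation background.

    ``observed`` is the raw ENS table (``cluster/end/end_type/ens``).  Output
    adds ``ens_raw``, ``z`` (NaN when the null has zero variance), ``p_emp``,
    ``n_perm`` and ``seed`` columns, sorted by (cluster, end).
    """
    rows = []
    for r in observed.itertuples(index=False):
        arr = null.null_for(r.cluster, r.end)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if null.n_perm > 1 else 0.0
        z = (r.ens - mean) / sd if sd > 0 else float("nan")
        p_emp = (1 + int((arr >= r.ens).sum())) / (1 + null.n_perm)
        rows.append((r.cluster, r.end, r.end_type, r.ens, z, p_emp, null.n_perm, null.seed))
    out = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return out.sort_values(["cluster", "end"], kind="mergesort").reset_index(drop=True)
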