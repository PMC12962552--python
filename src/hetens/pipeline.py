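"""End-to-end orchestration: DE table -> normalized End Node Scores.

This is the programmatic counterpart of the ``hetens score`` command; the
CLI, the permutation tests and downstream scripts all call
:func:`run_scoring` so observed and null scores are guaranteed to traverse
the identical pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import pandas as pd

from .deg import canonicalize, select_entries
from .dwpc import DwpcParams, compute_pair_scores
from .ens import filter_top_fraction, weight_and_aggregate
from .nulls import NullEnsemble, build_null, normalize
from .subgraphs import ClusterSubgraph, build_subgraph, select_top_ends
from .graphs import HetGraph

logger = logging.getLogger(__name__)

TABLE_FILES = {
    "entries": "entries.tsv",
    "pairs": "pair_scores.tsv",
    "retained": "pair_scores_retained.tsv",
    "ens": "ens.tsv",
    "records": "ens_normalized.tsv",
}


@dataclass
class PipelineResult:
    """All intermediate and final tables of one scoring run."""

    entries: pd.DataFrame
    pairs: pd.DataFrame
    retained: pd.DataFrame
    ens: pd.DataFrame
    null: NullEnsemble
    records: pd.DataFrame
    top_ends: dict[str, list[str]] = field(default_factory=dict)
    subgraphs: dict[str, ClusterSubgraph] = field(default_factory=dict)


def run_scoring(
    graph: HetGraph,
    deg_table: pd.DataFrame,
    *,
    params: DwpcParams = DwpcParams(),
    padj_max: float = 0.05,
    lfc_min: float = 0.0,
    frac: float = 0.05,
    scope: str = "per_cluster",
    n_perm: int = 500,
    seed: int = 0,
    top_k: int = 1,
    per_type: bool = True,
    universe: list[str] | None = None,
    gene_type: str = "Gene",
    with_subgraphs: bool = True,
) -> PipelineResult:
    """Run entry filter, pair scoring, ENS aggregation, permutation null,
    normalization and (optionally) sub-graph extraction."""
    entries = select_entries(canonicalize(deg_table), padj_max=padj_max, lfc_min=lfc_min)
    logger.info("%d entry gene rows across %d cluster(s)",
                len(entries), entries["cluster"].nunique() if len(entries) else 0)
    pairs = compute_pair_scores(graph, entries, params, gene_type=gene_type)
    retained = filter_top_fraction(pairs, frac=frac, scope=scope)
    ens = weight_and_aggregate(retained, entries)
    null = build_null(
        graph, entries, params, frac=frac, scope=scope,
        n_perm=n_perm, seed=seed, universe=universe, gene_type=gene_type,
    )
    records = normalize(ens, null)
    result = PipelineResult(entries, pairs, retained, ens, null, records)
    if with_subgraphs and not records.empty:
        result.top_ends = select_top_ends(records, k=top_k, per_type=per_type)
        for cluster, ends in result.top_ends.items():
            c_entries = entries.loc[entries["cluster"] == cluster]
            c_pairs = retained.loc[retained["cluster"] == cluster]
            zmap = records.loc[records["cluster"] == cluster].set_index("end")["z"]
            result.subgraphs[cluster] = build_subgraph(
                graph, c_entries, ends, c_pairs, params,
                end_scores=zmap.to_dict(),
            )
    return result


def write_result_tables(result: PipelineResult, out_dir: str | FsPath) -> dict[str, str]:
    """Write all pipeline tables as TSV; returns {table name: file path}.

    Rows are pre-sorted by the pipeline stages and floats use repr
    formatting, so identical runs produce byte-identical files.
    """
    out_dir = FsPath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, fname in TABLE_FILES.items():
        path = out_dir / fname
        getattr(result, name).to_csv(path, sep="\t", index=False, na_rep="NA")
        written[name] = str(path)
    return written
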