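"""Cluster sub-graph extraction for visualization.

After normalization, the highest-scoring end nodes of each cluster are
selected (by z, falling back to the empirical p when the null was
degenerate) and connected back to the entry genes through the union of all
retained simple paths within the length bound.  Every node in the resulting
sub-graph therefore lies on at least one supporting entry-to-end path and is
annotated with a role (entry / end / intermediate), its node type, and a
score (log2fc for entries, z or ENS for ends).  The sub-graph can be written
as GraphML, SIF or Cytoscape JSON for interactive exploration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .dwpc import DwpcParams, enumerate_paths
from .errors import ConfigurationError
from .graphs import Edge, HetGraph, write_subgraph

logger = logging.getLogger(__name__)


@dataclass
class ClusterSubgraph:
    """A cluster's visualization sub-graph with per-node annotations."""

    cluster: str
    graph: HetGraph
    roles: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def node_attrs(self) -> dict[str, dict[str, object]]:
        out: dict[str, dict[str, object]] = {}
        for n in self.graph.nodes:
            attrs: dict[str, object] = {
                "role": self.roles.get(n.id, "intermediate"),
                "cluster": self.cluster,
            }
            s = self.scores.get(n.id)
            if s is not None and math.isfinite(s):
                attrs["score"] = float(s)
            out[n.id] = attrs
        return out

    def write(self, path, fmt: str = "graphml") -> None:
        write_subgraph(self.graph, path, fmt, self.node_attrs())


def select_top_ends(
    records: pd.DataFrame, k: int = 1, per_type: bool = True
) -> dict[str, list[str]]:
    """Top-k end nodes per cluster from the normalized ENS table.

    Ranking is by z descending; records with missing z sort after all finite
    z and are ordered by p_emp ascending, then by end id for stability.  With
    ``per_type=True`` (study default, k=1) the top k of *each* end-node type
    are kept.  Groups smaller than k return all their end nodes.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if records.empty:
        return {}
    s = records.assign(_zkey=records["z"].fillna(float("-inf"))).sort_values(
        ["_zkey", "p_emp", "end"], ascending=[False, True, True], kind="mergesort"
    )
    out: dict[str, list[str]] = {}
    group_cols = ["cluster", "end_type"] if per_type else ["cluster"]
    top = s.groupby(group_cols, sort=False).head(k)
    for cl, sub in top.groupby("cluster", sort=True):
        out[cl] = sorted(sub["end"])
    return out


def build_subgraph(
    graph: HetGraph,
    entries: pd.DataFrame,
    ends: list[str],
    pairs: pd.DataFrame,
    params: DwpcParams = DwpcParams(),
    end_scores: dict[str, float] | None = None,
) -> ClusterSubgraph:
    """Union of retained simple paths from a cluster's entries to its ends.

    ``entries`` and ``pairs`` must come from one cluster's pipeline run;
    ``pairs`` is the *retained* pair table, so only (entry, end) pairs that
    survived the top-fraction filter contribute paths.  Selected end nodes
    with no retained pair are dropped with a warning.
    """
    clusters = entries["cluster"].unique()
    cluster = str(clusters[0]) if len(clusters) else ""
    if len(clusters) > 1:
        raise ConfigurationError("build_subgraph expects entries from one cluster")

    end_set = set(ends)
    allowed = {
        (r.entry, r.end)
        for r in pairs.itertuples(index=False)
        if r.end in end_set
    }
    node_ids: set[str] = set()
    edge_keys: set[tuple] = set()
    edge_list: list[Edge] = []
    connected_ends: set[str] = set()
    for gene in sorted(entries["gene"].unique()):
        if not graph.has_node(gene):
            continue
        targets = {e for (g, e) in allowed if g == gene}
        if not targets:
            continue
        for path in enumerate_paths(graph, gene, params.max_len, params.directed):
            if path.end not in targets:
                continue
            connected_ends.add(path.end)
            node_ids.update(path.nodes)
            for u, v, et in zip(path.nodes, path.nodes[1:], path.edge_types):
                a, b = sorted((u, v))
                key = (a, b, et)
                if key not in edge_keys:
                    edge_keys.add(key)
                    edge_list.append(Edge(u, v, et))

    dropped = end_set - connected_ends
    if dropped:
        logger.warning(
            "cluster %s: %d selected end node(s) have no retained supporting path: %s",
            cluster,
            len(dropped),
            sorted(dropped),
        )

    nodes = [graph.node(nid) for nid in sorted(node_ids)]
    sub = HetGraph(nodes, edge_list)
    roles: dict[str, str] = {}
    scores: dict[str, float] = {}
    entry_lfc = dict(zip(entries["gene"], entries["log2fc"]))
    for nid in sorted(node_ids):
        if nid in entry_lfc:
            roles[nid] = "entry"
            scores[nid] = float(entry_lfc[nid])
        elif nid in connected_ends:
            roles[nid] = "end"
            if end_scores and nid in end_scores:
                scores[nid] = float(end_scores[nid])
        else:
            roles[nid] = "intermediate"
    return ClusterSubgraph(cluster=cluster, graph=sub, roles=roles, scores=scores)
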