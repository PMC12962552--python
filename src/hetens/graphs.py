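"""Heterogeneous knowledge-graph data model and standard-format I/O.

A :class:`HetGraph` is a typed multigraph: every node carries a semantic type
(``Gene``, ``Disease``, ...) and a display name, every edge a semantic
relationship label.  Degree tables (total and per edge type) are maintained at
construction time and are the quantities that damp path scores downstream.

Edges are stored with their original orientation but treated as undirected for
degree counting and (by default) traversal; parallel edges of *different*
types between the same node pair are distinct, while exact duplicates of
``(source, edge_type, target)`` are collapsed with a logged warning.
Self-loops are rejected: a simple path can never use one.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, GraphLookupError, ReferentialIntegrityError

logger = logging.getLogger(__name__)

NODE_COLUMNS = ("id", "type", "name")
EDGE_COLUMNS = ("source", "edge_type", "target")
EXPORT_FORMATS = ("graphml", "sif", "cyjs")

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE", ""}


@dataclass(frozen=True)
class Node:
    """A typed graph node with an opaque, case-sensitive identifier."""

    id: str
    node_type: str
    name: str = ""


@dataclass(frozen=True)
class Edge:
    """A typed edge. ``directed`` only constrains traversal when the caller
    opts into direction-respecting path search; degrees always count both
    endpoints."""

    source: str
    target: str
    edge_type: str
    directed: bool = False

    def dedup_key(self) -> tuple:
        if self.directed:
            return (self.source, self.target, self.edge_type, True)
        a, b = sorted((self.source, self.target))
        return (a, b, self.edge_type, False)


class HetGraph:
    """Immutable typed multigraph with per-edge-type degree bookkeeping."""

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Edge]):
        self._nodes: dict[str, Node] = {}
        for n in nodes:
            if not n.node_type:
                raise FormatError(f"node {n.id!r} has an empty node type")
            if n.id in self._nodes:
                raise FormatError(f"duplicate node id {n.id!r}")
            self._nodes[n.id] = n

        self._edges: list[Edge] = []
        seen: set[tuple] = set()
        n_dup = 0
        bad_rows: list[tuple[int, str, str, str]] = []
        for i, e in enumerate(edges):
            if e.source not in self._nodes or e.target not in self._nodes:
                bad_rows.append((i, e.source, e.edge_type, e.target))
                continue
            if e.source == e.target:
                raise FormatError(
                    f"self-loop edge on node {e.source!r} (type {e.edge_type!r}) rejected"
                )
            key = e.dedup_key()
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            self._edges.append(e)
        if bad_rows:
            shown = ", ".join(
                f"row {i}: {s}-[{t}]->{g}" for i, s, t, g in bad_rows[:10]
            )
            raise ReferentialIntegrityError(
                f"{len(bad_rows)} edge(s) reference unknown node ids: {shown}"
            )
        if n_dup:
            logger.warning(
                "dropped %d duplicate (source, edge_type, target) edge(s)", n_dup
            )

        self._deg_by_type: dict[str, Counter] = {nid: Counter() for nid in self._nodes}
        self._deg_total: dict[str, int] = {nid: 0 for nid in self._nodes}
        for e in self._edges:
            for nid in (e.source, e.target):
                self._deg_by_type[nid][e.edge_type] += 1
                self._deg_total[nid] += 1

        self._adj_cache: dict[bool, dict[str, tuple[tuple[str, str], ...]]] = {}
        self._by_type_cache: dict[str, tuple[str, ...]] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes.values())

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphLookupError(f"unknown node id {node_id!r}") from None

    def node_type(self, node_id: str) -> str:
        return self.node(node_id).node_type

    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def nodes_of_type(self, node_type: str) -> list[str]:
        """Sorted ids of all nodes of the given semantic type."""
        if self._by_type_cache is None:
            by_type: dict[str, list[str]] = {}
            for nid, n in self._nodes.items():
                by_type.setdefault(n.node_type, []).append(nid)
            self._by_type_cache = {t: tuple(sorted(v)) for t, v in by_type.items()}
        return list(self._by_type_cache.get(node_type, ()))

    # -- degrees -----------------------------------------------------------

    def degree(self, node_id: str, edge_type: str | None = None) -> int:
        """Incident-edge count of ``node_id``, restricted to ``edge_type``
        when given (``None`` means all types).  Undirected counting."""
        if node_id not in self._nodes:
            raise GraphLookupError(f"unknown node id {node_id!r}")
        if edge_type is None:
            return self._deg_total[node_id]
        return self._deg_by_type[node_id].get(edge_type, 0)

    def recompute_degrees(self) -> tuple[dict[str, Counter], dict[str, int]]:
        """Recompute degree tables directly from the edge list (consistency
        oracle used by validation and tests)."""
        by_type: dict[str, Counter] = {nid: Counter() for nid in self._nodes}
        total: dict[str, int] = {nid: 0 for nid in self._nodes}
        for e in self._edges:
            for nid in (e.source, e.target):
                by_type[nid][e.edge_type] += 1
                total[nid] += 1
        return by_type, total

    def validate(self) -> None:
        """Assert degree-table consistency with the edge list."""
        by_type, total = self.recompute_degrees()
        if by_type != {k: v for k, v in self._deg_by_type.items()} or total != self._deg_total:
            raise FormatError("degree tables inconsistent with edge list")

    # -- traversal support -------------------------------------------------

    def adjacency(self, directed: bool = False) -> dict[str, tuple[tuple[str, str], ...]]:
        """Adjacency map ``node -> ((neighbor, edge_type), ...)``.

        With ``directed=True`` edges flagged directed are traversable only
        source->target; undirected edges remain bidirectional.
        """
        if directed not in self._adj_cache:
            adj: dict[str, list[tuple[str, str]]] = {nid: [] for nid in self._nodes}
            for e in self._edges:
                adj[e.source].append((e.target, e.edge_type))
                if not (directed and e.directed):
                    adj[e.target].append((e.source, e.edge_type))
            self._adj_cache[directed] = {u: tuple(v) for u, v in adj.items()}
        return self._adj_cache[directed]

    # -- conversion --------------------------------------------------------

    def to_networkx(
        self, node_attrs: Mapping[str, Mapping[str, object]] | None = None
    ) -> nx.MultiGraph:
        """Materialize as a ``networkx.MultiGraph`` with node/edge attributes,
        optionally merging extra per-node annotations (role, score, ...)."""
        g = nx.MultiGraph()
        for nid in sorted(self._nodes):
            n = self._nodes[nid]
            attrs = {"node_type": n.node_type, "name": n.name}
            if node_attrs and nid in node_attrs:
                for k, v in node_attrs[nid].items():
                    if v is None or (isinstance(v, float) and v != v):
                        continue  # GraphML has no null; drop missing values
                    attrs[k] = v
            g.add_node(nid, **attrs)
        for e in self._edges:
            g.add_edge(
                e.source,
                e.target,
                key=e.edge_type,
                edge_type=e.edge_type,
                directed=bool(e.directed),
            )
        return g


# -- readers / writers -----------------------------------------------------


def load_graph(node_path: str | FsPath, edge_path: str | FsPath) -> HetGraph:
    """Load a :class:`HetGraph` from node and edge TSV files.

    Node columns: ``id``, ``type``, ``name``; edge columns: ``source``,
    ``edge_type``, ``target`` plus an optional ``directed`` column of {0,1}.
    """
    ndf = pd.read_csv(node_path, sep="\t", dtype=str, keep_default_na=False)
    for col in NODE_COLUMNS:
        if col not in ndf.columns:
            raise FormatError(f"node file {node_path} is missing column {col!r}")
    edf = pd.read_csv(edge_path, sep="\t", dtype=str, keep_default_na=False)
    for col in EDGE_COLUMNS:
        if col not in edf.columns:
            raise FormatError(f"edge file {edge_path} is missing column {col!r}")

    nodes = [Node(r.id, r.type, r.name) for r in ndf.itertuples(index=False)]
    if "directed" in edf.columns:
        flags = []
        for v in edf["directed"]:
            if v in _TRUE:
                flags.append(True)
            elif v in _FALSE:
                flags.append(False)
            else:
                raise FormatError(f"invalid value {v!r} in 'directed' column")
    else:
        flags = [False] * len(edf)
    edges = [
        Edge(s, t, et, d)
        for (s, et, t), d in zip(
            edf[list(EDGE_COLUMNS)].itertuples(index=False), flags
        )
    ]
    return HetGraph(nodes, edges)


def write_graph_tsv(graph: HetGraph, node_path: str | FsPath, edge_path: str | FsPath) -> None:
    """Write node/edge TSVs in the dialect consumed by :func:`load_graph`."""
    pd.DataFrame(
        [(n.id, n.node_type, n.name) for n in graph.nodes],
        columns=list(NODE_COLUMNS),
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        [(e.source, e.edge_type, e.target, int(e.directed)) for e in graph.edges],
        columns=[*EDGE_COLUMNS[:1], "edge_type", "target", "directed"],
    ).to_csv(edge_path, sep="\t", index=False)


def write_subgraph(
    graph: HetGraph,
    path: str | FsPath,
    fmt: str = "graphml",
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Export the graph for Cytoscape as GraphML, SIF or Cytoscape JSON.

    Node types, display names and edge types are preserved as attributes
    (SIF, a pure interaction format, keeps only ids and edge types).
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(
            f"unsupported export format {fmt!r}; expected one of {EXPORT_FORMATS}"
        )
    path = FsPath(path)
    if fmt == "sif":
        lines = [
            f"{e.source}\t{e.edge_type}\t{e.target}" for e in graph.edges
        ]
        lines += [
            n.id for n in graph.nodes if graph.degree(n.id) == 0
        ]  # isolated nodes: bare-id lines per SIF convention
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    g = graph.to_networkx(node_attrs)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    else:  # cyjs
        data = nx.cytoscape_data(g)
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
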