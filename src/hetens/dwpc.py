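"""Degree-weighted path counts (DWPC) over a heterogeneous graph.

For an entry gene *g* and any other node *e*, the pair score is

    DWPCpair(g, e) = sum over simple paths g -> e of length 1..max_len
                     of the path-degree product (PDP),

where the PDP of a path is the product, over every (node, incident path-edge)
incidence, of ``degree(node)**(-w)``.  Equivalently, each edge (u, v) of type
t contributes ``(d_t(u) * d_t(v))**(-w)``; endpoints of the path contribute
one incidence, interior nodes two.  The damping exponent ``w`` (default 0.4,
the usual hetnet convention) penalizes paths through high-degree hubs; ``w=0``
reduces the score to the plain simple-path count.

Degrees are per edge type by default (``degree_mode='per_edge_type'``); a
total-degree mode is available for sensitivity analysis.  Paths are *simple*
(no repeated node) and enumerated by depth-bounded DFS, which is the
reference semantics; per-gene score tables are cached on the (immutable)
graph so permutation replicates reuse them.
"""

from __future__ import annotations

import logging
import math
import weakref
from dataclasses import dataclass
from typing import Iterator

import pandas as pd

from .errors import ConfigurationError, GraphLookupError
from .graphs import HetGraph

logger = logging.getLogger(__name__)

DEGREE_MODES = ("per_edge_type", "total")

PAIR_COLUMNS = ("cluster", "entry", "end", "end_type", "dwpc_pair")


@dataclass(frozen=True)
class DwpcParams:
    """Knobs of the path-scoring stage.

    max_len: maximum number of edges per path (study setting: 3).
    damping: degree exponent w >= 0; 0 disables degree weighting.
    degree_mode: 'per_edge_type' (hetnet convention) or 'total'.
    directed: respect the directed flag of edges during traversal
        (degrees remain undirected incident counts either way).
    """

    max_len: int = 3
    damping: float = 0.4
    degree_mode: str = "per_edge_type"
    directed: bool = False

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ConfigurationError(f"max_len must be >= 1, got {self.max_len}")
        if not math.isfinite(self.damping) or self.damping < 0:
            raise ConfigurationError(f"damping must be finite and >= 0, got {self.damping}")
        if self.degree_mode not in DEGREE_MODES:
            raise ConfigurationError(
                f"degree_mode must be one of {DEGREE_MODES}, got {self.degree_mode!r}"
            )


@dataclass(frozen=True)
class Path:
    """A simple path: k+1 nodes joined by k typed edges."""

    nodes: tuple[str, ...]
    edge_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.edge_types) + 1 or not self.edge_types:
            raise ValueError("path needs k>=1 edges and k+1 nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path is not simple (repeated node)")

    @property
    def length(self) -> int:
        return len(self.edge_types)

    @property
    def end(self) -> str:
        return self.nodes[-1]


def enumerate_paths(
    graph: HetGraph, source: str, max_len: int, directed: bool = False
) -> Iterator[Path]:
    """Yield every simple path of 1..max_len edges starting at ``source``.

    Parallel edges of different types give distinct paths.  Each path is
    yielded exactly once, in depth-first order with neighbors in edge
    insertion order.
    """
    if not graph.has_node(source):
        raise GraphLookupError(f"unknown source node {source!r}")
    if max_len < 1:
        raise ConfigurationError(f"max_len must be >= 1, got {max_len}")
    adj = graph.adjacency(directed)
    node_seq: list[str] = [source]
    type_seq: list[str] = []
    on_path = {source}

    def rec(u: str, depth: int) -> Iterator[Path]:
        for v, et in adj.get(u, ()):
            if v in on_path:
                continue
            node_seq.append(v)
            type_seq.append(et)
            yield Path(tuple(node_seq), tuple(type_seq))
            if depth < max_len:
                on_path.add(v)
                yield from rec(v, depth + 1)
                on_path.remove(v)
            node_seq.pop()
            type_seq.pop()

    yield from rec(source, 1)


def path_degree_product(path: Path, graph: HetGraph, params: DwpcParams) -> float:
    """PDP of one path: product over node-edge incidences of degree**(-w)."""
    w = params.damping
    per_type = params.degree_mode == "per_edge_type"
    prod = 1.0
    for u, v, et in zip(path.nodes, path.nodes[1:], path.edge_types):
        t = et if per_type else None
        prod *= (graph.degree(u, t) * graph.degree(v, t)) ** (-w)
    return prod


# -- cached fast scoring ---------------------------------------------------

# graph -> params -> {"adj": factor adjacency, "scores": {source: DataFrame}}
_CACHE: "weakref.WeakKeyDictionary[HetGraph, dict]" = weakref.WeakKeyDictionary()


def _factor_adjacency(graph: HetGraph, params: DwpcParams) -> dict[str, tuple]:
    """Adjacency with the per-edge PDP factor (d_u * d_v)**(-w) precomputed."""
    w = params.damping
    per_type = params.degree_mode == "per_edge_type"
    out: dict[str, tuple] = {}
    for u, nbrs in graph.adjacency(params.directed).items():
        lst = []
        for v, et in nbrs:
            t = et if per_type else None
            lst.append((v, (graph.degree(u, t) * graph.degree(v, t)) ** (-w)))
        out[u] = tuple(lst)
    return out


def _params_cache(graph: HetGraph, params: DwpcParams) -> dict:
    by_params = _CACHE.setdefault(graph, {})
    entry = by_params.get(params)
    if entry is None:
        entry = by_params[params] = {
            "adj": _factor_adjacency(graph, params),
            "scores": {},
        }
    return entry


def _dwpc_single(adj: dict[str, tuple], source: str, max_len: int) -> dict[str, list[float]]:
    """DFS accumulation of per-end PDP sums, broken down by path length."""
    acc: dict[str, list[float]] = {}

    def rec(u: str, depth: int, prod: float, on_path: set[str]) -> None:
        for v, f in adj.get(u, ()):
            if v in on_path:
                continue
            s = prod * f
            a = acc.get(v)
            if a is None:
                a = acc[v] = [0.0] * max_len
            a[depth - 1] += s
            if depth < max_len:
                on_path.add(v)
                rec(v, depth + 1, s, on_path)
                on_path.remove(v)

    rec(source, 1, 1.0, {source})
    return acc


def dwpc_from(graph: HetGraph, source: str, params: DwpcParams) -> pd.DataFrame:
    """DWPCpair scores from one source node to every reachable end node.

    Returns a frame with columns ``end``, ``end_type``, ``dwpc_pair`` and a
    per-length breakdown ``len1..len<max_len>``, sorted by end id.  Results
    are cached per (graph, params, source).
    """
    if not graph.has_node(source):
        raise GraphLookupError(f"unknown source node {source!r}")
    entry = _params_cache(graph, params)
    df = entry["scores"].get(source)
    if df is None:
        acc = _dwpc_single(entry["adj"], source, params.max_len)
        ends = sorted(acc)
        data = {
            "end": ends,
            "end_type": [graph.node_type(e) for e in ends],
            "dwpc_pair": [sum(acc[e]) for e in ends],
        }
        for k in range(params.max_len):
            data[f"len{k + 1}"] = [acc[e][k] for e in ends]
        df = entry["scores"][source] = pd.DataFrame(data)
    return df


def compute_pair_scores(
    graph: HetGraph,
    entries: pd.DataFrame,
    params: DwpcParams = DwpcParams(),
    lengths: bool = False,
    gene_type: str = "Gene",
) -> pd.DataFrame:
    """DWPCpair table for every (entry gene, reachable end node) pair.

    ``entries`` must carry ``gene`` and ``cluster`` columns (the output of
    :func:`hetens.deg.select_entries`).  Entry genes that do not map to a
    node of ``gene_type`` in the graph are dropped with a logged count.
    Pairs with zero score (unreachable ends) are omitted; an entry gene is
    never its own end node.
    """
    cols = list(PAIR_COLUMNS) + (
        [f"len{k + 1}" for k in range(params.max_len)] if lengths else []
    )
    if entries.empty:
        return pd.DataFrame(columns=cols)

    genes = entries["gene"].unique()
    mapped = {
        g for g in genes if graph.has_node(g) and graph.node_type(g) == gene_type
    }
    n_unmapped = len(genes) - len(mapped)
    if n_unmapped:
        logger.warning(
            "%d entry gene(s) not mapped to %s nodes in the graph; dropped",
            n_unmapped,
            gene_type,
        )

    frames = []
    for row in entries.sort_values(["cluster", "gene"], kind="mergesort").itertuples(index=False):
        if row.gene not in mapped:
            continue
        base = dwpc_from(graph, row.gene, params)
        if base.empty:
            continue
        d = base if lengths else base[["end", "end_type", "dwpc_pair"]]
        d = d.copy()
        d.insert(0, "entry", row.gene)
        d.insert(0, "cluster", row.cluster)
        frames.append(d)
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    return out[cols]
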