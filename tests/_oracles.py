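"""Independent brute-force oracles for path scoring.

These deliberately avoid the package's traversal and degree machinery: they
work from the raw node/edge lists only, enumerate simple paths by naive
recursion, and multiply degree factors counted directly off the edge list.
"""

from collections import Counter

import numpy as np

from hetens.graphs import Edge, HetGraph, Node


def edge_list_degrees(edges):
    """(node, edge_type) -> degree and node -> total degree, from scratch."""
    by_type = Counter()
    total = Counter()
    for e in edges:
        for nid in (e.source, e.target):
            by_type[(nid, e.edge_type)] += 1
            total[nid] += 1
    return by_type, total


def brute_force_pair_scores(graph, source, max_len, damping, degree_mode="per_edge_type"):
    """dict end -> summed path-degree product over all simple paths <= max_len."""
    edges = graph.edges
    by_type, total = edge_list_degrees(edges)
    adj = {}
    for e in edges:
        adj.setdefault(e.source, []).append((e.target, e.edge_type))
        adj.setdefault(e.target, []).append((e.source, e.edge_type))

    def pdp(path_nodes, path_types):
        prod = 1.0
        for u, v, t in zip(path_nodes, path_nodes[1:], path_types):
            if degree_mode == "per_edge_type":
                du, dv = by_type[(u, t)], by_type[(v, t)]
            else:
                du, dv = total[u], total[v]
            prod *= (du * dv) ** (-damping)
        return prod

    scores = {}

    def rec(nodes, types):
        u = nodes[-1]
        for v, t in adj.get(u, ()):
            if v in nodes:
                continue
            new_nodes, new_types = nodes + [v], types + [t]
            scores[v] = scores.get(v, 0.0) + pdp(new_nodes, new_types)
            if len(new_types) < max_len:
                rec(new_nodes, new_types)

    rec([source], [])
    return scores


def brute_force_path_count(graph, source, end, max_len):
    """Exact number of simple paths source -> end with <= max_len edges."""
    scores = brute_force_pair_scores(graph, source, max_len, damping=0.0)
    return round(scores.get(end, 0.0))


def random_het_graph(rng: np.random.Generator, max_nodes: int = 25) -> HetGraph:
    """A small random typed multigraph with mixed edge types (may include
    parallel edges of different types between the same pair)."""
    n = int(rng.integers(5, max_nodes + 1))
    node_types = ["Gene", "Disease", "Pathway"][: int(rng.integers(2, 4))]
    nodes = [
        Node(f"n{i}", node_types[int(rng.integers(len(node_types)))], f"node {i}")
        for i in range(n)
    ]
    edge_types = ["rel_a", "rel_b", "rel_c"][: int(rng.integers(2, 4))]
    m = int(rng.integers(n, 3 * n))
    seen = set()
    edges = []
    for _ in range(m):
        u, v = rng.integers(n, size=2)
        if u == v:
            continue
        et = edge_types[int(rng.integers(len(edge_types)))]
        a, b = sorted((f"n{u}", f"n{v}"))
        if (a, b, et) in seen:
            continue
        seen.add((a, b, et))
        edges.append(Edge(f"n{u}", f"n{v}", et))
    return HetGraph(nodes, edges)
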