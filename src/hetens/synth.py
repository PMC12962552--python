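"""Seedable synthetic heterogeneous knowledge graphs and DE tables.

The generator emulates, at desk scale, the inputs the scoring pipeline
consumes in practice: a typed biomedical graph (Gene, Disease, Anatomy,
Pathway, Symptom, Compound nodes joined by semantic relations with
heavy-tailed degrees) and DESeq2-dialect differential-expression tables with
a signed log2 fold change and an adjusted p-value per gene and cluster.  An
optional *planted* association wires a chosen gene set to one end node with
extra edges, providing ground truth for parameter-recovery tests.

Everything is reproducible from ``(config, seed)``: independent RNG streams
are spawned for the graph, the DE tables and the planted signal, so changing
one stage never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GraphLookupError
from .graphs import Edge, HetGraph, Node

logger = logging.getLogger(__name__)

DEGREE_MODELS = ("configuration_powerlaw", "uniform_random")

PLANT_MODES = ("direct", "bridge", "mixed")

#: edge type used for planted gene -> end associations
PLANTED_DIRECT_TYPE = "PLANTED_ASSOCIATES"
#: edge type used for planted two-hop bridges
PLANTED_BRIDGE_TYPE = "PLANTED_LINKS"

DEFAULT_NODE_TYPE_COUNTS: dict[str, int] = {
    "Gene": 300,
    "Disease": 40,
    "Anatomy": 30,
    "Pathway": 50,
    "Symptom": 30,
    "Compound": 50,
}


@dataclass(frozen=True)
class EdgeTypeSpec:
    """One semantic relation: mean_degree is the expected number of edges of
    this type per *source-type* node."""

    source_type: str
    edge_type: str
    target_type: str
    mean_degree: float


DEFAULT_EDGE_TYPE_SPECS: tuple[EdgeTypeSpec, ...] = (
    EdgeTypeSpec("Gene", "INTERACTS_GiG", "Gene", 3.0),
    EdgeTypeSpec("Gene", "PARTICIPATES_GpP", "Pathway", 2.0),
    EdgeTypeSpec("Gene", "ASSOCIATES_GaD", "Disease", 1.0),
    EdgeTypeSpec("Gene", "EXPRESSED_IN_GeA", "Anatomy", 1.5),
    EdgeTypeSpec("Disease", "PRESENTS_DpS", "Symptom", 2.0),
    EdgeTypeSpec("Disease", "LOCALIZES_DlA", "Anatomy", 1.5),
    EdgeTypeSpec("Compound", "TREATS_CtD", "Disease", 1.0),
    EdgeTypeSpec("Compound", "BINDS_CbG", "Gene", 2.0),
)


@dataclass(frozen=True)
class PlantedConfig:
    """Ground-truth association: extra edges from a random gene set to one
    random end node of ``end_node_type``.

    ``mode='mixed'`` (default) adds one direct gene-end edge per gene while
    genes without one remain, then routes further connections through fresh
    two-hop bridge intermediates — a duplicated direct "associates" fact
    carries no extra information, so saturation beyond one direct edge per
    gene is expressed as indirect links instead.  ``mode='direct'`` forces
    gene-end edges only, using numbered parallel edge types once a gene
    already has one (exact duplicates of (source, type, target) are
    collapsed, parallel edges of different types are distinct);
    ``mode='bridge'`` routes every connection through a bridge."""

    gene_set_size: int = 10
    end_node_type: str = "Disease"
    extra_edges: int = 20
    mode: str = "mixed"


@dataclass(frozen=True)
class DegModel:
    """Shape of the synthetic DE tables, per cluster.

    True upregulated genes draw log2fc from Normal(1.5, 0.5) truncated at 0
    and padj from Uniform(0, 0.05); null genes draw log2fc from
    Normal(0, 0.3) and padj from Uniform(0, 1), so about 2.5% of null genes
    pass the entry filter by chance.
    """

    clusters: tuple[str, ...] = ("cluster0",)
    n_genes_tested: int = 200
    n_true_up: int = 20
    lfc_up_mean: float = 1.5
    lfc_up_sd: float = 0.5
    lfc_null_sd: float = 0.3
    padj_up_max: float = 0.05


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for one synthetic dataset (graph + DE tables)."""

    seed: int = 0
    node_type_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NODE_TYPE_COUNTS)
    )
    edge_type_specs: tuple[EdgeTypeSpec, ...] = DEFAULT_EDGE_TYPE_SPECS
    degree_model: str = "configuration_powerlaw"
    powerlaw_exponent: float = 2.5
    planted: PlantedConfig | None = None
    deg: DegModel = DegModel()

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        """Build a config from a plain mapping (YAML-friendly schema).

        Keys mirror the dataclass fields; ``edge_type_specs`` is a list of
        4-item lists, ``planted`` and ``deg`` nested mappings.
        """
        kwargs: dict = {}
        allowed = {
            "seed", "node_type_counts", "edge_type_specs", "degree_model",
            "powerlaw_exponent", "planted", "deg",
        }
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("seed", "degree_model", "powerlaw_exponent"):
            if key in d:
                kwargs[key] = d[key]
        if "node_type_counts" in d:
            kwargs["node_type_counts"] = dict(d["node_type_counts"])
        if "edge_type_specs" in d:
            kwargs["edge_type_specs"] = tuple(
                EdgeTypeSpec(*spec) for spec in d["edge_type_specs"]
            )
        if d.get("planted") is not None:
            kwargs["planted"] = PlantedConfig(**d["planted"])
        if "deg" in d:
            deg = dict(d["deg"])
            if "clusters" in deg:
                deg["clusters"] = tuple(deg["clusters"])
            kwargs["deg"] = DegModel(**deg)
        return cls(**kwargs)


def _validate(config: SynthConfig) -> None:
    for t, c in config.node_type_counts.items():
        if c < 0:
            raise ConfigurationError(f"negative node count for type {t!r}")
    if config.degree_model not in DEGREE_MODELS:
        raise ConfigurationError(
            f"degree_model must be one of {DEGREE_MODELS}, got {config.degree_model!r}"
        )
    if config.degree_model == "configuration_powerlaw" and config.powerlaw_exponent <= 1:
        raise ConfigurationError("powerlaw_exponent must exceed 1")
    p = config.planted
    if p is not None:
        if p.mode not in PLANT_MODES:
            raise ConfigurationError(f"planted mode must be one of {PLANT_MODES}")
        if p.gene_set_size > config.node_type_counts.get("Gene", 0):
            raise ConfigurationError("planted gene_set_size exceeds Gene count")


def _validate_deg(config: SynthConfig) -> None:
    if config.deg.n_true_up > config.deg.n_genes_tested:
        raise ConfigurationError("n_true_up exceeds n_genes_tested")
    if config.deg.n_genes_tested > config.node_type_counts.get("Gene", 0):
        raise ConfigurationError("n_genes_tested exceeds Gene count")


def node_ids_for_type(config: SynthConfig, node_type: str) -> list[str]:
    """Deterministic node ids (``Type:0007``) for a configured node type."""
    n = config.node_type_counts.get(node_type, 0)
    return [f"{node_type}:{i:04d}" for i in range(n)]


def _type_weights(
    config: SynthConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-type endpoint-sampling weights; a fixed weight vector per type
    makes the same nodes hubs across all their edge types."""
    weights: dict[str, np.ndarray] = {}
    for t in sorted(config.node_type_counts):
        n = config.node_type_counts[t]
        if n == 0:
            weights[t] = np.array([])
            continue
        if config.degree_model == "configuration_powerlaw":
            # expected degrees proportional to rank^(-1/(alpha-1)) yields a
            # degree distribution with tail exponent ~alpha
            ranks = rng.permutation(n) + 1
            w = ranks.astype(float) ** (-1.0 / (config.powerlaw_exponent - 1.0))
        else:
            w = np.ones(n)
        weights[t] = w / w.sum()
    return weights


def _draw_edges(
    rng: np.random.Generator,
    spec: EdgeTypeSpec,
    src_ids: Sequence[str],
    tgt_ids: Sequence[str],
    w_src: np.ndarray,
    w_tgt: np.ndarray,
    m: int,
) -> list[Edge]:
    same = spec.source_type == spec.target_type
    n_s, n_t = len(src_ids), len(tgt_ids)
    max_m = n_s * (n_s - 1) // 2 if same else n_s * n_t
    if m > max_m:
        raise ConfigurationError(
            f"edge spec {spec.edge_type!r}: mean degree {spec.mean_degree} needs "
            f"{m} simple edges but only {max_m} are possible"
        )
    chosen: set[tuple[str, str]] = set()
    edges: list[Edge] = []
    attempts = 0
    while len(edges) < m:
        if attempts > 200:
            raise ConfigurationError(
                f"edge spec {spec.edge_type!r}: could not place {m} distinct edges"
            )
        k = m - len(edges)
        ss = rng.choice(n_s, size=2 * k + 8, p=w_src)
        tt = rng.choice(n_t, size=2 * k + 8, p=w_tgt)
        for si, ti in zip(ss, tt):
            s, t = src_ids[si], tgt_ids[ti]
            if s == t:
                continue
            key = (min(s, t), max(s, t)) if same else (s, t)
            if key in chosen:
                continue
            chosen.add(key)
            edges.append(Edge(s, t, spec.edge_type))
            if len(edges) == m:
                break
        attempts += 1
    return edges


def generate_graph(config: SynthConfig) -> HetGraph:
    """Generate the typed graph (without any planted signal)."""
    _validate(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    nodes = [
        Node(nid, t, f"{t} {i}")
        for t in sorted(config.node_type_counts)
        for i, nid in enumerate(node_ids_for_type(config, t))
    ]
    weights = _type_weights(config, rng)
    edges: list[Edge] = []
    for spec in config.edge_type_specs:
        src_ids = node_ids_for_type(config, spec.source_type)
        tgt_ids = node_ids_for_type(config, spec.target_type)
        if not src_ids or not tgt_ids:
            continue
        same = spec.source_type == spec.target_type
        m = round(spec.mean_degree * len(src_ids) / (2 if same else 1))
        if m <= 0:
            continue
        edges.extend(
            _draw_edges(
                rng, spec, src_ids, tgt_ids,
                weights[spec.source_type], weights[spec.target_type], m,
            )
        )
    return HetGraph(nodes, edges)


def plant_signal(
    graph: HetGraph,
    gene_ids: Iterable[str],
    end_node: str,
    extra_edges: int,
    rng: np.random.Generator,
    mode: str = "mixed",
) -> HetGraph:
    """Return a copy of the graph with ``extra_edges`` planted connections
    from ``gene_ids`` to ``end_node``.

    Each connection is either one direct gene-end edge or a two-hop bridge
    (gene - partner gene - end through a fresh non-planted Gene
    intermediate); both raise the end node's degree by exactly one per
    connection.  Bridging through partner genes keeps the planted
    association uniquely attached to ``end_node`` — an intermediate of the
    end node's own type would itself become a decoy ground truth — and only
    uses relation patterns (gene-gene, gene-concept) that typed biomedical
    schemas contain.  In ``direct`` mode, connections beyond one per gene
    take numbered parallel edge types; ``mixed`` uses direct edges while
    genes without one remain, then bridges.
    """
    if mode not in PLANT_MODES:
        raise ConfigurationError(f"mode must be one of {PLANT_MODES}, got {mode!r}")
    if extra_edges < 0:
        raise ConfigurationError("extra_edges must be >= 0")
    genes = sorted(set(gene_ids))
    for nid in [*genes, end_node]:
        if not graph.has_node(nid):
            raise GraphLookupError(f"unknown node id {nid!r}")
    if extra_edges == 0:
        return graph

    existing = {e.dedup_key() for e in graph.edges}
    new_edges: list[Edge] = []

    def _direct_type(gene: str) -> str:
        # first free parallel planted type for this gene-end pair
        i = 1
        while True:
            et = PLANTED_DIRECT_TYPE if i == 1 else f"{PLANTED_DIRECT_TYPE}_{i}"
            if Edge(gene, end_node, et).dedup_key() not in existing:
                return et
            i += 1

    direct_free = [
        g for g in genes
        if Edge(g, end_node, PLANTED_DIRECT_TYPE).dedup_key() not in existing
    ]
    bridge_pool = sorted(
        nid for nid in graph.nodes_of_type("Gene")
        if nid not in genes and nid != end_node
    )
    used_bridges: set[str] = set()
    for _ in range(extra_edges):
        direct = mode == "direct" or (mode == "mixed" and direct_free)
        if direct:
            if direct_free:
                g = direct_free.pop(int(rng.integers(len(direct_free))))
            else:
                g = genes[int(rng.integers(len(genes)))]
            e = Edge(g, end_node, _direct_type(g))
            existing.add(e.dedup_key())
            new_edges.append(e)
        else:
            if not bridge_pool:
                raise ConfigurationError("no non-planted Gene nodes available for bridges")
            placed = False
            for _try in range(100):
                b = bridge_pool[int(rng.integers(len(bridge_pool)))]
                if b in used_bridges:
                    continue
                g = genes[int(rng.integers(len(genes)))]
                e1 = Edge(g, b, PLANTED_BRIDGE_TYPE)
                e2 = Edge(b, end_node, PLANTED_BRIDGE_TYPE)
                if e1.dedup_key() in existing or e2.dedup_key() in existing:
                    continue
                used_bridges.add(b)
                existing.update({e1.dedup_key(), e2.dedup_key()})
                new_edges.extend([e1, e2])
                placed = True
                break
            if not placed:
                raise ConfigurationError("could not place planted bridge after 100 tries")
    return HetGraph(graph.nodes, [*graph.edges, *new_edges])


def generate_deg_tables(
    config: SynthConfig, planted_gene_ids: Sequence[str] = ()
) -> pd.DataFrame:
    """Synthetic DE tables for all configured clusters, DESeq2 dialect.

    Planted genes are forced into every cluster's true-upregulated set, so
    they always pass the entry filter; remaining tested genes are sampled at
    random from the Gene universe.  Columns: ``gene``, ``cluster``,
    ``log2FoldChange``, ``padj``.
    """
    _validate(config)
    _validate_deg(config)
    universe = node_ids_for_type(config, "Gene")
    planted = sorted(planted_gene_ids)
    missing = set(planted) - set(universe)
    if missing:
        raise ConfigurationError(f"planted genes outside the Gene universe: {sorted(missing)}")
    dm = config.deg
    if len(planted) > dm.n_genes_tested:
        raise ConfigurationError("more planted genes than tested genes")

    frames = []
    for ci, cluster in enumerate(dm.clusters):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, ci))
        )
        others = [g for g in universe if g not in set(planted)]
        extra_tested = rng.choice(
            np.asarray(others, dtype=object),
            size=dm.n_genes_tested - len(planted),
            replace=False,
        ).tolist()
        n_extra_up = max(0, dm.n_true_up - len(planted))
        true_up = set(planted) | set(extra_tested[:n_extra_up])
        tested = sorted([*planted, *extra_tested])
        rows = []
        for gene in tested:
            if gene in true_up:
                lfc = rng.normal(dm.lfc_up_mean, dm.lfc_up_sd)
                while lfc <= 0:  # truncate at zero; redraw boundary draws
                    lfc = rng.normal(dm.lfc_up_mean, dm.lfc_up_sd)
                padj = rng.uniform(0, dm.padj_up_max)
                while not (0 < padj < dm.padj_up_max):
                    padj = rng.uniform(0, dm.padj_up_max)
            else:
                lfc = rng.normal(0.0, dm.lfc_null_sd)
                padj = rng.uniform(0, 1)
            rows.append((gene, cluster, lfc, padj))
        frames.append(
            pd.DataFrame(rows, columns=["gene", "cluster", "log2FoldChange", "padj"])
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SynthDataset:
    """One generated dataset: graph, DE table, and planted ground truth."""

    graph: HetGraph
    deg_table: pd.DataFrame
    planted_genes: tuple[str, ...] = ()
    planted_end: str | None = None


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate graph + DE tables, planting the configured signal if any."""
    graph = generate_graph(config)
    planted_genes: tuple[str, ...] = ()
    planted_end = None
    if config.planted is not None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
        gene_pool = graph.nodes_of_type("Gene")
        planted_genes = tuple(
            sorted(
                rng.choice(
                    np.asarray(gene_pool, dtype=object),
                    size=config.planted.gene_set_size,
                    replace=False,
                ).tolist()
            )
        )
        ends = graph.nodes_of_type(config.planted.end_node_type)
        if not ends:
            raise ConfigurationError(
                f"no nodes of planted end type {config.planted.end_node_type!r}"
            )
        planted_end = ends[int(rng.integers(len(ends)))]
        graph = plant_signal(
            graph, planted_genes, planted_end, config.planted.extra_edges,
            rng, config.planted.mode,
        )
    deg_table = generate_deg_tables(config, planted_genes)
    return SynthDataset(graph, deg_table, planted_genes, planted_end)
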