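# Methods

## Model

`hetens` treats interpretation of a differential-expression signature as a
connectivity problem on a heterogeneous knowledge graph.  The graph is a
typed multigraph: every node has a semantic type (Gene, Disease, Anatomy,
Pathway, Symptom, Compound, ...) and every edge a semantic relation label.
Parallel edges of different types between the same pair are distinct
relations; exact duplicates of `(source, edge_type, target)` are collapsed
at load with a warning, and self-loops are rejected (a simple path can never
use one).  Node identifiers are opaque, case-sensitive strings; no
normalization is attempted.

### Path scoring

The connectivity of entry gene *g* to end node *e* is the degree-weighted
path count: the sum over all simple paths of 1..`max_len` edges of a
path-degree product, where each node-edge incidence contributes
`degree^(-w)`.  Equivalently each edge `(u, v)` of type `t` contributes
`(d_t(u) * d_t(v))^(-w)`: endpoints of the path appear in one incidence,
interior nodes in two.  Degrees are restricted to the incident edge's type
by default (`degree_mode="per_edge_type"`), so a node that is a hub in one
relation but not another is damped only where it is a hub; a total-degree
mode exists for sensitivity analysis.  Walks revisiting a node are excluded.

Reference semantics are depth-bounded DFS enumeration; the production
implementation is the same DFS with the per-edge factor precomputed and the
running product carried down the stack, and per-gene score tables are cached
on the (immutable) graph so permutation replicates never recompute a gene's
paths.  Equivalence with a naive enumerator that multiplies degree factors
read directly off the edge list is asserted to 1e-10 over random graphs in
the test suite.

### Aggregation

Pair scores are filtered to the top `ceil(frac * n)` per end-node type
(default `frac = 0.05`), then weighted by the entry gene's log2 fold change
and summed per end node into the End Node Score.  The ceil rule means a
nonempty group always retains at least one pair; ties at the cutoff break by
lexicographic `(entry, end)` order so results are reproducible.  Because the
original description filters "per node type" but scores "per cluster", the
filter scope is configurable: `per_cluster` (default — each cluster's table
filtered independently, matching the per-cluster visualization of results)
or `pooled` across clusters.

### Permutation null and normalization

The background asks how large an ENS a random signature of the same size
and weight profile would produce.  "Permuting the differentially expressed
genes" is read as resampling gene *identities* uniformly without
replacement from the Gene universe (all Gene-type nodes, or a configured
tested-gene list) and reassigning the observed log2fc multiset in random
order, per cluster independently — the reading that yields a usable
per-end-node background when clusters share genes.  Label shuffling across
clusters is a possible alternative reading and is not implemented.  Every
replicate reruns the identical pipeline, including the top-fraction filter;
end nodes a replicate never reaches contribute 0.  The default is 500
permutations (the study setting); desk-scale checks use 100.

Because no closed normalization formula is fixed by the description, two
complementary normalizations are reported: a z-score against the null mean
and standard deviation (ddof = 1; flagged missing when the null is
degenerate), and an add-one empirical p-value
`(1 + #{null >= obs}) / (1 + n_perm)`, which is always in (0, 1] and counts
ties conservatively.  Ranking uses z where defined, else p.

Replicate RNG streams come from `SeedSequence(seed, spawn_key=(cluster_index,
replicate))`, so runs are byte-reproducible and increasing `n_perm` extends
the ensemble without changing earlier replicates.

### Sub-graph extraction

For display, the top-k end nodes (default k = 1 per end-node type, matching
the habit of showing the best concept of each kind) are joined to the entry
genes by the union of all retained supporting paths within the length
bound — rather than the induced subgraph on selected nodes — so every
included node lies on at least one entry-to-end path and every inclusion has
a provenance.  Nodes are annotated with role (entry / end / intermediate),
cluster, and a score (log2fc for entries, z for ends); exports are GraphML,
SIF or Cytoscape JSON.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_len` | 3 | path length bound, in edges |
| `damping` (w) | 0.4 | degree exponent; 0 reduces scores to simple-path counts |
| `degree_mode` | `per_edge_type` | degree used in the damping factor |
| `padj_max`, `lfc_min` | 0.05, 0.0 | entry filter, strict inequalities |
| `frac` | 0.05 | top fraction of pairs kept per end-node type |
| `scope` | `per_cluster` | filter grouping |
| `n_perm` | 500 | permutation replicates |
| `top_k`, `per_type` | 1, true | end-node selection for sub-graphs |

The damping exponent is not fixed by the method description; 0.4 is the
established hetnet convention and is exposed as a flag.  Edge direction is
ignored during traversal by default (semantic relations are traversed both
ways, maximizing reachability of "any node"); a direction-respecting mode
exists but degrees always count both endpoints.

## Synthetic data

The generator emulates the *shape* of the real inputs at desk scale: 500
typed nodes (Gene 300, Disease 40, Anatomy 30, Pathway 50, Symptom 30,
Compound 50), eight semantic relations with per-relation mean degrees
between 1 and 3 (gene-gene interaction, gene-pathway, gene-disease,
gene-anatomy, disease-symptom, disease-anatomy, compound-disease,
compound-gene), and heavy-tailed degrees from a rank-weight configuration
model (endpoint sampling weights `rank^(-1/(alpha-1))`, default alpha = 2.5,
with one weight vector per node type so the same nodes are hubs across all
their relations).  DE tables follow the DESeq2 dialect: true upregulated
genes draw log2fc from Normal(1.5, 0.5) truncated at zero and padj from
Uniform(0, 0.05); null genes draw log2fc from Normal(0, 0.3) and padj from
Uniform(0, 1), so ~2.5% of null genes pass the entry filter by chance.
All draws derive from independent spawned streams of one seed.

The planted signal adds `extra_edges` connections (default 20) from a
random gene set (default 10) to one random end node of a chosen type
(default Disease).  The default `mixed` mode adds one direct gene-end edge
per gene and routes the remainder through fresh two-hop bridges via
non-planted partner genes.  Two points of this design matter:

- duplicated direct "associates" facts carry no information (exact duplicate
  edges collapse), so saturation beyond one direct edge per gene is
  expressed as indirect links;
- bridge intermediates are partner *genes*, never nodes of the end node's
  own type: an intermediate of the target's type would receive direct
  planted edges from the signature and become a decoy ground truth, and
  gene-gene / gene-concept steps are the only relation patterns such typed
  schemas actually contain.

What the generator does **not** emulate: real SPOKE-scale size (tens of
millions of nodes), its edge-type vocabulary, correlated expression between
interacting genes, count-level DE statistics (padj is drawn, not computed),
or batch structure.  Passing tests therefore demonstrate the correctness
and calibration machinery of the scoring pipeline, not biological validity
on any real graph.

## Numerical and degenerate-input choices

- Entry-filter comparisons are strict; missing padj never passes; duplicate
  (cluster, gene) rows keep the larger log2fc with a warning.
- Entry genes absent from the graph's Gene nodes are dropped at scoring
  time with a logged count.
- An entry gene is never its own end node; other entry genes may be ends.
- Zero-variance nulls flag z as missing (`NA` in TSV output); p_emp is
  still computed.
- Pipeline tables are emitted in fixed sort orders with repr float
  formatting, so identical inputs and seed give byte-identical outputs.
- Scaled-down problem sizes used by the checked-in checks: 100-permutation
  nulls, 25 recovery replicates, 500-node graphs — chosen so the whole
  suite completes in a couple of minutes on one CPU while leaving every
  pipeline stage exercised at its defaults.

## Known limitations

- **Within-run dependence of empirical p-values.**  All end nodes share one
  observed gene draw and one permutation set, so their p-values are
  strongly positively dependent: the whole p-vector shifts with the overall
  connectivity of the observed signature, and the top-fraction filter
  additionally restricts reporting to end nodes that survived filtering in
  the observed run.  Per-end p-values are individually valid (the observed
  signature is exchangeable with its permutations), but the collection of
  p-values from a single run is not a sample of independent uniforms — a
  fraction-significant or uniformity test applied to one run's p-values
  will generally reject even under the null.  Calibration should be judged
  across independent datasets (as done in the null-model tests); no
  multiple-testing correction across end nodes is attempted.
- Enumeration is exact and exponential in `max_len`; the intended regime is
  path length <= 3 on graphs up to tens of thousands of edges.  No
  matrix-based approximation is provided.
- The permutation universe is gene identity only; weights are reassigned,
  never resampled, so the null conditions on the observed effect-size
  profile.
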