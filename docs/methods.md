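# Methods

This note documents the model implemented by `netfingerprint`, the
numerical and design choices behind it, what the synthetic fixtures do and
do not emulate, and the package's known limitations.

## The similarity model

A fingerprint coordinate is the standardized similarity between a query
network G₁ and one reference network G₂, both undirected gene graphs with
string gene identifiers. The computation:

**Merging.** G_m = (V₁ ∪ V₂, E₁ ∪ E₂) with name-based node
identification: a node present in both inputs becomes a single *shared*
node inheriting every interaction; duplicate edges collapse. Each merged
node carries a provenance label (`only_G1`, `only_G2`, `shared`). Node
order is sorted lexicographically, which fixes matrix indexing and makes
the pipeline invariant to input edge order.

**Semantic weighting.** `semantic_matrix` gives the full symmetric matrix
S_m of Resnik gene similarities over the merged node order. Resnik term
similarity is the information content (IC) of the most informative common
ancestor; IC is −ln of a term's annotation frequency in the
ancestor-closed corpus, computed from the loaded annotation file itself
(self-contained; no external frequency tables). Gene-level similarity
lifts term similarity over the two genes' term sets, by plain maximum
(default) or bidirectional best-match average (`combine="bma"`) — both are
provided because either convention is defensible; the maximum is the more
permissive and is the default. Unannotated genes score 0 against
everything (including themselves) rather than being dropped, so node sets
stay aligned with the topology; occurrences are logged.

**Clustering input: weighted adjacency, not the full matrix.** Affinity
propagation (AP) clusters the merged nodes on the *adjacency-masked*
semantic matrix — S_m(i,j) where (i,j) ∈ E_m, zero elsewhere. This is a
deliberate design decision, and the one place where two superficially
plausible designs differ sharply. Clustering the full semantic matrix
would make every downstream quantity (clusters, provenance, cluster
scores) independent of the edge sets entirely: degree-preserving
rewiring could then never change the score, the null distribution would
be a point mass, and standardization would degenerate. Masking by
adjacency makes the clusters functional-topological modules of the merged
network, which is exactly the structure the rewiring null is meant to
randomize. `SimilarityParams(cluster_on="full")` retains the unmasked
behaviour for comparison.

**Cluster scoring.** Scoring, by contrast, must use the full semantic
matrix: a G₁-only node and a G₂-only node are never adjacent in E₁ ∪ E₂
(neither input network contains both endpoints), so an adjacency-masked
cluster score would be identically zero. Each cluster k is scored by the
bidirectional best-match average LS_k between its G₁-only and G₂-only
members (see README for the formula); the global raw score is the
arithmetic mean of LS_k over all clusters. Shared nodes are excluded from
both sides by default — they are trivially "similar to themselves" and
would inflate the score; `shared_on_both_sides=True` includes them on
both sides instead. A cluster with an empty side contributes LS = 0 and
stays in the mean, penalizing clusters without cross-network
correspondence (`skip_one_sided=True` drops them instead).

**Standardization.** The raw score is z-scored against a null built by
Maslov–Sneppen rewiring: `swaps_per_edge × |E|` double-edge swap
*attempts* (default 10 per edge, the conventional mixing heuristic), each
accepted only if it creates no self-loop or duplicate, conserving every
node's degree and the node set exactly. Both query and reference are
rewired each draw by default (`rewire_mode` accepts `query`/`ref`/`both`;
which side the original formulation randomized is not documented, and
rewiring both removes topological bias from either side). Because node
labels never change, the semantic matrix is computed once per
query–reference pair and reused across all permutations; only the
adjacency mask, clustering and scoring are recomputed. The default number
of randomized networks is `nperm = 100`, balancing the precision of the
null moments against the fact that standardization dominates the total
runtime (each reference costs nperm + 1 cluster-and-score passes). The
null sd uses the n−1 (sample) estimator. A degenerate null (sd = 0)
standardizes to 0 when the observed score equals the null mean and to a
signed-infinity sentinel otherwise (serialized as `inf`/`-inf` in
exported tables).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `combine` | `max` | gene-level lift of Resnik term similarity (`max` or `bma`) |
| `preference` | `median_nonzero` | AP preference; `median` = median off-diagonal similarity, `median_nonzero` restricts to nonzero entries (the masked matrix is mostly zeros, whose median would force mass non-convergence) |
| `damping` | 0.9 | AP message damping in [0.5, 1) |
| `max_iter` / `conv_iter` | 1000 / 50 | AP iteration budget / stability window |
| `cluster_on` | `adjacency` | clustering input: adjacency-masked or full semantic matrix |
| `nperm` | 100 | randomized networks per reference |
| `swaps_per_edge` | 10 | Maslov–Sneppen swap attempts per edge |
| `rewire_mode` | `both` | which side(s) the null rewires |
| namespace | `biological_process` | GO namespace used for similarity (the namespace where Resnik pairwise similarity performs best in benchmark studies); switchable |

IC uses natural logarithms throughout. `part_of` edges count as ancestry
by default (common GO practice; toggleable). All GAF evidence codes are
accepted by default, with an optional exclusion list (e.g. `{"IEA"}`).

## Numerical choices and degenerate inputs

- AP ties are controlled: node order is sorted before matrix
  construction, cluster ids are relabelled by exemplar order, and the
  sklearn backend receives a seed-derived `random_state` for its internal
  tie-breaking jitter, so the whole pipeline is bitwise-reproducible at a
  fixed seed.
- If AP does not converge, the assignment falls back to one cluster per
  connected component of the nonzero-similarity graph (`converged=False`,
  warning logged) — deterministic and topology-aware.
- A similarity matrix whose off-diagonal entries are all equal and no
  larger than the preference carries no evidence to merge anything; every
  node becomes its own exemplar (n singleton clusters).
- Merging a network with itself makes every node shared, so every cluster
  has empty one-sided node sets and the raw score is exactly 0.
- Networks with fewer than two edges cannot be rewired and are returned
  unchanged (with a warning), which can produce degenerate nulls — handled
  by the sd = 0 sentinel above.
- Seeds are managed with `numpy` seed sequences: one master seed spawns
  per-reference streams, each of which spawns per-permutation streams, so
  results are reproducible and changing `nperm` does not perturb earlier
  draws.

## What the synthetic fixtures emulate

`synthfix` generates every input the pipeline reads. Random toy
ontologies (`make_toy_ontology`) are single-root DAGs with multi-parent
attachment for exercising the ontology machinery; structured scenario
ontologies (`make_branching_ontology`) have disjoint branches of
sub-branch chains so that cross-branch gene pairs have zero similarity
and within-sub-branch pairs share a deep, high-IC ancestor.
`make_network_pair` plants the statistical structure the method assumes
about related networks: a shared node fraction and module-aligned
annotation (connected subgraphs whose genes draw terms from the same
sub-branch). The bundled scenario (`make_refset_scenario`) uses networks
of 16 nodes, a 30% planted overlap, four modules per network, and one
related plus three unrelated references — sizes chosen so the full
pipeline at nperm = 100 runs in seconds per reference on one CPU while
the planted signal remains recoverable.

What the fixtures do **not** emulate: scale-free or otherwise realistic
degree distributions, the size and redundancy of the real Gene Ontology,
annotation noise and evidence-code heterogeneity, identifier ambiguity,
or the hub structure of curated pathway databases. Passing tests
demonstrate that the algorithmic machinery is correct and that planted
functional overlap is recovered under controlled conditions — not that
any particular biological conclusion follows on real KEGG/GO data, where
scores additionally depend on corpus composition and annotation depth.

## Known limitations

- Node identity is exact string match; no symbol/Entrez mapping layer.
- Input networks are treated as undirected and unweighted; KGML relation
  direction is discarded, and multi-gene KGML entries are expanded to
  cliques by convention (`expand_entry_cliques=False` disables the
  within-entry edges).
- Lin and Jiang–Conrath similarities are not implemented; Resnik is the
  similarity whose pairwise form performs best in published benchmarks
  and is the one the score definitions here assume.
- Standardization is Monte-Carlo: coordinates vary slightly across seeds
  (by design); consumers should compare fingerprints computed with the
  same `nperm` and treat small z differences as noise.
- The live KEGG download helpers (`fetch_kegg_pathway`,
  `build_kegg_refnet`) require network access and are provided as
  untested conveniences; the supported ingestion path is file-based.
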