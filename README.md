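# netfingerprint

Network Fingerprint analysis of biological networks in Python.

Biological networks — protein–protein interaction maps, signalling
pathways, disease gene networks — are hard to compare directly: they live
in different "shapes" and sizes, and purely topological measures ignore
what the genes actually do. The Network Fingerprint approach characterizes
a query network the way a spectrum characterizes a compound: it measures
the similarity of the query against an ordered panel of well-studied
reference ("basic") networks, such as KEGG pathways, and represents the
query as the resulting vector of standardized scores. Networks can then be
compared, classified and interpreted in that common coordinate system.

Given references P = (P₁, …, Pₙ), a query G becomes

    S = (s₁, …, sₙ),   sᵢ = sim(G, Pᵢ)

where each coordinate is computed in three stages:

1. **Merge** — G and Pᵢ are pooled into the union network
   G_m = (V₁ ∪ V₂, E₁ ∪ E₂); nodes with the same gene identifier collapse
   into a single shared node that inherits all interactions.
2. **Similarity scoring** — node pairs of G_m are weighted by Resnik
   semantic similarity over the Gene Ontology (information content of the
   most informative common ancestor, lifted to genes by max or best-match
   average). Affinity-propagation clustering on the semantically weighted
   adjacency groups the merged nodes into functional-topological modules,
   and each cluster k is scored by the bidirectional best-match average
   between its G-only and Pᵢ-only members:

       LS_k = [ Σ_{i∈V¹ₖ} max_{j∈V²ₖ} S_m(i,j) + Σ_{j∈V²ₖ} max_{i∈V¹ₖ} S_m(i,j) ]
              / ( n(V¹ₖ) + n(V²ₖ) )

   The raw similarity is the mean of LS_k over all clusters.
3. **Standardization** — the raw score is z-scored against a null of
   degree-preserving (Maslov–Sneppen) rewirings of both networks
   (100 randomized networks by default), removing the part of the score
   explained by degree structure alone.

The package ships readers for the standard formats (OBO ontologies, GAF
annotations, edge lists, GraphML, KGML pathway XML, manifest-based
reference sets) and a synthetic-fixture module that generates toy
ontologies, annotations and network pairs with planted, ledgered
structure, so the whole pipeline runs and is tested fully offline.

## Worked example

```python
from netfingerprint import calc_fingerprint, top_fraction
from netfingerprint.synthfix import make_refset_scenario

bundle = make_refset_scenario(seed=1)          # 1 query + 4 references
fp = calc_fingerprint(bundle.query, bundle.refset, bundle.background,
                      nperm=100, seed=1)
print(fp.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"))
```

prints

```
     group    name    raw  null_mean  null_sd  standardized  n_clusters
   planted related 0.4569     0.1994   0.1864        1.3817          10
background  unrel1 0.0000     0.0000   0.0000        0.0000          17
background  unrel2 0.0000     0.0000   0.0000        0.0000          17
background  unrel3 0.0000     0.0000   0.0000        0.0000          19
```

The scenario plants one reference (`related`) that shares ~30% of its
nodes and its annotation branch with the query; the three `unrel*`
references are node-disjoint and annotated to unrelated ontology
branches. The planted reference's raw similarity (0.457) clearly exceeds
its rewired-null mean (0.199), giving a standardized coordinate of
z ≈ 1.38 — the top of the fingerprint (`top_fraction(fp, 0.25)` returns
exactly this entry). The unrelated references show no cross-network
correspondence at all: raw and null scores are identically zero, so their
coordinates are 0. Because standardization is stochastic, different seeds
shift the z values slightly while the ranking of the planted reference
stays stable.

The scripts in `examples/` walk through each capability: semantic
similarity (`01`), merging and cluster scoring (`02`), full fingerprints
(`03`) and fingerprint comparison (`04`).

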