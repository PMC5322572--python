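"""Information content and Resnik similarity on a toy ontology.

Builds a small random GO-style DAG with leaf-biased gene annotations,
computes per-term information content from the annotation corpus itself,
and prints term- and gene-level Resnik similarities.
"""

from netfingerprint import SemanticBackground, resnik_term_sim
from netfingerprint.synthfix import make_annotations, make_toy_ontology

dag, _ = make_toy_ontology(n_terms=40, seed=1)
genes = [f"gene{i:02d}" for i in range(20)]
ann, _ = make_annotations(dag, genes, terms_per_gene=3, seed=1)
bg = SemanticBackground.from_tables(dag, ann)

print(f"ontology: {len(dag.term_ids)} terms, root {dag.root}")
print(f"corpus: {bg.ic.corpus_size} annotated genes")
print(f"IC(root) = {bg.ic[dag.root]:.3f}  (always 0: every gene reaches the root)")

deep = max(bg.ic.ic, key=bg.ic.get)
print(f"most informative annotated term: {deep} with IC {bg.ic[deep]:.3f}")
print(f"Resnik(t, t) recovers its own IC: {resnik_term_sim(bg.ic, dag, deep, deep):.3f}")

# gene-level similarity: max over term pairs (default) vs best-match average
a, b = genes[0], genes[1]
print(f"\ngene_sim({a}, {b}, max) = {bg.gene_sim(a, b, 'max'):.3f}")
print(f"gene_sim({a}, {b}, bma) = {bg.gene_sim(a, b, 'bma'):.3f}")
print("higher values mean the two genes share a more specific (higher-IC) ancestor")
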