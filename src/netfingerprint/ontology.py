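"""Gene Ontology handling: DAG parsing, annotation tables, information
content and Resnik semantic similarity.

The similarity machinery here follows the classical information-content
(IC) family: the IC of a term is ``-ln`` of the probability that a gene in
the annotation corpus is annotated (directly or through an ancestor) to
that term, and the Resnik similarity of two terms is the IC of their most
informative common ancestor (MICA).  Gene-level similarity lifts term
similarity over the two genes' term sets, either by a plain maximum or by
the bidirectional best-match average (BMA).

The corpus used for term probabilities is the loaded annotation table
itself after ancestor closure, so the package is self-contained: no
external gene-frequency tables are required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx
import obonet

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

CombineMode = Literal["max", "bma"]


@dataclass
class OntologyDAG:
    """One namespace of an ontology as a rooted DAG with child->parent edges.

    ``parents`` maps every term to its (possibly empty) set of parents via
    ``is_a`` and, optionally, ``part_of``.  Exactly one term (the root) has
    no parents, and the graph is acyclic.
    """

    namespace: str
    parents: dict[str, frozenset[str]]
    root: str
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology parent graph contains a cycle")
        roots = [t for t, ps in self.parents.items() if not ps]
        if roots != [self.root] and set(roots) != {self.root}:
            raise ValueError(
                f"expected unique root {self.root!r}, found parentless terms {sorted(roots)}"
            )

    @property
    def term_ids(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def canonical(self, term: str) -> str:
        """Map an alt_id to its canonical id (identity for canonical ids)."""
        return self.alt_ids.get(term, term)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including ``term`` itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """All descendants of ``term`` including ``term`` itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        children: dict[str, list[str]] = {t: [] for t in self.parents}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].append(child)
        out: set[str] = {term}
        stack = children[term][:]
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(children[t])
        return frozenset(out)

    def depth(self, term: str) -> int:
        """Shortest parent-path distance from ``term`` up to the root."""
        if term == self.root:
            return 0
        g = self.to_networkx()
        return nx.shortest_path_length(g, term, self.root)


@dataclass
class AnnotationTable:
    """gene -> set of ontology terms; ``closed`` marks ancestor closure."""

    gene_terms: dict[str, frozenset[str]]
    closed: bool = False

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_terms)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())


@dataclass
class ICTable:
    """Per-term information content in natural-log units.

    ``ic[t] = -ln(n_t / n_root)`` where ``n_t`` counts genes whose closed
    annotation set contains ``t``.  Terms never reached by any gene are
    absent.  ``ic[root] = 0`` by construction.
    """

    ic: dict[str, float]
    corpus_size: int

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def get(self, term: str, default: float = 0.0) -> float:
        return self.ic.get(term, default)


def load_obo(
    path,
    namespace: str = "biological_process",
    include_part_of: bool = True,
) -> OntologyDAG:
    """Read an OBO 1.2/1.4 file and return one namespace as an :class:`OntologyDAG`.

    Obsolete terms are dropped (the underlying reader skips them) and
    ``alt_id`` entries are recorded so annotations to superseded ids can be
    mapped to the canonical term.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}; expected one of {NAMESPACES}")
    graph = obonet.read_obo(path, ignore_obsolete=True)
    keep_rel = {"is_a"} | ({"part_of"} if include_part_of else set())

    terms = {t for t, d in graph.nodes(data=True) if d.get("namespace") == namespace}
    if not terms:
        raise ValueError(f"namespace {namespace!r} absent from {path}")

    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, rel in graph.edges(keys=True):
        if rel in keep_rel and child in terms and parent in terms:
            parents[child].add(parent)

    alt_ids: dict[str, str] = {}
    for t in terms:
        for alt in graph.nodes[t].get("alt_id", []):
            alt_ids[alt] = t

    dag = OntologyDAG(
        namespace=namespace,
        parents={t: frozenset(ps) for t, ps in parents.items()},
        root=_find_root(parents),
        alt_ids=alt_ids,
    )
    return dag


def _find_root(parents: Mapping[str, set[str] | frozenset[str]]) -> str:
    roots = sorted(t for t, ps in parents.items() if not ps)
    if len(roots) != 1:
        raise ValueError(f"expected a single root term, found {roots}")
    return roots[0]


#: GAF 2.x column indices (0-based): DB object id, qualifier, term, evidence, aspect
_GAF_ID, _GAF_QUALIFIER, _GAF_TERM, _GAF_EVIDENCE, _GAF_ASPECT = 1, 3, 4, 6, 8
_GAF_MIN_COLUMNS = 15

_ASPECT_OF_NAMESPACE = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


def load_gaf(
    path,
    dag: OntologyDAG,
    exclude_evidence: Iterable[str] = (),
) -> AnnotationTable:
    """Read a GAF 2.x annotation file against ``dag``.

    Rows carrying a NOT qualifier are skipped, as are rows whose term (after
    alt_id mapping) is absent from ``dag`` or whose aspect does not match the
    DAG's namespace.  ``exclude_evidence`` optionally drops evidence codes
    (e.g. ``{"IEA"}``); all codes are accepted by default.
    """
    exclude = set(exclude_evidence)
    aspect = _ASPECT_OF_NAMESPACE[dag.namespace]
    gene_terms: dict[str, set[str]] = {}
    n_rows = n_used = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < _GAF_MIN_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_GAF_MIN_COLUMNS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            n_rows += 1
            if "NOT" in cols[_GAF_QUALIFIER].split("|"):
                continue
            if cols[_GAF_ASPECT] and cols[_GAF_ASPECT] != aspect:
                continue
            if cols[_GAF_EVIDENCE] in exclude:
                continue
            term = dag.canonical(cols[_GAF_TERM])
            if term not in dag:
                continue
            gene_terms.setdefault(cols[_GAF_ID], set()).add(term)
            n_used += 1
    if n_used == 0:
        raise ValueError(f"no usable annotations in {path} ({n_rows} data rows)")
    return AnnotationTable(
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()}, closed=False
    )


def close_annotations(dag: OntologyDAG, ann: AnnotationTable) -> AnnotationTable:
    """Replace each gene's term set by its ancestor closure (idempotent)."""
    closed: dict[str, frozenset[str]] = {}
    for gene, terms in ann.gene_terms.items():
        out: set[str] = set()
        for t in terms:
            if t not in dag:
                raise KeyError(f"annotation term {t!r} (gene {gene!r}) not in ontology")
            out |= dag.ancestors(t)
        closed[gene] = frozenset(out)
    return AnnotationTable(gene_terms=closed, closed=True)


def compute_ic(dag: OntologyDAG, closed_ann: AnnotationTable) -> ICTable:
    """Information content from annotation frequencies in the closed corpus."""
    if not closed_ann.closed:
        raise ValueError("annotations must be ancestor-closed before IC computation")
    counts: dict[str, int] = {}
    for terms in closed_ann.gene_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n_root = counts.get(dag.root, 0)
    if n_root == 0:
        raise ValueError("no gene reaches the ontology root; empty IC corpus")
    ic = {t: -math.log(n / n_root) + 0.0 for t, n in counts.items()}  # +0.0 kills -0.0
    return ICTable(ic=ic, corpus_size=n_root)


def resnik_term_sim(ic: ICTable, dag: OntologyDAG, t1: str, t2: str) -> float:
    """Resnik similarity: IC of the most informative common ancestor.

    Each term counts as its own ancestor.  Returns 0 when the only shared
    ancestor is the root or when either term carries no information content.
    """
    if t1 not in dag or t2 not in dag:
        raise KeyError(f"unknown term in pair ({t1!r}, {t2!r})")
    if t1 not in ic or t2 not in ic:
        return 0.0
    common = dag.ancestors(t1) & dag.ancestors(t2)
    return max((ic.get(a, 0.0) for a in common), default=0.0)


def gene_sim(
    ic: ICTable,
    dag: OntologyDAG,
    closed_ann: AnnotationTable,
    g1: str,
    g2: str,
    combine: CombineMode = "max",
) -> float:
    """Gene-level Resnik similarity over the two genes' term sets.

    ``combine="max"`` takes the maximum term-pair similarity; ``"bma"`` the
    bidirectional best-match average.  An unannotated gene yields 0 (with a
    debug log), so genes present in a network but absent from the annotation
    corpus stay comparable rather than being dropped.
    """
    ts1, ts2 = closed_ann.terms_of(g1), closed_ann.terms_of(g2)
    if not ts1 or not ts2:
        log.debug("gene_sim: unannotated gene in pair (%s, %s) -> 0", g1, g2)
        return 0.0
    if combine == "max":
        return max(resnik_term_sim(ic, dag, a, b) for a in ts1 for b in ts2)
    if combine == "bma":
        best1 = [max(resnik_term_sim(ic, dag, a, b) for b in ts2) for a in ts1]
        best2 = [max(resnik_term_sim(ic, dag, a, b) for a in ts1) for b in ts2]
        return (sum(best1) + sum(best2)) / (len(best1) + len(best2))
    raise ValueError(f"unknown combine mode {combine!r}")


@dataclass
class SemanticBackground:
    """Bundle of (DAG, closed annotations, IC table) threaded through the pipeline."""

    dag: OntologyDAG
    annotations: AnnotationTable
    ic: ICTable

    def __post_init__(self) -> None:
        if not self.annotations.closed:
            raise ValueError("SemanticBackground requires ancestor-closed annotations")

    @classmethod
    def from_files(
        cls,
        obo_path,
        gaf_path,
        namespace: str = "biological_process",
        include_part_of: bool = True,
        exclude_evidence: Iterable[str] = (),
    ) -> "SemanticBackground":
        dag = load_obo(obo_path, namespace=namespace, include_part_of=include_part_of)
        ann = close_annotations(dag, load_gaf(gaf_path, dag, exclude_evidence))
        return cls(dag=dag, annotations=ann, ic=compute_ic(dag, ann))

    @classmethod
    def from_tables(cls, dag: OntologyDAG, ann: AnnotationTable) -> "SemanticBackground":
        if not ann.closed:
            ann = close_annotations(dag, ann)
        return cls(dag=dag, annotations=ann, ic=compute_ic(dag, ann))

    def gene_sim(self, g1: str, g2: str, combine: CombineMode = "max") -> float:
        return gene_sim(self.ic, self.dag, self.annotations, g1, g2, combine)
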