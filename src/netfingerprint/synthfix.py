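"""Synthetic ontologies, annotations and networks with planted structure.

Everything the pipeline consumes — OBO ontology files, GAF annotation
files, networks in every supported format, reference-set manifests — can
be generated here, so the full method is testable offline and every
generated artifact is reproducible byte-for-byte from (seed, parameters).

The generators emulate the statistical structure the fingerprint method
assumes about related networks: *related* network pairs share a planted
fraction of nodes and draw their annotations from a common ontology
branch, organized into functional modules (connected subgraphs whose
genes are annotated to the same sub-branch); *unrelated* pairs have
disjoint node sets annotated to disjoint branches.  Each generator also
returns a :class:`FixtureLedger` recording the planted ground truth
(overlaps, per-gene term assignments, related/unrelated labels) so tests
can check recovery against it.

Fixtures are written through the package's public writers and read back
through its public readers, so the format code is exercised by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .netio import (
    BioNetwork,
    RefEntry,
    ReferenceNetworkSet,
    load_refset,
    read_network,
    write_network,
)
from .ontology import AnnotationTable, OntologyDAG, SemanticBackground, load_gaf, load_obo

TERM_PREFIX = "SYN"


@dataclass
class FixtureLedger:
    """Ground-truth bookkeeping for one generated fixture."""

    seed: int
    parameters: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)


def _term_id(i: int) -> str:
    return f"{TERM_PREFIX}:{i:07d}"


# --------------------------------------------------------------------------
# ontology generators and OBO writer


def make_toy_ontology(
    n_terms: int,
    max_children: int = 3,
    seed: int = 0,
    max_parents: int = 2,
) -> tuple[OntologyDAG, FixtureLedger]:
    """Random single-root DAG grown by preferential-free random attachment.

    The first four terms form a root chain, guaranteeing depth >= 3 for any
    ``n_terms >= 4``; subsequent terms attach to 1–``max_parents`` existing
    terms, preferring parents with spare child slots (< ``max_children``).
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms (root plus two descendants)")
    rng = np.random.default_rng(seed)
    terms = [_term_id(i + 1) for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    child_count: dict[str, int] = {terms[0]: 0}
    chain = terms[: min(4, n_terms)]
    for child, parent in zip(chain[1:], chain[:-1]):
        parents[child] = {parent}
        child_count[parent] += 1
        child_count[child] = 0
    for t in terms[len(chain):]:
        existing = list(parents)
        open_slots = [p for p in existing if child_count[p] < max_children]
        pool = open_slots or existing
        k = int(rng.integers(1, max_parents + 1)) if max_parents > 1 else 1
        k = min(k, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        parents[t] = set(chosen)
        child_count[t] = 0
        for p in chosen:
            child_count[p] += 1
    dag = OntologyDAG(
        namespace="biological_process",
        parents={t: frozenset(ps) for t, ps in parents.items()},
        root=terms[0],
    )
    ledger = FixtureLedger(
        seed=seed,
        parameters={"n_terms": n_terms, "max_children": max_children,
                    "max_parents": max_parents},
        records={"parents": {t: sorted(ps) for t, ps in parents.items()}},
    )
    return dag, ledger


def make_branching_ontology(
    n_branches: int = 4,
    n_sub: int = 4,
    chain_len: int = 3,
    seed: int = 0,
) -> tuple[OntologyDAG, FixtureLedger]:
    """Deterministic DAG of disjoint branches for planted-structure scenarios.

    The root has ``n_branches`` children (branch roots); each branch root
    has ``n_sub`` sub-branch roots, each continuing as a specialization
    chain of ``chain_len`` terms.  Branches share only the root, so genes
    annotated to different branches have zero Resnik similarity, while
    genes annotated within one sub-branch share a deep (high-IC) ancestor.
    The ledger records the term pool of every (branch, sub-branch).
    """
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return _term_id(counter[0])

    root = fresh()
    parents: dict[str, set[str]] = {root: set()}
    branch_pools: list[list[list[str]]] = []
    branch_roots: list[str] = []
    for _ in range(n_branches):
        b = fresh()
        parents[b] = {root}
        branch_roots.append(b)
        sub_pools: list[list[str]] = []
        for _ in range(n_sub):
            s = fresh()
            parents[s] = {b}
            pool = [s]
            prev = s
            for _ in range(chain_len):
                c = fresh()
                parents[c] = {prev}
                pool.append(c)
                prev = c
            sub_pools.append(pool)
        branch_pools.append(sub_pools)
    dag = OntologyDAG(
        namespace="biological_process",
        parents={t: frozenset(ps) for t, ps in parents.items()},
        root=root,
    )
    ledger = FixtureLedger(
        seed=seed,
        parameters={"n_branches": n_branches, "n_sub": n_sub, "chain_len": chain_len},
        records={"branch_roots": branch_roots, "branch_pools": branch_pools},
    )
    return dag, ledger


def write_obo(dag: OntologyDAG, path) -> Path:
    """Write an OBO 1.2 file that :func:`~netfingerprint.ontology.load_obo`
    reads back to an identical parent map."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t in sorted(dag.parents):
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            fh.write(f"namespace: {dag.namespace}\n")
            for p in sorted(dag.parents[t]):
                fh.write(f"is_a: {p} ! synthetic term {p}\n")
    return path


# --------------------------------------------------------------------------
# annotation generator and GAF writer


def make_annotations(
    dag: OntologyDAG,
    genes: list[str],
    terms_per_gene: int = 3,
    seed: int = 0,
) -> tuple[AnnotationTable, FixtureLedger]:
    """Assign each gene ``terms_per_gene`` terms, biased toward deep terms.

    Sampling weight grows quadratically with term depth so leaves dominate,
    mimicking the specificity of curated annotation.  The ledger stores the
    exact per-gene assignment.
    """
    if not genes:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(seed)
    terms = sorted(dag.term_ids)
    depth = {t: dag.depth(t) for t in terms}
    w = np.array([(1 + depth[t]) ** 2 for t in terms], dtype=float)
    w /= w.sum()
    k = min(terms_per_gene, len(terms))
    gene_terms: dict[str, frozenset[str]] = {}
    for g in genes:
        picks = rng.choice(len(terms), size=k, replace=False, p=w)
        gene_terms[g] = frozenset(terms[i] for i in picks)
    ann = AnnotationTable(gene_terms=gene_terms, closed=False)
    ledger = FixtureLedger(
        seed=seed,
        parameters={"terms_per_gene": terms_per_gene, "n_genes": len(genes)},
        records={"assignments": {g: sorted(ts) for g, ts in gene_terms.items()}},
    )
    return ann, ledger


def write_gaf(ann: AnnotationTable, path, namespace: str = "biological_process") -> Path:
    """Write direct annotations as GAF 2.2 (17 columns), readable by
    :func:`~netfingerprint.ontology.load_gaf`."""
    aspect = {"biological_process": "P", "molecular_function": "F",
              "cellular_component": "C"}[namespace]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(ann.gene_terms):
            for term in sorted(ann.gene_terms[gene]):
                cols = ["SYNDB", gene, gene, "involved_in", term, "SYN:ref",
                        "IDA", "", aspect, f"{gene} protein", "", "protein",
                        "taxon:0000", "20260101", "SYNDB", "", ""]
                fh.write("\t".join(cols) + "\n")
    return path


# --------------------------------------------------------------------------
# KGML writer (subset: gene entries + relations), for fixture round-trips


def write_kgml(net: BioNetwork, path, number: str = "00001") -> Path:
    """Write a minimal KGML file with one gene entry per node and one
    PPrel relation per edge; reads back via ``read_network(..., "kgml")``."""
    from xml.sax.saxutils import quoteattr

    path = Path(path)
    nodes = sorted(net.nodes)
    ids = {n: i + 1 for i, n in enumerate(nodes)}
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name={quoteattr("path:syn" + number)} org="syn" '
        f'number="{number}" title={quoteattr(net.name)}>',
    ]
    for n in nodes:
        lines.append(
            f'  <entry id="{ids[n]}" name={quoteattr(n)} type="gene">'
            f'<graphics name={quoteattr(n)} type="rectangle"/></entry>'
        )
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
        lines.append(
            f'  <relation entry1="{ids[u]}" entry2="{ids[v]}" type="PPrel">'
            '<subtype name="binding/association" value="---"/></relation>'
        )
    lines.append("</pathway>")
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# network-pair and scenario generators


def _modular_edges(
    rng: np.random.Generator,
    module_nodes: list[list[str]],
    extra_per_module: int = 2,
) -> list[tuple[str, str]]:
    """Connect each module as a random path plus extra chords, then chain
    consecutive modules with a single bridge edge."""
    edges: list[tuple[str, str]] = []
    for nodes in module_nodes:
        if len(nodes) < 2:
            continue
        perm = [nodes[i] for i in rng.permutation(len(nodes))]
        edges.extend(zip(perm[:-1], perm[1:]))
        for _ in range(extra_per_module):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            edges.append((nodes[i], nodes[j]))
    occupied = [m for m in module_nodes if m]
    for a, b in zip(occupied[:-1], occupied[1:]):
        edges.append((a[int(rng.integers(len(a)))], b[int(rng.integers(len(b)))]))
    return edges


def _assign_terms(
    rng: np.random.Generator,
    genes: list[str],
    pool: list[str],
    terms_per_gene: int,
) -> dict[str, frozenset[str]]:
    k = min(terms_per_gene, len(pool))
    out = {}
    for g in genes:
        picks = rng.choice(len(pool), size=k, replace=False)
        out[g] = frozenset(pool[i] for i in picks)
    return out


def make_network_pair(
    n1: int,
    n2: int,
    overlap_frac: float,
    related: bool,
    dag: OntologyDAG,
    seed: int = 0,
    pools: list[list[list[str]]] | None = None,
    n_modules: int = 4,
    terms_per_gene: int = 3,
    gene_prefix: tuple[str, str, str] = ("qry", "ref", "shr"),
) -> tuple[BioNetwork, BioNetwork, AnnotationTable, FixtureLedger]:
    """Generate a (query, reference) network pair with planted structure.

    A fraction ``overlap_frac`` of the smaller node count is shared between
    the two networks.  Nodes are organized into ``n_modules`` functional
    modules — connected subgraphs whose genes are annotated to one
    sub-branch term pool.  When ``related``, both networks draw from the
    same ontology branch and module ``m`` of the query corresponds to
    module ``m`` of the reference; when not, the two networks use disjoint
    branches (and ``overlap_frac`` is forced to 0 — unrelated networks
    share no nodes).

    ``pools`` is the nested branch/sub-branch term-pool structure from
    :func:`make_branching_ontology`; if omitted, branch pools are derived
    from the children of ``dag``'s root.  Returns the two networks, the
    *direct* (unclosed) annotation table covering all their genes, and a
    ledger recording the planted overlap and assignments.
    """
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if pools is None:
        pools = _derive_pools(dag)
    if len(pools) < (1 if related else 2):
        raise ValueError("ontology does not expose enough disjoint branches")
    if not related:
        overlap_frac = 0.0
    n_shared = int(round(overlap_frac * min(n1, n2)))
    qp, rp, sp = gene_prefix
    shared = [f"{sp}{i:03d}" for i in range(n_shared)]
    only1 = [f"{qp}{i:03d}" for i in range(n1 - n_shared)]
    only2 = [f"{rp}{i:03d}" for i in range(n2 - n_shared)]

    branch1 = pools[0]
    branch2 = pools[0] if related else pools[1]
    n_modules = max(1, min(n_modules, len(branch1), len(branch2)))

    def modules_of(nodes: list[str]) -> dict[str, int]:
        return {g: i % n_modules for i, g in enumerate(nodes)}

    module_of = {**modules_of(shared), **modules_of(only1), **modules_of(only2)}

    gene_terms: dict[str, frozenset[str]] = {}
    for m in range(n_modules):
        g1_genes = [g for g in shared + only1 if module_of[g] == m]
        g2_genes = [g for g in only2 if module_of[g] == m]
        gene_terms.update(_assign_terms(rng, g1_genes, branch1[m], terms_per_gene))
        gene_terms.update(_assign_terms(rng, g2_genes, branch2[m], terms_per_gene))

    def build(name: str, nodes: list[str]) -> BioNetwork:
        module_nodes = [[g for g in nodes if module_of[g] == m] for m in range(n_modules)]
        return BioNetwork.from_edges(name, _modular_edges(rng, module_nodes), nodes=nodes)

    g1 = build("query", shared + only1)
    g2 = build("reference", shared + only2)
    ann = AnnotationTable(gene_terms=gene_terms, closed=False)
    ledger = FixtureLedger(
        seed=seed,
        parameters={
            "n1": n1, "n2": n2, "overlap_frac": overlap_frac, "related": related,
            "n_modules": n_modules, "terms_per_gene": terms_per_gene,
        },
        records={
            "shared_nodes": shared,
            "only_g1": only1,
            "only_g2": only2,
            "module_of": dict(module_of),
            "assignments": {g: sorted(ts) for g, ts in gene_terms.items()},
        },
    )
    return g1, g2, ann, ledger


def _derive_pools(dag: OntologyDAG) -> list[list[list[str]]]:
    """Branch/sub-branch term pools from the root's children of a generic DAG.

    A branch is a root child whose descendant set is disjoint from the other
    branches'; its sub-pools are the descendant sets of its own children.
    """
    children = sorted(
        t for t, ps in dag.parents.items() if dag.root in ps
    )
    pools: list[list[list[str]]] = []
    used: set[str] = set()
    for b in children:
        desc = dag.descendants(b)
        if desc & used:
            continue
        used |= desc
        sub_roots = sorted(t for t in desc if b in dag.parents[t])
        subs = [sorted(dag.descendants(s)) for s in sub_roots]
        if not subs:
            subs = [sorted(desc)]
        pools.append(subs)
    return pools


@dataclass
class ScenarioBundle:
    """A full planted-recovery scenario, reloaded through the public readers."""

    query: BioNetwork
    refset: ReferenceNetworkSet
    background: SemanticBackground
    ledger: FixtureLedger
    paths: dict[str, Path] = field(default_factory=dict)


#: scenario study conditions: per-network size, planted node overlap,
#: reference count (1 related + 3 unrelated) and module granularity
SCENARIO_N_NODES = 16
SCENARIO_OVERLAP = 0.3
SCENARIO_N_UNRELATED = 3
SCENARIO_N_MODULES = 4


def make_refset_scenario(seed: int, out_dir=None) -> ScenarioBundle:
    """Deterministic planted-recovery scenario: one query, four references.

    Reference ``related`` shares ~30% of its nodes with the query and draws
    annotations from the query's ontology branch (module-aligned);
    references ``unrel1..3`` are node-disjoint and annotated to disjoint
    branches.  All artifacts are written as real files (OBO, GAF, edge
    list, GraphML, KGML, manifest) into ``out_dir`` (a temporary directory
    if omitted) and read back through the public readers, so the returned
    objects went through the full I/O path.
    """
    import tempfile

    out_dir = Path(out_dir) if out_dir is not None else Path(tempfile.mkdtemp(prefix="synthfix_"))
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    s_pair, *s_unrel = (int(s) % 2**31 for s in master.generate_state(1 + SCENARIO_N_UNRELATED))

    dag, ont_ledger = make_branching_ontology(
        n_branches=1 + SCENARIO_N_UNRELATED, n_sub=SCENARIO_N_MODULES, chain_len=3, seed=seed
    )
    pools = ont_ledger.records["branch_pools"]

    query, related, ann, pair_ledger = make_network_pair(
        SCENARIO_N_NODES, SCENARIO_N_NODES, SCENARIO_OVERLAP, related=True,
        dag=dag, seed=s_pair, pools=[pools[0]],
        gene_prefix=("qry", "rel", "shr"),
    )
    all_terms = dict(ann.gene_terms)
    unrelated: list[BioNetwork] = []
    for i, s in enumerate(s_unrel):
        _, net, ann_u, _ = make_network_pair(
            SCENARIO_N_NODES, SCENARIO_N_NODES, 0.0, related=False,
            dag=dag, seed=s, pools=[pools[0], pools[1 + i]],
            gene_prefix=("dis", f"un{i}", "xx"),
        )
        net = net.copy(name=f"unrel{i + 1}")
        # the throwaway first network of the pair never enters the scenario
        all_terms.update(
            {g: ts for g, ts in ann_u.gene_terms.items() if g in net.nodes}
        )
        unrelated.append(net)

    obo = write_obo(dag, out_dir / "toy.obo")
    gaf = write_gaf(AnnotationTable(gene_terms=all_terms, closed=False), out_dir / "toy.gaf")
    paths: dict[str, Path] = {"obo": obo, "gaf": gaf}
    paths["query"] = write_network(query, out_dir / "query.edgelist")
    # reference files deliberately span every supported format
    manifest_rows = []
    ref_files = [
        ("planted", "related", related, "edgelist", "related.edgelist"),
        ("background", "unrel1", unrelated[0], "graphml", "unrel1.graphml"),
        ("background", "unrel2", unrelated[1], "kgml", "unrel2.xml"),
        ("background", "unrel3", unrelated[2], "edgelist", "unrel3.edgelist"),
    ]
    for group, name, net, fmt, fname in ref_files:
        fpath = out_dir / fname
        if fmt == "kgml":
            write_kgml(net, fpath)
        else:
            write_network(net, fpath, fmt)
        paths[name] = fpath
        manifest_rows.append(f"{group}\t{name}\t{fname}\t{fmt}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    paths["manifest"] = manifest

    # reload everything through the public readers
    dag_r = load_obo(obo)
    ann_r = load_gaf(gaf, dag_r)
    background = SemanticBackground.from_tables(dag_r, ann_r)
    refset = load_refset(manifest)
    query_r = read_network(paths["query"], "edgelist", name="query")

    ledger = FixtureLedger(
        seed=seed,
        parameters={
            "n_nodes": SCENARIO_N_NODES,
            "overlap_frac": SCENARIO_OVERLAP,
            "n_unrelated": SCENARIO_N_UNRELATED,
            "n_modules": SCENARIO_N_MODULES,
        },
        records={
            "related_reference": "related",
            "shared_nodes": pair_ledger.records["shared_nodes"],
            "pair": pair_ledger.records,
            "ontology": ont_ledger.parameters,
        },
    )
    return ScenarioBundle(
        query=query_r, refset=refset, background=background, ledger=ledger, paths=paths
    )
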