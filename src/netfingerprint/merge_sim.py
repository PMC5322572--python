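"""Network merging, semantic weighting, AP clustering and raw similarity.

The raw (unstandardized) similarity between two gene networks G1 and G2 is
computed in four stages:

1. **Merge** — pool nodes and edges into the union network
   ``G_m = (V1 ∪ V2, E1 ∪ E2)``; nodes with the same identifier collapse
   into one node that keeps every interaction, and each node carries a
   provenance label (only-G1 / only-G2 / shared).
2. **Semantic weighting** — Resnik gene similarity between merged nodes
   gives a symmetric non-negative matrix S_m over a fixed (sorted) node
   order.  For clustering, S_m is masked by the merged adjacency (the
   "weighted adjacency matrix"): that is how topology enters the score,
   and what the degree-preserving null later randomizes.
3. **Affinity propagation** — AP clustering on the weighted adjacency
   groups the merged nodes into functional-topological modules; the
   cluster count emerges from the preference parameter.
4. **Scoring** — each cluster k is scored by the bidirectional best-match
   average of S_m between its G1-only and G2-only members::

       LS_k = [ Σ_{i∈Vk1} max_{j∈Vk2} S_m(i,j)
              + Σ_{j∈Vk2} max_{i∈Vk1} S_m(i,j) ] / (n(Vk1) + n(Vk2))

   and the global score is the mean of LS_k over all clusters.  A cluster
   whose G1-only or G2-only side is empty scores 0 by default (it shows no
   cross-network correspondence); see ``skip_one_sided``.

Note the scoring in stage 4 uses the *full* semantic matrix: G1-only and
G2-only nodes are never adjacent in E1 ∪ E2, so restricting Eq-style
scoring to edges would make every cluster score vanish identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .netio import BioNetwork
from .ontology import CombineMode, SemanticBackground

log = logging.getLogger(__name__)

ONLY_G1, ONLY_G2, SHARED = "only_G1", "only_G2", "shared"

Provenance = Literal["only_G1", "only_G2", "shared"]


@dataclass
class MergedNetwork:
    """Union network with per-node provenance and a fixed node order."""

    network: BioNetwork
    provenance: dict[str, str]
    order: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.order)

    def nodes_with(self, prov: str) -> list[str]:
        return [n for n in self.order if self.provenance[n] == prov]

    def adjacency(self) -> np.ndarray:
        """0/1 adjacency over ``order`` (diagonal 0)."""
        idx = {n: i for i, n in enumerate(self.order)}
        a = np.zeros((len(self.order), len(self.order)))
        for u, v in self.network.graph.edges:
            i, j = idx[u], idx[v]
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass
class ClusterAssignment:
    """Result of exemplar-based clustering over a merged node order."""

    label: dict[str, int]
    exemplar: dict[int, str]
    n_clusters: int
    converged: bool

    def members(self, k: int) -> list[str]:
        if k not in self.exemplar:
            raise KeyError(f"unknown cluster id {k}")
        return [n for n, lab in self.label.items() if lab == k]

    def cluster_ids(self) -> list[int]:
        return sorted(self.exemplar)

    def partition(self) -> frozenset[frozenset[str]]:
        """Cluster memberships as a set of node sets (order-free comparison)."""
        return frozenset(frozenset(self.members(k)) for k in self.exemplar)


@dataclass
class SimilarityParams:
    """Tunable knobs of the raw-similarity pipeline (see docs/methods.md)."""

    combine: CombineMode = "max"
    preference: float | str = "median_nonzero"
    damping: float = 0.9
    max_iter: int = 1000
    conv_iter: int = 50
    cluster_on: Literal["adjacency", "full"] = "adjacency"
    skip_one_sided: bool = False
    shared_on_both_sides: bool = False

    def snapshot(self) -> dict:
        return {
            "combine": self.combine,
            "preference": self.preference,
            "damping": self.damping,
            "max_iter": self.max_iter,
            "conv_iter": self.conv_iter,
            "cluster_on": self.cluster_on,
            "skip_one_sided": self.skip_one_sided,
            "shared_on_both_sides": self.shared_on_both_sides,
        }


def merge_networks(g1: BioNetwork, g2: BioNetwork) -> MergedNetwork:
    """Union merge with name-based node identification.

    Nodes present in both inputs collapse into a single ``shared`` node
    inheriting all interactions; edges connecting the same two nodes merge
    into one.  Node order is lexicographically sorted for deterministic
    matrix indexing.
    """
    if g1.n_nodes == 0 or g2.n_nodes == 0:
        raise ValueError("cannot merge an empty network")
    union = BioNetwork.from_edges(
        f"{g1.name}+{g2.name}",
        [tuple(sorted(e)) for e in (g1.edges | g2.edges)],
        nodes=g1.nodes | g2.nodes,
    )
    prov = {}
    for n in union.nodes:
        in1, in2 = n in g1.nodes, n in g2.nodes
        prov[n] = SHARED if (in1 and in2) else (ONLY_G1 if in1 else ONLY_G2)
    return MergedNetwork(network=union, provenance=prov, order=tuple(sorted(union.nodes)))


def semantic_matrix(
    merged: MergedNetwork,
    ont: SemanticBackground,
    combine: CombineMode = "max",
) -> np.ndarray:
    """Symmetric Resnik gene-similarity matrix S_m over ``merged.order``.

    Unannotated genes give zero rows/columns (including the diagonal).
    """
    n = merged.n_nodes
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = ont.gene_sim(merged.order[i], merged.order[j], combine=combine)
            s[i, j] = s[j, i] = v
    return s


def weighted_adjacency(
    merged: MergedNetwork, sem: np.ndarray
) -> np.ndarray:
    """Semantic similarity masked by merged-network adjacency (diagonal 0)."""
    return sem * merged.adjacency()


def _resolve_preference(sim: np.ndarray, preference: float | str) -> float:
    off = sim[~np.eye(sim.shape[0], dtype=bool)]
    if preference == "median":
        return float(np.median(off)) if off.size else 0.0
    if preference == "median_nonzero":
        nz = off[off != 0]
        return float(np.median(nz)) if nz.size else 0.0
    return float(preference)


def _component_fallback(sim: np.ndarray, order: tuple[str, ...]) -> ClusterAssignment:
    """One cluster per connected component of the nonzero-similarity graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(order)))
    ii, jj = np.nonzero(np.triu(sim, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    label: dict[str, int] = {}
    exemplar: dict[int, str] = {}
    comps = sorted(nx.connected_components(g), key=min)
    for k, comp in enumerate(comps):
        idxs = sorted(comp)
        exemplar[k] = order[idxs[0]]
        for i in idxs:
            label[order[i]] = k
    return ClusterAssignment(
        label=label, exemplar=exemplar, n_clusters=len(comps), converged=False
    )


def ap_cluster(
    sim: np.ndarray,
    order: tuple[str, ...],
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """Affinity-propagation clustering of a similarity matrix.

    ``preference`` may be a number, ``"median"`` (median off-diagonal
    similarity) or ``"median_nonzero"`` (median of the nonzero off-diagonal
    entries — the pipeline default for sparse adjacency-masked input).
    On non-convergence the assignment falls back to one cluster per
    connected component of the nonzero-similarity graph, with
    ``converged=False`` and a logged warning.
    """
    n = sim.shape[0]
    if n < 2:
        raise ValueError("AP clustering requires at least 2 nodes")
    if sim.shape != (n, n) or len(order) != n:
        raise ValueError("similarity matrix and node order sizes disagree")
    pref = _resolve_preference(sim, preference)
    off = sim[~np.eye(n, dtype=bool)]
    if off.size and np.all(off == off.flat[0]) and off.flat[0] <= pref:
        # uniform similarities no stronger than the preference: no evidence
        # to merge anything, so every node is its own exemplar
        return ClusterAssignment(
            label={node: i for i, node in enumerate(order)},
            exemplar=dict(enumerate(order)),
            n_clusters=n,
            converged=True,
        )
    ap = AffinityPropagation(
        affinity="precomputed",
        preference=pref,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=conv_iter,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = ap.fit_predict(sim)
    if np.any(labels < 0) or len(ap.cluster_centers_indices_) == 0:
        log.warning(
            "AP did not converge on %d nodes (preference=%.4g); "
            "falling back to similarity components", n, pref,
        )
        return _component_fallback(sim, order)
    # relabel clusters by exemplar node-order index for determinism
    centers = list(ap.cluster_centers_indices_)
    center_rank = {c: r for r, c in enumerate(sorted(centers))}
    label = {order[i]: center_rank[centers[labels[i]]] for i in range(n)}
    exemplar = {center_rank[c]: order[c] for c in centers}
    return ClusterAssignment(
        label=label, exemplar=exemplar, n_clusters=len(centers), converged=True
    )


def _side_nodes(
    k: int,
    clusters: ClusterAssignment,
    merged: MergedNetwork,
    shared_on_both_sides: bool,
) -> tuple[list[str], list[str]]:
    members = clusters.members(k)
    side1 = [n for n in members if merged.provenance[n] == ONLY_G1]
    side2 = [n for n in members if merged.provenance[n] == ONLY_G2]
    if shared_on_both_sides:
        shared = [n for n in members if merged.provenance[n] == SHARED]
        side1 += shared
        side2 += shared
    return side1, side2


def local_similarity(
    k: int,
    clusters: ClusterAssignment,
    sim: np.ndarray,
    merged: MergedNetwork,
    shared_on_both_sides: bool = False,
) -> float:
    """Per-cluster bidirectional best-match-average score LS_k.

    Returns 0 when the cluster has no G1-only or no G2-only members (no
    cross-network correspondence to score).
    """
    side1, side2 = _side_nodes(k, clusters, merged, shared_on_both_sides)
    n1, n2 = len(side1), len(side2)
    if n1 + n2 == 0 or n1 == 0 or n2 == 0:
        return 0.0
    idx = {n: i for i, n in enumerate(merged.order)}
    i1 = [idx[n] for n in side1]
    i2 = [idx[n] for n in side2]
    block = sim[np.ix_(i1, i2)]
    return float(block.max(axis=1).sum() + block.max(axis=0).sum()) / (n1 + n2)


def global_similarity(
    clusters: ClusterAssignment,
    sim: np.ndarray,
    merged: MergedNetwork,
    skip_one_sided: bool = False,
    shared_on_both_sides: bool = False,
) -> float:
    """Mean of LS_k over clusters — the raw network–network similarity.

    With ``skip_one_sided``, clusters lacking one provenance side are
    excluded from the mean instead of contributing 0.
    """
    ids = clusters.cluster_ids()
    if not ids:
        raise ValueError("no clusters to score")
    scores = []
    for k in ids:
        side1, side2 = _side_nodes(k, clusters, merged, shared_on_both_sides)
        if skip_one_sided and (not side1 or not side2):
            continue
        scores.append(
            local_similarity(k, clusters, sim, merged, shared_on_both_sides)
        )
    return float(np.mean(scores)) if scores else 0.0


@dataclass
class RawSimilarityResult:
    score: float
    merged: MergedNetwork
    sem: np.ndarray = field(repr=False)
    clusters: ClusterAssignment = field(repr=False)


def raw_similarity_detailed(
    g1: BioNetwork,
    g2: BioNetwork,
    ont: SemanticBackground,
    params: SimilarityParams | None = None,
    seed: int = 0,
) -> RawSimilarityResult:
    """Full pipeline returning the score plus intermediate objects."""
    params = params or SimilarityParams()
    merged = merge_networks(g1, g2)
    sem = semantic_matrix(merged, ont, combine=params.combine)
    result = score_merged(merged, sem, params, seed=seed)
    return result


def score_merged(
    merged: MergedNetwork,
    sem: np.ndarray,
    params: SimilarityParams,
    seed: int = 0,
    adjacency: np.ndarray | None = None,
) -> RawSimilarityResult:
    """Cluster and score a merged network with a precomputed semantic matrix.

    ``adjacency`` lets callers (the randomization null) substitute a rewired
    topology without recomputing the semantic matrix, which depends only on
    node identities.
    """
    if params.cluster_on == "adjacency":
        mask = adjacency if adjacency is not None else merged.adjacency()
        cluster_input = sem * mask
    else:
        cluster_input = sem
    clusters = ap_cluster(
        cluster_input,
        merged.order,
        preference=params.preference,
        damping=params.damping,
        max_iter=params.max_iter,
        conv_iter=params.conv_iter,
        seed=seed,
    )
    score = global_similarity(
        clusters,
        sem,
        merged,
        skip_one_sided=params.skip_one_sided,
        shared_on_both_sides=params.shared_on_both_sides,
    )
    return RawSimilarityResult(score=score, merged=merged, sem=sem, clusters=clusters)


def raw_similarity(
    g1: BioNetwork,
    g2: BioNetwork,
    ont: SemanticBackground,
    params: SimilarityParams | None = None,
    seed: int = 0,
) -> float:
    """Raw (unstandardized) similarity score between two networks."""
    return raw_similarity_detailed(g1, g2, ont, params, seed=seed).score


def export_clusters(result: RawSimilarityResult, path) -> None:
    """Write the cluster assignment as TSV (node, cluster, exemplar, provenance)."""
    with open(path, "w") as fh:
        fh.write("node\tcluster\texemplar\tprovenance\n")
        for n in result.merged.order:
            k = result.clusters.label[n]
            fh.write(
                f"{n}\t{k}\t{result.clusters.exemplar[k]}\t{result.merged.provenance[n]}\n"
            )


__all__ = [
    "MergedNetwork",
    "ClusterAssignment",
    "SimilarityParams",
    "RawSimilarityResult",
    "merge_networks",
    "semantic_matrix",
    "weighted_adjacency",
    "ap_cluster",
    "local_similarity",
    "global_similarity",
    "raw_similarity",
    "raw_similarity_detailed",
    "score_merged",
    "export_clusters",
    "ONLY_G1",
    "ONLY_G2",
    "SHARED",
]
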