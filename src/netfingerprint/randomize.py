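"""Degree-preserving randomization and z-score standardization.

A raw similarity score partly reflects the topology (degree structure) of
the two networks rather than genuine functional correspondence.  To remove
that bias, the score is standardized against a null distribution obtained
by Maslov–Sneppen rewiring: repeated double-edge swaps that keep every
node's degree (and the node set, hence all annotations) unchanged while
shuffling who connects to whom.  The fingerprint coordinate is then the
z-score of the observed raw similarity against the rewired null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .merge_sim import SimilarityParams, merge_networks, score_merged, semantic_matrix
from .netio import BioNetwork
from .ontology import SemanticBackground

log = logging.getLogger(__name__)

RewireMode = Literal["query", "ref", "both"]

#: conventional Maslov–Sneppen mixing: swap attempts per edge
DEFAULT_SWAPS_PER_EDGE = 10

#: number of randomized networks used for standardization
DEFAULT_NPERM = 100


@dataclass
class NullDistribution:
    """Raw-similarity scores on rewired networks, with summary moments."""

    scores: np.ndarray
    nperm: int
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.nperm,):
            raise ValueError("score vector length must equal nperm")

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        # sample sd (n-1); degenerate single-draw nulls are rejected upstream
        return float(self.scores.std(ddof=1))

    def export_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("permutation\tscore\n")
            for i, s in enumerate(self.scores):
                fh.write(f"{i}\t{float(s)!r}\n")


def rewire(
    net: BioNetwork,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> BioNetwork:
    """Maslov–Sneppen degree-preserving rewiring by double-edge swaps.

    Performs ``swaps_per_edge * |E|`` swap *attempts*: each picks two
    distinct edges (a,b), (c,d) and replaces them with (a,d), (c,b) unless
    that would create a self-loop or a duplicate edge.  The node set and
    every node's degree are invariant.  Networks with fewer than 2 edges
    are returned as copies with a warning (nothing can be swapped).
    """
    m = net.n_edges
    if m < 2:
        log.warning("rewire: %s has %d edge(s); returning an unchanged copy", net.name, m)
        return net.copy()
    rng = np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in net.graph.edges]
    edges.sort()
    present = set(edges)
    attempts = swaps_per_edge * m
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):  # random orientation of the second edge
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 in present or e2 in present or e1 == e2:
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        present.add(e1)
        present.add(e2)
        edges[i], edges[j] = e1, e2
    return BioNetwork.from_edges(net.name, sorted(present), nodes=net.nodes)


def null_distribution(
    query: BioNetwork,
    ref: BioNetwork,
    ont: SemanticBackground,
    params: SimilarityParams | None = None,
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
    rewire_mode: RewireMode = "both",
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> NullDistribution:
    """Null raw-similarity distribution from rewired networks.

    Each permutation rewires the query and/or reference (``rewire_mode``,
    default both) with independent seed streams split from the master
    ``seed``, then recomputes the raw similarity.  Node labels — hence the
    semantic matrix — are untouched; only the wiring changes, so the
    semantic matrix is computed once and reused across permutations.
    """
    if nperm < 2:
        raise ValueError("nperm must be >= 2 to estimate a null sd")
    params = params or SimilarityParams()
    merged = merge_networks(query, ref)
    sem = semantic_matrix(merged, ont, combine=params.combine)
    streams = np.random.SeedSequence(seed).spawn(nperm)
    scores = np.empty(nperm)
    for p, stream in enumerate(streams):
        sq, sr, sc = (int(s) % 2**31 for s in stream.generate_state(3))
        rq = rewire(query, swaps_per_edge, seed=sq) if rewire_mode in ("query", "both") else query
        rr = rewire(ref, swaps_per_edge, seed=sr) if rewire_mode in ("ref", "both") else ref
        null_merged = merge_networks(rq, rr)
        # rewiring preserves node sets, so the merged order (and sem) is unchanged
        adj = null_merged.adjacency()
        scores[p] = score_merged(merged, sem, params, seed=sc, adjacency=adj).score
    return NullDistribution(scores=scores, nperm=nperm, seed=seed)


def standardize(observed: float, null: NullDistribution) -> float:
    """z-score of the observed raw similarity against the rewired null.

    A degenerate null (sd = 0) returns 0 when the observed score equals the
    null mean, otherwise a signed-infinity sentinel with a warning.
    """
    if null.nperm == 0 or null.scores.size == 0:
        raise ValueError("empty null distribution")
    sd = null.sd
    if sd == 0.0:
        if math.isclose(observed, null.mean, rel_tol=0.0, abs_tol=1e-12):
            return 0.0
        log.warning(
            "degenerate null (sd=0) with observed %.6g != mean %.6g; "
            "returning signed infinity sentinel", observed, null.mean,
        )
        return math.inf if observed > null.mean else -math.inf
    return (observed - null.mean) / sd
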