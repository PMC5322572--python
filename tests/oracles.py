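"""Independent brute-force oracles used to verify the implementation.

Everything here is written from the definitions, deliberately ignoring the
package's own code paths: ancestor sets by naive graph walks, IC by
re-scanning every gene per term, Resnik by enumerating common ancestors,
cluster scores by double loops, and affinity propagation by a direct
transcription of the message-passing update equations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_ancestors(parents: dict[str, frozenset[str]], term: str) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents[t]:
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def brute_closure(parents, gene_terms: dict[str, frozenset[str]]) -> dict[str, set[str]]:
    return {
        g: set().union(*(brute_ancestors(parents, t) for t in ts)) if ts else set()
        for g, ts in gene_terms.items()
    }


def brute_ic(parents, root: str, closed: dict[str, set[str]]) -> dict[str, float]:
    all_terms = set().union(*closed.values()) if closed else set()
    n_root = sum(1 for ts in closed.values() if root in ts)
    out = {}
    for t in all_terms:
        n_t = sum(1 for ts in closed.values() if t in ts)
        if n_t:
            out[t] = -math.log(n_t / n_root)
    return out


def brute_resnik(parents, ic: dict[str, float], t1: str, t2: str) -> float:
    if t1 not in ic or t2 not in ic:
        return 0.0
    common = brute_ancestors(parents, t1) & brute_ancestors(parents, t2)
    return max((ic.get(a, 0.0) for a in common), default=0.0)


def brute_gene_sim(parents, ic, closed, g1, g2, combine="max") -> float:
    ts1, ts2 = closed.get(g1, set()), closed.get(g2, set())
    if not ts1 or not ts2:
        return 0.0
    pairs = [[brute_resnik(parents, ic, a, b) for b in sorted(ts2)] for a in sorted(ts1)]
    if combine == "max":
        return max(max(row) for row in pairs)
    rows = [max(row) for row in pairs]
    cols = [max(row[j] for row in pairs) for j in range(len(pairs[0]))]
    return (sum(rows) + sum(cols)) / (len(rows) + len(cols))


def brute_local_similarity(members, provenance, sim_lookup) -> float:
    """LS_k by explicit double loop.

    ``members``: nodes of the cluster; ``provenance``: node -> label;
    ``sim_lookup(a, b)``: semantic similarity of two nodes.
    """
    v1 = [n for n in members if provenance[n] == "only_G1"]
    v2 = [n for n in members if provenance[n] == "only_G2"]
    if not v1 or not v2:
        return 0.0
    total = sum(max(sim_lookup(i, j) for j in v2) for i in v1)
    total += sum(max(sim_lookup(i, j) for i in v1) for j in v2)
    return total / (len(v1) + len(v2))


def brute_global_similarity(clusters_members, provenance, sim_lookup) -> float:
    scores = [
        brute_local_similarity(m, provenance, sim_lookup) for m in clusters_members
    ]
    return sum(scores) / len(scores)


def reference_affinity_propagation(
    S: np.ndarray,
    preference: float,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
    jitter_seed: int = 0,
):
    """Plain-numpy affinity propagation from the update equations.

    A tiny seeded jitter breaks exact ties (symmetric inputs otherwise
    oscillate between equivalent fixed points).  Returns
    (labels, exemplar_indices, converged); labels are exemplar indices per
    point, or None when no exemplar emerged.
    """
    S = S.astype(float).copy()
    n = S.shape[0]
    np.fill_diagonal(S, preference)
    scale = np.abs(S).max() or 1.0
    S += 1e-10 * scale * np.random.default_rng(jitter_seed).standard_normal((n, n))
    A = np.zeros((n, n))
    R = np.zeros((n, n))
    stable = 0
    last_exemplars: frozenset[int] = frozenset()
    converged = False
    for _ in range(max_iter):
        AS = A + S
        top_idx = AS.argmax(axis=1)
        top = AS[np.arange(n), top_idx]
        AS[np.arange(n), top_idx] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - top[:, None]
        Rnew[np.arange(n), top_idx] = S[np.arange(n), top_idx] - second
        R = damping * R + (1 - damping) * Rnew

        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, 0.0)
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, R.diagonal()[None, :] + colsum[None, :] - Rp)
        np.fill_diagonal(Anew, colsum)
        A = damping * A + (1 - damping) * Anew

        exemplars = frozenset(np.flatnonzero((A + R).diagonal() > 0).tolist())
        if exemplars and exemplars == last_exemplars:
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars
    exemplars = sorted(last_exemplars)
    if not exemplars:
        return None, [], False
    ex = np.array(exemplars)
    labels = ex[S[:, ex].argmax(axis=1)]
    labels[ex] = ex
    return labels, exemplars, converged


def partition_of_labels(labels, order) -> frozenset[frozenset[str]]:
    groups: dict[int, set[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(order[i])
    return frozenset(frozenset(v) for v in groups.values())
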