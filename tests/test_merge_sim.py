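import numpy as np
import pytest

from netfingerprint.merge_sim import (
    ONLY_G1,
    ONLY_G2,
    SHARED,
    SimilarityParams,
    ap_cluster,
    global_similarity,
    local_similarity,
    merge_networks,
    raw_similarity,
    raw_similarity_detailed,
    semantic_matrix,
    weighted_adjacency,
)
from netfingerprint.netio import BioNetwork
from netfingerprint.ontology import AnnotationTable, SemanticBackground
from netfingerprint.synthfix import make_annotations, make_network_pair, make_toy_ontology

from oracles import (
    brute_gene_sim,
    brute_global_similarity,
    brute_local_similarity,
    partition_of_labels,
    reference_affinity_propagation,
)


def _net(name, edges, nodes=()):
    return BioNetwork.from_edges(name, edges, nodes=nodes)


class TestMerge:
    def test_self_merge_all_shared(self):
        g = _net("g", [("a", "b"), ("b", "c")])
        m = merge_networks(g, g)
        assert m.network.nodes == g.nodes
        assert m.network.edges == g.edges
        assert all(p == SHARED for p in m.provenance.values())

    def test_disjoint_union(self):
        g1 = _net("g1", [("a", "b")])
        g2 = _net("g2", [("x", "y")])
        m = merge_networks(g1, g2)
        assert m.network.n_nodes == 4
        assert SHARED not in m.provenance.values()
        assert m.provenance["a"] == ONLY_G1
        assert m.provenance["x"] == ONLY_G2

    def test_inclusion_exclusion_on_planted_overlap(self):
        dag, _ = make_toy_ontology(n_terms=40, seed=5)
        g1, g2, _, ledger = make_network_pair(
            12, 10, 0.3, related=True, dag=dag, seed=5,
            pools=[[sorted(dag.term_ids)]],
        )
        m = merge_networks(g1, g2)
        shared = set(ledger.records["shared_nodes"])
        assert {n for n, p in m.provenance.items() if p == SHARED} == shared
        assert m.network.n_nodes == g1.n_nodes + g2.n_nodes - len(shared)

    def test_commutes_up_to_provenance_swap(self):
        g1 = _net("g1", [("a", "b"), ("b", "c")])
        g2 = _net("g2", [("b", "x")])
        m12, m21 = merge_networks(g1, g2), merge_networks(g2, g1)
        assert m12.order == m21.order
        assert m12.network.edges == m21.network.edges
        swap = {ONLY_G1: ONLY_G2, ONLY_G2: ONLY_G1, SHARED: SHARED}
        assert {n: swap[p] for n, p in m12.provenance.items()} == m21.provenance

    def test_empty_input_errors(self):
        g = _net("g", [("a", "b")])
        with pytest.raises(ValueError, match="empty"):
            merge_networks(g, BioNetwork(name="empty"))

    def test_order_is_sorted(self):
        m = merge_networks(_net("g1", [("b", "z")]), _net("g2", [("a", "z")]))
        assert m.order == tuple(sorted(m.order))


class TestSemanticMatrix:
    def test_all_unannotated_gives_zero_matrix(self, forked_background):
        m = merge_networks(_net("g1", [("u1", "u2")]), _net("g2", [("u3", "u4")]))
        s = semantic_matrix(m, forked_background)
        assert not s.any()

    def test_diagonal_is_self_similarity(self, forked_background):
        m = merge_networks(_net("g1", [("gA", "gB")]), _net("g2", [("gC", "gD")]))
        s = semantic_matrix(m, forked_background)
        for i, n in enumerate(m.order):
            assert s[i, i] == pytest.approx(forked_background.gene_sim(n, n))

    def test_symmetry_and_nonnegativity(self, forked_background):
        m = merge_networks(_net("g1", [("gA", "gB")]), _net("g2", [("gB", "gC")]))
        s = semantic_matrix(m, forked_background)
        assert np.allclose(s, s.T)
        assert (s >= 0).all()

    @pytest.mark.parametrize("combine", ["max", "bma"])
    def test_matches_elementwise_oracle(self, combine):
        dag, _ = make_toy_ontology(n_terms=30, seed=2)
        genes = [f"g{i}" for i in range(10)]
        ann, _ = make_annotations(dag, genes, 3, seed=2)
        bg = SemanticBackground.from_tables(dag, ann)
        g1 = _net("g1", [(genes[i], genes[i + 1]) for i in range(4)])
        g2 = _net("g2", [(genes[i], genes[i + 1]) for i in range(4, 9)])
        m = merge_networks(g1, g2)
        s = semantic_matrix(m, bg, combine=combine)
        closed = {g: set(ts) for g, ts in bg.annotations.gene_terms.items()}
        for i, a in enumerate(m.order):
            for j, b in enumerate(m.order):
                expected = brute_gene_sim(dag.parents, bg.ic.ic, closed, a, b, combine)
                assert s[i, j] == pytest.approx(expected, abs=1e-12)

    def test_weighted_adjacency_masks_non_edges(self, forked_background):
        m = merge_networks(_net("g1", [("gA", "gB")]), _net("g2", [("gA", "gC")]))
        s = semantic_matrix(m, forked_background)
        w = weighted_adjacency(m, s)
        idx = {n: i for i, n in enumerate(m.order)}
        assert w[idx["gB"], idx["gC"]] == 0.0  # not adjacent
        assert w[idx["gA"], idx["gB"]] == pytest.approx(s[idx["gA"], idx["gB"]])
        assert np.diagonal(w).sum() == 0.0


class TestAPCluster:
    def test_two_blocks_recovered(self):
        s = np.zeros((10, 10))
        s[:5, :5] = 3.0
        s[5:, 5:] = 3.0
        np.fill_diagonal(s, 0)
        order = tuple(f"n{i}" for i in range(10))
        res = ap_cluster(s, order, preference="median", seed=0)
        expected = frozenset(
            {frozenset(order[:5]), frozenset(order[5:])}
        )
        assert res.partition() == expected
        # and the independent message-passing oracle agrees
        pref = float(np.median(s[~np.eye(10, dtype=bool)]))
        labels, _, _ = reference_affinity_propagation(s, pref)
        assert partition_of_labels(labels, order) == expected

    def test_all_zero_similarity_gives_singletons(self):
        n = 6
        order = tuple(f"n{i}" for i in range(n))
        res = ap_cluster(np.zeros((n, n)), order, preference=0.0, seed=0)
        assert res.n_clusters == n
        assert all(res.exemplar[res.label[x]] == x for x in order)

    def test_duplicate_rows_share_cluster(self):
        # two groups of mutually identical points
        s = np.zeros((8, 8))
        s[:4, :4] = 2.0
        s[4:, 4:] = 2.0
        np.fill_diagonal(s, 0)
        order = tuple(f"n{i}" for i in range(8))
        res = ap_cluster(s, order, preference="median", seed=1)
        labels = {res.label[o] for o in order[:4]}
        assert len(labels) == 1
        assert len({res.label[o] for o in order[4:]}) == 1

    def test_single_node_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            ap_cluster(np.zeros((1, 1)), ("n0",))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_reference_implementation(self, seed):
        """Partition equality with an independent message-passing oracle on
        small instances with clearly separated planted clusters."""
        r = np.random.default_rng(seed)
        k, m = int(r.integers(2, 4)), int(r.integers(3, 5))
        n = min(k * m, 12)
        centers = 3.0 * np.arange(k)[:, None] * np.ones((k, 2))
        pts = np.vstack([centers[i // m] + 0.1 * r.normal(size=2) for i in range(n)])
        s = -((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        order = tuple(f"n{i}" for i in range(n))
        res = ap_cluster(s, order, preference="median", seed=seed)
        pref = float(np.median(s[~np.eye(n, dtype=bool)]))
        labels, _, _ = reference_affinity_propagation(s, pref)
        assert labels is not None
        assert res.partition() == partition_of_labels(labels, order)


def _fixed_clusters(merged, assignment):
    """Build a ClusterAssignment by hand for scoring tests."""
    from netfingerprint.merge_sim import ClusterAssignment

    exemplar = {}
    for node, k in assignment.items():
        exemplar.setdefault(k, node)
    return ClusterAssignment(
        label=dict(assignment),
        exemplar=exemplar,
        n_clusters=len(exemplar),
        converged=True,
    )


class TestLocalGlobalSimilarity:
    def _setup(self):
        m = merge_networks(_net("g1", [("a", "s")]), _net("g2", [("b", "s")]))
        idx = {n: i for i, n in enumerate(m.order)}
        sim = np.zeros((3, 3))
        sim[idx["a"], idx["b"]] = sim[idx["b"], idx["a"]] = 2.0
        return m, sim, idx

    def test_closed_form_single_pair(self):
        m, sim, _ = self._setup()
        clusters = _fixed_clusters(m, {"a": 0, "b": 0, "s": 0})
        # LS = (2.0 + 2.0) / 2
        assert local_similarity(0, clusters, sim, m) == pytest.approx(2.0)

    def test_shared_only_cluster_scores_zero(self):
        m, sim, _ = self._setup()
        clusters = _fixed_clusters(m, {"a": 0, "b": 0, "s": 1})
        assert local_similarity(1, clusters, sim, m) == 0.0

    def test_unknown_cluster_errors(self):
        m, sim, _ = self._setup()
        clusters = _fixed_clusters(m, {"a": 0, "b": 0, "s": 0})
        with pytest.raises(KeyError):
            local_similarity(7, clusters, sim, m)

    def test_global_is_exact_mean(self):
        m, sim, _ = self._setup()
        clusters = _fixed_clusters(m, {"a": 0, "b": 0, "s": 1})
        # LS_0 = 2.0, LS_1 = 0.0
        assert global_similarity(clusters, sim, m) == pytest.approx(1.0)
        assert global_similarity(
            clusters, sim, m, skip_one_sided=True
        ) == pytest.approx(2.0)

    def test_shared_on_both_sides_flag(self):
        m, sim, idx = self._setup()
        sim[idx["s"], idx["b"]] = sim[idx["b"], idx["s"]] = 5.0
        clusters = _fixed_clusters(m, {"a": 0, "b": 0, "s": 0})
        plain = local_similarity(0, clusters, sim, m)
        both = local_similarity(0, clusters, sim, m, shared_on_both_sides=True)
        assert plain == pytest.approx(2.0)
        assert both > plain  # shared node now contributes on both sides

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_random_clusters_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        dag, _ = make_toy_ontology(n_terms=30, seed=seed)
        g1, g2, ann, _ = make_network_pair(
            8, 8, 0.25, related=True, dag=dag, seed=seed,
            pools=[[sorted(dag.term_ids)]],
        )
        bg = SemanticBackground.from_tables(dag, ann)
        m = merge_networks(g1, g2)
        sim = semantic_matrix(m, bg)
        assignment = {n: int(rng.integers(0, 3)) for n in m.order}
        clusters = _fixed_clusters(m, assignment)
        idx = {n: i for i, n in enumerate(m.order)}
        lookup = lambda a, b: sim[idx[a], idx[b]]
        for k in clusters.cluster_ids():
            expected = brute_local_similarity(clusters.members(k), m.provenance, lookup)
            assert local_similarity(k, clusters, sim, m) == pytest.approx(expected, abs=1e-12)
        members = [clusters.members(k) for k in clusters.cluster_ids()]
        expected_g = brute_global_similarity(members, m.provenance, lookup)
        assert global_similarity(clusters, sim, m) == pytest.approx(expected_g, abs=1e-12)


class TestRawSimilarity:
    def test_self_comparison_is_zero(self, forked_background):
        g = _net("g", [("gA", "gB"), ("gB", "gC")])
        assert raw_similarity(g, g, forked_background) == 0.0

    def test_related_beats_unrelated(self):
        from netfingerprint.synthfix import make_branching_ontology

        dag, ledger = make_branching_ontology(n_branches=2, seed=0)
        pools = ledger.records["branch_pools"]
        g1, g2, ann, _ = make_network_pair(
            12, 12, 0.3, related=True, dag=dag, seed=0, pools=[pools[0]]
        )
        h1, h2, ann_u, _ = make_network_pair(
            12, 12, 0.0, related=False, dag=dag, seed=1, pools=pools,
            gene_prefix=("ua", "ub", "uc"),
        )
        merged_terms = {**ann.gene_terms, **ann_u.gene_terms}
        bg = SemanticBackground.from_tables(
            dag, AnnotationTable(gene_terms=merged_terms)
        )
        related_score = raw_similarity(g1, g2, bg, seed=0)
        unrelated_score = raw_similarity(h1, h2, bg, seed=0)
        assert unrelated_score < related_score
        assert unrelated_score == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_argument_swap(self, forked_background):
        g1 = _net("g1", [("gA", "gB")])
        g2 = _net("g2", [("gB", "gC")])
        s12 = raw_similarity(g1, g2, forked_background, seed=3)
        s21 = raw_similarity(g2, g1, forked_background, seed=3)
        assert s12 == pytest.approx(s21)

    def test_invariant_under_input_edge_order(self, forked_background):
        edges = [("gA", "gB"), ("gB", "gC"), ("gC", "gD")]
        g_fwd = _net("g", edges)
        g_rev = _net("g", [(b, a) for a, b in reversed(edges)])
        g2 = _net("h", [("gA", "gD")])
        assert raw_similarity(g_fwd, g2, forked_background, seed=1) == pytest.approx(
            raw_similarity(g_rev, g2, forked_background, seed=1)
        )

    def test_detailed_exposes_clusters(self, forked_background):
        g1 = _net("g1", [("gA", "gB")])
        g2 = _net("g2", [("gC", "gD")])
        detail = raw_similarity_detailed(g1, g2, forked_background, seed=0)
        assert detail.clusters.n_clusters >= 1
        assert set(detail.clusters.label) == set(detail.merged.order)

    def test_cluster_on_full_matrix_option(self, forked_background):
        g1 = _net("g1", [("gA", "gB")])
        g2 = _net("g2", [("gB", "gC")])
        params = SimilarityParams(cluster_on="full", preference="median")
        score = raw_similarity(g1, g2, forked_background, params=params, seed=0)
        assert score >= 0.0
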