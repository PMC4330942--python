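import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from seasonet import (community_significance, modularity, walktrap,
                      wilcoxon_signed_rank)


class TestModularity:
    def test_single_community_is_zero(self, barbell_triangles):
        assign = {v: 0 for v in barbell_triangles}
        assert modularity(barbell_triangles, assign) == pytest.approx(0.0)

    def test_singletons_are_negative(self, barbell_triangles):
        assign = {v: i for i, v in enumerate(barbell_triangles)}
        assert modularity(barbell_triangles, assign) < 0

    def test_barbell_triangle_partition(self, barbell_triangles):
        assign = {v: (0 if v in "abc" else 1) for v in barbell_triangles}
        # hand computation: m = 7, each triangle has 3 internal edges and
        # total strength 7, so Q = 2 * (3/7 - (7/14)^2) = 5/14
        assert modularity(barbell_triangles, assign) == pytest.approx(5 / 14)

    def test_matches_networkx(self, random_graph_factory):
        for seed in range(10):
            g = random_graph_factory(seed, n=15, p=0.3, weighted=True)
            assign = {v: v % 3 for v in g}
            groups = [{v for v in g if v % 3 == c} for c in range(3)]
            ours = modularity(g, assign)
            ref = nx.community.modularity(g, [s for s in groups if s],
                                          weight="weight")
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_unknown_node_rejected(self, barbell_triangles):
        assign = {v: 0 for v in barbell_triangles}
        assign["ghost"] = 1
        with pytest.raises(ValueError, match="ghost"):
            modularity(barbell_triangles, assign)


class TestWalktrap:
    def test_barbell_recovers_the_two_triangles(self, barbell_triangles):
        part = walktrap(barbell_triangles, t=4)
        comms = {frozenset(m) for m in part.communities.values()}
        assert comms == {frozenset("abc"), frozenset("def")}
        assert part.best_modularity == pytest.approx(5 / 14)

    def test_barbell_best_cut_is_bruteforce_optimum(self, barbell_triangles):
        # exhaustive search over all partitions of 6 nodes into <= 3 groups
        nodes = list(barbell_triangles)
        best = -1.0
        for labels in itertools.product(range(3), repeat=6):
            q = modularity(barbell_triangles, dict(zip(nodes, labels)))
            best = max(best, q)
        assert walktrap(barbell_triangles).best_modularity == pytest.approx(best)

    def test_disjoint_cliques_separated(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        part = walktrap(g, t=4)
        comms = {frozenset(m) for m in part.communities.values()}
        assert comms == {frozenset(range(4)), frozenset(range(4, 9))}

    def test_merge_count_equals_nodes_minus_components(self, random_graph_factory):
        for seed in range(20):
            g = random_graph_factory(seed, n=18, p=0.12)
            part = walktrap(g)
            n_comp = nx.number_connected_components(g)
            assert len(part.dendrogram) == g.number_of_nodes() - n_comp

    def test_dendrogram_is_valid_merge_forest(self, random_graph_factory):
        g = random_graph_factory(3, n=15, p=0.2)
        part = walktrap(g)
        alive = set(range(g.number_of_nodes()))
        for a, b, new, ds in part.dendrogram:
            assert a in alive and b in alive and ds >= 0
            alive -= {a, b}
            alive.add(new)

    def test_best_cut_dominates_dendrogram_partitions(self, random_graph_factory):
        # internal consistency: the chosen cut maximizes modularity over
        # every partition the merge sequence visits
        for seed in range(10):
            g = random_graph_factory(seed + 100, n=12, p=0.3, weighted=True)
            part = walktrap(g)
            assert part.best_modularity == pytest.approx(max(part.modularity_trace))

    def test_agrees_with_igraph_on_planted_partition(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(15)
        sizes = [8, 8, 8]
        probs = [[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]
        g = nx.stochastic_block_model(sizes, probs, seed=16)
        if not nx.is_connected(g):
            pytest.skip("sampled graph disconnected")
        part = walktrap(g, t=4)
        ig = igraph.Graph.TupleList((str(u), str(v)) for u, v in g.edges())
        ig_part = ig.community_walktrap(steps=4).as_clustering()
        ig_assign = {ig.vs[i]["name"]: c for c, comm in enumerate(ig_part)
                     for i in comm}
        ours = [part.assignment[v] for v in g]
        theirs = [ig_assign[str(v)] for v in g]
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(ours, theirs) == 1.0

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-0.5)
        with pytest.raises(ValueError, match="rho"):
            walktrap(g)

    def test_isolated_nodes_kept(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        g.add_node("lonely")
        part = walktrap(g)
        assert "lonely" in part.assignment


class TestWilcoxonSignedRank:
    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(5, 15))
            d = rng.normal(size=n)
            d = np.sign(d) * (np.abs(d) + np.linspace(0.01, 0.02, n))  # no ties
            x, y = d, np.zeros(n)
            w, p, _ = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(d, method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_positive_equal_differences_exact(self):
        # 10 identical positive differences: P(W+ = max) = 1/2^10 per tail
        x = np.full(10, 9.0)
        y = np.full(10, 1.0)
        w, p, _ = wilcoxon_signed_rank(x, y)
        assert w == pytest.approx(55.0)
        assert p == pytest.approx(2 / 1024)

    def test_normal_approximation_branch(self):
        rng = np.random.default_rng(18)
        d = rng.normal(0.5, 1.0, size=40)
        d = d[d != 0]
        w, p, _ = wilcoxon_signed_rank(d, np.zeros_like(d))
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_degenerate(self):
        w, p, n_zero = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0 and n_zero == 2


class TestCommunitySignificance:
    def make_k10_with_pendants(self):
        g = nx.complete_graph(10)
        for i in range(10):
            g.add_edge(i, f"ext{i}")
        return g

    def test_k10_pendant_fixture_exact_p(self):
        g = self.make_k10_with_pendants()
        assignment = {v: (0 if isinstance(v, int) else 1 + int(str(v)[3:]))
                      for v in g}
        results = community_significance(g, assignment, min_size=9)
        big = [r for r in results if r.community == 0][0]
        assert big.tested and big.size == 10
        # every member: internal degree 9, residual 1, difference +8
        assert all(big.internal_degrees[v] == 9 for v in big.members)
        assert all(big.residual_degrees[v] == 1 for v in big.members)
        assert big.p_value == pytest.approx(2 / 1024)

    def test_community_of_nine_not_tested(self):
        g = nx.complete_graph(9)
        results = community_significance(g, {v: 0 for v in g}, min_size=9)
        assert results[0].tested is False
        assert np.isnan(results[0].p_value)

    def test_internal_plus_residual_equals_degree(self, random_graph_factory):
        rng = np.random.default_rng(19)
        for seed in range(100):
            g = random_graph_factory(seed, n=int(8 + seed % 18), p=0.3)
            assignment = {v: int(rng.integers(0, 3)) for v in g}
            for res in community_significance(g, assignment, min_size=0):
                for v in res.members:
                    assert (res.internal_degrees[v] + res.residual_degrees[v]
                            == g.degree(v))

    def test_equal_internal_and_residual_degenerate(self):
        # 4-cycle split into adjacent pairs: every node has exactly one
        # internal and one external edge
        g = nx.cycle_graph(4)
        assignment = {0: 0, 1: 0, 2: 1, 3: 1}
        results = community_significance(g, assignment, min_size=1)
        for r in results:
            assert r.tested and r.degenerate
            assert r.p_value == 1.0

    def test_pvalues_roughly_uniform_under_rewiring_null(self):
        # degree-preserving rewiring destroys community structure, so the
        # test applied to an arbitrary 12-node group should not be
        # systematically significant
        # 29 nodes with a 15-node group: every member sees exactly half of
        # the other 28 nodes inside the group, so internal and residual
        # degrees are exchangeable under rewiring
        rng = np.random.default_rng(20)
        base = nx.gnp_random_graph(29, 0.25, seed=21)
        pvals = []
        for rep in range(200):
            g = base.copy()
            nx.double_edge_swap(g, nswap=60, max_tries=5000,
                                seed=int(rng.integers(2**31)))
            nodes = list(g)
            rng.shuffle(nodes)
            assignment = {v: (0 if v in set(nodes[:15]) else 1) for v in g}
            res = [r for r in community_significance(g, assignment, min_size=9)
                   if r.community == 0][0]
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
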