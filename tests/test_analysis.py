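import networkx as nx
import numpy as np
import pytest

import infrank as ir
from infrank.analysis import (kcore_baseline, pagerank_baseline,
                              pairwise_distance_profile, rank_by_cutoff,
                              seed_subnetwork, spearman_rho,
                              subsample_stability, top_fold_change)
from infrank.distance import DistanceTable, all_pairs
from infrank.network_io import BackgroundNetwork
from conftest import random_mixed_network


class TestSpearman:
    def test_closed_form_endpoints(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # classic formula 1 - 6*sum(d^2)/(n(n^2-1)) without ties:
        # ranks (1,2,3,4,5) vs (2,1,4,3,5): d^2 sums to 4 -> 1 - 24/120 = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)


class TestRankByCutoff:
    def test_all_distance_one_network_is_flat(self):
        net, expr, _ = ir.generate(ir.SyntheticSpec(
            seed=2, n_pathway_edges=0, n_ppi_edges=0))
        dist = all_pairs(net, cap=15)
        rep = rank_by_cutoff(net, dist, expr, k_max=3, m=10)
        # the planted star only has distance-1 pairs: every cutoff identical
        assert all(rho == pytest.approx(1.0) for rho in rep.spearman.values())

    def test_final_cutoff_rho_is_one(self):
        net, expr, _ = ir.generate(ir.SyntheticSpec(seed=3))
        dist = all_pairs(net, cap=15)
        rep = rank_by_cutoff(net, dist, expr, k_max=4, m=20)
        assert rep.spearman[4] == pytest.approx(1.0)

    def test_rho_trends_toward_one(self):
        net, expr, _ = ir.generate(ir.SyntheticSpec(seed=6))
        dist = all_pairs(net, cap=15)
        rep = rank_by_cutoff(net, dist, expr, k_max=5, m=25)
        rhos = [rep.spearman[k] for k in rep.cutoffs if rep.spearman[k] is not None]
        assert rhos[-1] == pytest.approx(1.0)
        assert min(rhos) >= -1.0 and rhos[-1] >= rhos[0] - 1e-12


class TestSubsampleStability:
    def test_full_fraction_gives_perfect_overlap(self):
        net, expr, _ = ir.generate(ir.SyntheticSpec(seed=1))
        dist = all_pairs(net, cap=15)
        rep = subsample_stability(net, dist, expr, k=10, n_resamples=3,
                                  fraction=1.0, seed=0)
        assert rep.overlaps == [10, 10, 10]
        assert rep.mean == 10.0 and rep.sd == 0.0

    def test_seeded_runs_are_reproducible(self):
        net, expr, _ = ir.generate(ir.SyntheticSpec(seed=1))
        dist = all_pairs(net, cap=15)
        a = subsample_stability(net, dist, expr, k=5, n_resamples=5,
                                fraction=0.5, seed=9)
        b = subsample_stability(net, dist, expr, k=5, n_resamples=5,
                                fraction=0.5, seed=9)
        assert a.overlaps == b.overlaps

    def test_too_small_fraction_errors(self):
        net, expr, _ = ir.generate(ir.SyntheticSpec(seed=1))
        dist = all_pairs(net, cap=15)
        with pytest.raises(ValueError, match="fraction"):
            subsample_stability(net, dist, expr, fraction=0.01, n_resamples=1)


def brute_force_coreness(net):
    """Iterative peeling oracle on the undirected view."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.directed_edges)
    g.add_edges_from(net.undirected_edges)
    core = {}
    k = 0
    g = g.copy()
    while g.nodes:
        while True:
            drop = [n for n in g.nodes if g.degree(n) <= k]
            if not drop:
                break
            for n in drop:
                core[n] = k
                g.remove_node(n)
        k += 1
    return core


class TestKCoreBaseline:
    def test_clique_plus_pendant(self):
        net = BackgroundNetwork()
        clique = ["a", "b", "c", "d"]
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                net.add_undirected(u, v)
        net.add_undirected("d", "pend")
        ranked = kcore_baseline(net, clique + ["pend"], k_top=5)
        assert set(ranked[:4]) == set(clique)
        assert ranked[4] == "pend"

    def test_tree_all_coreness_one(self):
        net = BackgroundNetwork()
        for u, v in [("r", "a"), ("r", "b"), ("a", "c"), ("a", "d")]:
            net.add_undirected(u, v)
        # ties broken by degree then id: 'a' (deg 3) before 'r' (deg 2)
        ranked = kcore_baseline(net, sorted(net.nodes), k_top=6)
        assert ranked[0] == "a" and ranked[1] == "r"

    def test_matches_peeling_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            net = random_mixed_network(rng, n_nodes=12, p_dir=0.2, p_undir=0.2)
            oracle = brute_force_coreness(net)
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            g.add_edges_from(net.directed_edges)
            g.add_edges_from(net.undirected_edges)
            assert nx.core_number(g) == oracle


class TestPageRankBaseline:
    def test_star_hub_ranks_first(self):
        net = BackgroundNetwork()
        for leaf in "bcdef":
            net.add_undirected("hub", leaf)
        assert pagerank_baseline(net, 1)[0] == "hub"

    def test_regular_graph_uniform(self):
        net = BackgroundNetwork()
        cycle = ["a", "b", "c", "d", "e"]
        for i, u in enumerate(cycle):
            net.add_undirected(u, cycle[(i + 1) % 5])
        ranked = pagerank_baseline(net, 5)
        assert ranked == sorted(cycle)  # all tied -> lexicographic

    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(8):
            net = random_mixed_network(rng, n_nodes=10, p_dir=0.2, p_undir=0.2)
            if net.n_edges == 0:
                continue
            g = nx.DiGraph()
            g.add_nodes_from(net.nodes)
            for u, v in net.directed_edges:
                g.add_edge(u, v)
            for a, b in net.undirected_edges:
                g.add_edge(a, b)
                g.add_edge(b, a)
            beta = 0.2
            nx_scores = nx.pagerank(g, alpha=1 - beta, tol=1e-12, max_iter=2000)
            from infrank.dynamic import DynamicNetwork, DynEdge
            from infrank.tspr import (TSPRConfig, build_transition, tspr_run,
                                      uniform_topic)
            edges = {}
            for u, v in net.directed_edges:
                edges[(u, v)] = DynEdge(1.0, 1, 1.0)
            for a, b in net.undirected_edges:
                edges.setdefault((a, b), DynEdge(1.0, 1, 1.0))
                edges.setdefault((b, a), DynEdge(1.0, 1, 1.0))
            dyn = DynamicNetwork(edges=edges, node_universe=set(net.nodes))
            res = tspr_run(build_transition(dyn, sorted(net.nodes)),
                           uniform_topic(net.nodes),
                           TSPRConfig(beta=beta, tol=1e-13, max_iter=5000,
                                      dangling="uniform"))
            for g_ in net.nodes:
                assert res.scores[g_] == pytest.approx(nx_scores[g_], abs=1e-8)


class TestDistanceProfileAndSubnetwork:
    def test_connected_clique_no_isolated(self):
        net = BackgroundNetwork()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            net.add_undirected(u, v)
        dist = all_pairs(net, cap=3)
        hist, isolated = pairwise_distance_profile(["a", "b", "c"], dist)
        assert isolated == [] and hist == {1: 6}

    def test_mutually_unreachable_all_isolated(self):
        dist = DistanceTable(entries={}, cap=3)
        hist, isolated = pairwise_distance_profile(["x", "y", "z"], dist)
        assert hist == {} and isolated == ["x", "y", "z"]

    def test_single_planted_outlier(self):
        net = BackgroundNetwork()
        net.add_undirected("a", "b")
        net.add_undirected("b", "c")
        net.add_directed("far1", "far2")  # 'lone' touches nothing in the set
        net.nodes.add("lone")
        dist = all_pairs(net, cap=5)
        _, isolated = pairwise_distance_profile(["a", "b", "c", "lone"], dist)
        assert isolated == ["lone"]

    def test_seed_chain_subnetwork(self):
        net = BackgroundNetwork()
        net.add_directed("A", "B")
        net.add_directed("B", "C")
        dist = all_pairs(net, cap=5)
        edges = seed_subnetwork(["A", "B", "C"], dist, max_d=3)
        assert set(edges) == {("A", "B", 1), ("B", "C", 1), ("A", "C", 2)}

    def test_disconnected_seeds_empty(self):
        dist = DistanceTable(entries={}, cap=3)
        assert seed_subnetwork(["p", "q"], dist) == []

    def test_subnetwork_agrees_with_table(self):
        rng = np.random.default_rng(17)
        net = random_mixed_network(rng, n_nodes=10)
        dist = all_pairs(net, cap=10)
        seeds = sorted(net.nodes)[:6]
        for u, v, d in seed_subnetwork(seeds, dist, max_d=3):
            assert dist.get(u, v) == d and d <= 3


def test_top_fold_change_orders_by_weight():
    net, expr, truth = ir.generate(ir.SyntheticSpec(seed=0))
    top = top_fold_change(expr, 5)
    assert top[0] == truth["regulators"][0]
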