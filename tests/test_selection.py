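import numpy as np
import pytest

from mulnet.clusters import ClusterRecord
from mulnet.phylo import Multiset
from mulnet.selection import (CompatibilityGraph, approx_compatible, build_graph,
                              node_weight, solve_bruteforce, solve_ilp,
                              verify_solution)


def rec(labels, m=1, s=1):
    return ClusterRecord(Multiset(labels), m, s)


class TestApproxCompatible:
    L = Multiset("xxyzz")

    def test_disjoint_remainder(self):
        # L \ {x,y} = {x,z,z} contains {x,z}
        assert approx_compatible(rec("xy"), rec("xz"), self.L)

    def test_containment_ignores_L(self):
        assert approx_compatible(rec("x"), rec("xy"), self.L)
        assert approx_compatible(rec("xy"), rec("x"), self.L)

    def test_incompatible_with_multiplicities(self):
        L = Multiset("xxyyzz")
        assert not approx_compatible(rec("xy", m=2), rec("yz", m=2), L)

    def test_not_fitting_raises(self):
        with pytest.raises(ValueError):
            approx_compatible(rec("xxx"), rec("xy"), self.L)

    def test_symmetric_by_default(self, rng):
        labels = "xyz"
        L = Multiset("xxyyzz")
        for _ in range(50):
            c1 = Multiset(rng.choice(list(labels), size=rng.integers(1, 4)))
            c2 = Multiset(rng.choice(list(labels), size=rng.integers(1, 4)))
            m1 = int(rng.integers(1, 3))
            m2 = int(rng.integers(1, 3))
            if not (c1.scaled(m1) <= L and c2.scaled(m2) <= L):
                continue
            r1, r2 = ClusterRecord(c1, m1, 1), ClusterRecord(c2, m2, 1)
            assert approx_compatible(r1, r2, L) == approx_compatible(r2, r1, L)

    def test_reflexive_containment(self):
        r = rec("xy")
        assert approx_compatible(r, r, self.L)

    def test_asymmetric_strict_mode_exists(self):
        # strict one-directional reading can disagree with its mirror
        L = Multiset("aabb")
        r1 = ClusterRecord(Multiset("ab"), 2, 1)
        r2 = ClusterRecord(Multiset("aab"), 1, 1)
        fwd = approx_compatible(r1, r2, L, symmetric=False)
        rev = approx_compatible(r2, r1, L, symmetric=False)
        sym = approx_compatible(r1, r2, L, symmetric=True)
        assert sym == (fwd or rev)


class TestNodeWeight:
    def test_unit(self):
        assert node_weight(rec("x", m=1, s=1), alpha=0.65) == pytest.approx(1.0)

    def test_paper_formula(self):
        w = node_weight(rec("abc", m=2, s=5), alpha=0.65)
        assert w == pytest.approx(2 * 5 * 3 ** 0.65, abs=1e-6)
        assert w == pytest.approx(20.4234, abs=1e-3)

    def test_monotonicity(self):
        assert node_weight(rec("ab", s=2)) == 2 * node_weight(rec("ab", s=1))
        assert node_weight(rec("abc")) > node_weight(rec("ab"))


class TestBuildGraph:
    def test_containment_chain_is_complete(self):
        L = Multiset("abcd")
        records = [rec("a"), rec("ab"), rec("abc"), rec("abcd")]
        g = build_graph(records, L)
        assert g.adjacency[np.triu_indices(4, 1)].all()

    def test_toy_edge(self, toy_tree):
        from mulnet.clusters import compute_sorted_clusters
        records, _ = compute_sorted_clusters([toy_tree])
        records = records + [ClusterRecord(Multiset("xy"), 1, 1)]
        L = toy_tree.leaf_multiset()
        g = build_graph(records, L)
        idx = {r.cluster: i for i, r in enumerate(g.records)}
        assert g.adjacency[idx[Multiset("xy")], idx[Multiset("xz")]]

    def test_adjacency_symmetric(self, rng):
        from mulnet.simulate import random_binary_multree
        from mulnet.clusters import compute_sorted_clusters
        trees = [random_binary_multree(rng, "abcd", max_copies=2) for _ in range(5)]
        records, _ = compute_sorted_clusters(trees)
        from mulnet.consensus import infer_leaf_multiset
        g = build_graph(records, infer_leaf_multiset(trees))
        assert (g.adjacency == g.adjacency.T).all()
        assert not g.adjacency.diagonal().any()

    def test_unfitting_record_dropped(self):
        L = Multiset("ab")
        g = build_graph([rec("ab"), rec("aab")], L)
        assert g.n == 1


def synthetic_graph(records, weights, edges):
    n = len(records)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return CompatibilityGraph(records, np.asarray(weights, float), adj)


class TestSolveILP:
    def test_empty(self):
        g = synthetic_graph([], [], [])
        assert solve_ilp(g) == solve_bruteforce(g)
        assert solve_ilp(g).total_weight == 0.0

    def test_pair_beats_heavier_singleton(self):
        g = synthetic_graph([rec("a"), rec("b"), rec("c")], [3, 2, 2], [(1, 2)])
        sol = solve_ilp(g)
        assert set(sol.selected) == {1, 2}
        assert sol.total_weight == pytest.approx(4.0)

    def test_one_multiplicity_per_cluster(self):
        r1 = ClusterRecord(Multiset("ab"), 1, 1)
        r2 = ClusterRecord(Multiset("ab"), 2, 1)
        g = synthetic_graph([r1, r2], [2, 3], [(0, 1)])
        sol = solve_ilp(g)
        assert sol.selected == (1,)
        assert sol.total_weight == pytest.approx(3.0)

    def test_single_vertex(self):
        g = synthetic_graph([rec("a")], [1.5], [])
        assert solve_bruteforce(g).selected == (0,)
        assert solve_ilp(g).total_weight == pytest.approx(1.5)

    def test_no_edges_best_singleton(self):
        g = synthetic_graph([rec("a"), rec("b"), rec("c")], [1, 5, 2], [])
        assert solve_bruteforce(g).selected == (1,)
        assert solve_ilp(g).total_weight == pytest.approx(5.0)


def random_instance(rng, n):
    """Random weights, adjacency and base-cluster groupings on n vertices."""
    n_clusters = int(rng.integers(max(1, n // 2), n + 1))
    records = []
    for i in range(n):
        base = int(rng.integers(n_clusters))
        m = int(rng.integers(1, 4))
        records.append(ClusterRecord(Multiset([f"c{base}"] * 2), m, 1))
    # dedupe (cluster, multiplicity) keys: perturb multiplicities
    seen = {}
    for i, r in enumerate(records):
        while r.key() in seen:
            r = ClusterRecord(r.cluster, r.multiplicity + 1, 1)
        seen[r.key()] = True
        records[i] = r
    weights = rng.uniform(0.1, 10.0, size=n)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                adj[i, j] = adj[j, i] = True
    return CompatibilityGraph(records, weights, adj)


class TestOracleEquivalence:
    def test_small_random_instances(self, rng):
        for _ in range(50):
            g = random_instance(rng, int(rng.integers(1, 11)))
            a, b = solve_ilp(g), solve_bruteforce(g)
            assert a.total_weight == pytest.approx(b.total_weight, abs=1e-6)
            assert verify_solution(g, a) and verify_solution(g, b)
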