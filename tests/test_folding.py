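import numpy as np
import pytest

from conftest import make_random_network
from mulnet.clusters import ClusterFrequencyMap
from mulnet.folding import (are_near_isomorphic, assign_codes, binarize_reticulations,
                            compute_clade_score, fold, normalized_ged)
from mulnet.metrics import network_distance
from mulnet.phylo import Multiset, parse_enewick, parse_newick, unfold, write_enewick


def clades_of(text):
    """Parse and return (tree, root's children)."""
    t = parse_newick(text)
    return t, t.root.children


class TestCodes:
    def test_leaf_code(self):
        t = parse_newick("x;")
        assert assign_codes(t)[t.root] == "x"

    def test_child_order_invariant(self):
        t1 = parse_newick("(a,b);")
        t2 = parse_newick("(b,a);")
        assert assign_codes(t1)[t1.root] == assign_codes(t2)[t2.root] == "(a,b)"

    def test_topology_sensitive(self):
        t1 = parse_newick("(a,(b,c));")
        t2 = parse_newick("((a,b),c);")
        assert assign_codes(t1)[t1.root] != assign_codes(t2)[t2.root]


class TestNormalizedGED:
    def test_identical_zero(self):
        t1 = parse_newick("((a,b),c);")
        t2 = parse_newick("((a,b),c);")
        assert normalized_ged(t1.root, t2.root) == 0.0

    def test_single_substitution(self):
        # cherry vs cherry differing in one leaf label: GED 1, |V|+|E| = 5 each
        t1 = parse_newick("(a,b);")
        t2 = parse_newick("(a,c);")
        assert normalized_ged(t1.root, t2.root) == pytest.approx(1 / 10)

    def test_symmetric_and_bounded(self):
        t1 = parse_newick("(a,b);")
        t2 = parse_newick("(a,(b,c));")
        d12 = normalized_ged(t1.root, t2.root)
        d21 = normalized_ged(t2.root, t1.root)
        assert d12 == pytest.approx(d21)
        assert 0 < d12 < 1

    def test_large_clades_use_anytime_bound(self):
        labels = [f"t{i}" for i in range(10)]
        t1 = parse_newick("(" + ",".join(labels) + ");")
        t2 = parse_newick("(" + ",".join(reversed(labels)) + ");")
        d = normalized_ged(t1.root, t2.root, exact_cap=5)
        assert 0.0 <= d <= 1.0


class TestAreNearIsomorphic:
    def test_equal_codes(self):
        t = parse_newick("((a,b),(b,a));")
        u, v = t.root.children
        assert are_near_isomorphic(u, v, 0.0)

    def test_cluster_gate(self):
        t = parse_newick("((a,(b,c)),(a,b));")
        u, v = t.root.children
        assert not are_near_isomorphic(u, v, 1.0)

    def test_threshold(self):
        t = parse_newick("((a,(b,c)),((a,b),c));")
        u, v = t.root.children
        d = normalized_ged(u, v)
        assert are_near_isomorphic(u, v, 0.3) == (d <= 0.3)
        assert not are_near_isomorphic(u, v, 0.0)


class TestCladeScore:
    def test_doubled_multiplicity_branch(self):
        s = ClusterFrequencyMap({(Multiset("ab"), 2): 4})
        t = parse_newick("(a,b);")
        assert compute_clade_score(t.root, s) == 8.0

    def test_fallback_branch(self):
        s = ClusterFrequencyMap({(Multiset("ab"), 1): 7})
        t = parse_newick("(a,b);")
        assert compute_clade_score(t.root, s) == 7.0

    def test_unknown_clusters_zero(self):
        t = parse_newick("((a,b),c);")
        assert compute_clade_score(t.root, ClusterFrequencyMap()) == 0.0


class TestFold:
    def test_double_cherry(self):
        t = parse_newick("((a,b),(a,b));")
        net = fold(t, delta=0.0)
        assert len(net.reticulations()) == 1
        from conftest import trees_isomorphic
        assert trees_isomorphic(unfold(net), t)

    def test_uniquely_labeled_untouched(self):
        t = parse_newick("((a,b),(c,d));")
        net = fold(t, delta=0.0)
        assert net.is_tree()
        assert len(net.leaves()) == 4

    def test_code_equality_merges_mirrored_clades(self):
        t = parse_newick("((x,(a,b)),(y,(b,a)));")
        net = fold(t, delta=0.0)
        assert len(net.reticulations()) == 1
        retic = net.reticulations()[0]
        below = sorted(l.label for l in _net_leaves_below(retic))
        assert below == ["a", "b"]

    def test_delta_gates_clade_level_merge(self):
        t = parse_newick("((x,(a,(b,c))),(y,((a,b),c)));")
        assert len(fold(t, delta=0.0).reticulations()) == 3
        assert len(fold(t, delta=0.3).reticulations()) == 1

    def test_leaf_label_conservation(self, rng):
        for _ in range(5):
            net = make_random_network(rng, "abcdef", 2)
            t = unfold(net)
            folded = fold(t, delta=0.0)
            assert sorted(l.label for l in folded.leaves()) == \
                sorted(t.leaf_multiset().support())

    def test_roundtrip_random_networks(self, rng):
        for k in (1, 2, 3):
            for _ in range(5):
                net = make_random_network(rng, "abcdefgh", k)
                refolded = fold(unfold(net), delta=0.0)
                assert network_distance(net, refolded) == 0.0

    def test_structural_invariants(self, rng):
        net = make_random_network(rng, "abcdef", 2)
        folded = fold(unfold(net), delta=0.0)
        folded.validate()  # acyclic, retic out-degree 1, unique leaves

    def test_delta_out_of_range(self):
        t = parse_newick("((a,b),(a,b));")
        with pytest.raises(ValueError):
            fold(t, delta=1.5)

    def test_score_selects_representative(self):
        # two near-isomorphic clades; the better-supported one must survive
        t = parse_newick("(((a,(b,c)),x),(((a,b),c),y));")
        s = ClusterFrequencyMap({(Multiset("ab"), 1): 9})
        net = fold(t, delta=0.5, s=s)
        retics = net.reticulations()
        assert len(retics) == 1
        kept = retics[0].children[0]
        # representative contains the (a,b) cherry that the score rewards
        labels = [sorted(ch.label for ch in n.children if ch.label)
                  for n in _net_internal_below(kept)]
        assert ["a", "b"] in labels

    def test_binarize_option(self):
        t = parse_newick("((a,b),(a,b),(a,b));")
        net = fold(t, delta=0.0, binarize=True)
        for r in net.reticulations():
            assert len(r.parents) == 2


def _net_leaves_below(node):
    out = []
    stack = [node]
    seen = set()
    while stack:
        n = stack.pop()
        if id(n) in seen:
            continue
        seen.add(id(n))
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _net_internal_below(node):
    out = []
    stack = [node]
    seen = set()
    while stack:
        n = stack.pop()
        if id(n) in seen:
            continue
        seen.add(id(n))
        if not n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


class TestDeltaMonotonicity:
    def test_reticulation_count_non_increasing(self, rng):
        # empirical sanity check on discordant MUL-trees
        from mulnet.simulate import MSCModel, preset_scenario, simulate_gene_trees
        from mulnet.consensus import build_consensus
        net, model = preset_scenario("D", "moderate")
        genes = simulate_gene_trees(model, 100, seed=11)
        tree, freq = build_consensus(genes)
        counts = [len(fold(tree, delta=d, s=freq).reticulations())
                  for d in (0.0, 0.3)]
        assert counts[1] <= counts[0]
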