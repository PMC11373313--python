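"""Dissimilarity measures between MUL-trees and between networks.

- ``multree_distance``: normalized graph edit distance on whole trees (same
  cost model as the folding module).
- ``network_distance``: nodes are labeled by their path-multiplicity vector
  (number of directed paths to each leaf label); the distance is the size of
  the multiset symmetric difference of node labels over |V1| + |V2|.
- ``rooted_rf``: symmetric difference of the nontrivial clade-cluster
  censuses, counted with multiplicity, over both census sizes.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Tuple

from .folding import DEFAULT_GED_EXACT_CAP, normalized_ged
from .phylo import Multiset, NetNode, PhyloNetwork, RootedMULTree

__all__ = [
    "multree_distance",
    "network_distance",
    "rooted_rf",
    "path_multiplicity_labels",
]


def multree_distance(t1: RootedMULTree, t2: RootedMULTree,
                     exact_cap: int = DEFAULT_GED_EXACT_CAP) -> float:
    """Normalized GED between whole trees; 0 iff isomorphic in exact mode."""
    return normalized_ged(t1.root, t2.root, exact_cap=exact_cap)


def path_multiplicity_labels(network: PhyloNetwork) -> Counter:
    """Multiset of per-node path-count vectors (tuples over sorted taxa)."""
    taxa = sorted(leaf.label for leaf in network.leaves())
    index = {t: i for i, t in enumerate(taxa)}
    vectors: Dict[int, Tuple[int, ...]] = {}

    def vec(node: NetNode) -> Tuple[int, ...]:
        if id(node) in vectors:
            return vectors[id(node)]
        if node.is_leaf:
            v = tuple(1 if i == index[node.label] else 0 for i in range(len(taxa)))
        else:
            acc = [0] * len(taxa)
            for child in node.children:  # parallel edges count twice
                cv = vec(child)
                for i, x in enumerate(cv):
                    acc[i] += x
            v = tuple(acc)
        vectors[id(node)] = v
        return v

    return Counter(vec(n) for n in network.nodes())


def network_distance(n1: PhyloNetwork, n2: PhyloNetwork) -> float:
    """Path-multiplicity label distance in [0, 1]; 0 for isomorphic networks."""
    taxa1 = sorted(leaf.label for leaf in n1.leaves())
    taxa2 = sorted(leaf.label for leaf in n2.leaves())
    if taxa1 != taxa2:
        raise ValueError(f"taxon sets differ: {taxa1} vs {taxa2}")
    l1 = path_multiplicity_labels(n1)
    l2 = path_multiplicity_labels(n2)
    sym_diff = sum(((l1 - l2) + (l2 - l1)).values())
    total = sum(l1.values()) + sum(l2.values())
    return sym_diff / total if total else 0.0


def _nontrivial_census(tree: RootedMULTree) -> Counter:
    census: Counter = Counter()
    below: Dict[int, Multiset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = Multiset([node.label])
            continue
        acc = Multiset()
        for c in node.children:
            acc = acc + below[id(c)]
        below[id(node)] = acc
        if node is not tree.root:
            census[acc] += 1
    return census


def rooted_rf(t1: RootedMULTree, t2: RootedMULTree) -> float:
    """Normalized rooted Robinson-Foulds on cluster multisets."""
    if t1.leaf_multiset() != t2.leaf_multiset():
        raise ValueError("leaf multisets differ")
    c1, c2 = _nontrivial_census(t1), _nontrivial_census(t2)
    total = sum(c1.values()) + sum(c2.values())
    if total == 0:
        return 0.0
    sym_diff = sum(((c1 - c2) + (c2 - c1)).values())
    return sym_diff / total
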