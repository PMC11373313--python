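"""Multispecies-coalescent simulation on species MUL-trees, plus random
topology generators for testing.

Gene trees are sampled lineage-by-lineage on the (unfolded) species MUL-tree
with branch lengths in coalescent units: within each species branch, the k
current lineages coalesce pairwise at rate k(k-1)/2 until the branch is
exhausted; survivors above the root coalesce without bound. Subgenome copies
are independent lineage sources sharing a taxon label, so sampled gene trees
are multilabeled. Gene-tree estimation error is emulated by random rooted
NNI moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .phylo import (Multiset, NetNode, PhyloNetwork, RootedMULTree, TreeNode,
                    parse_enewick, unfold)

__all__ = [
    "MSCModel",
    "simulate_gene_trees",
    "perturb_nni",
    "preset_scenario",
    "PRESET_NAMES",
    "ILS_LEVELS",
    "random_binary_multree",
    "random_network",
    "scale_branch_lengths",
]

log = logging.getLogger(__name__)


@dataclass
class MSCModel:
    """Species MUL-tree with coalescent-unit branch lengths."""

    species_multree: RootedMULTree
    samples_per_leaf: int = 1

    def __post_init__(self) -> None:
        for node in self.species_multree.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")
        if self.samples_per_leaf < 1:
            raise ValueError("samples_per_leaf must be >= 1")

    def leaf_multiset(self) -> Multiset:
        return self.species_multree.leaf_multiset().scaled(self.samples_per_leaf)


def _coalesce_in_branch(lineages: List[TreeNode], t_start: float,
                        duration: Optional[float],
                        rng: np.random.Generator,
                        times: Dict[int, float]) -> Tuple[List[TreeNode], float]:
    """Coalesce at rate C(k,2) for `duration` (None = until one lineage)."""
    t = t_start
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if duration is not None and t + wait > t_start + duration:
            t = t_start + duration
            break
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = TreeNode()
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        times[id(parent)] = t
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(parent)
    else:
        if duration is not None:
            t = t_start + duration
    return lineages, t


def simulate_gene_trees(model: MSCModel, n: int, seed: int) -> List[RootedMULTree]:
    """Sample n gene trees under the MSC; deterministic given seed.

    Gene i uses the independent substream ``default_rng([seed, i])`` so
    per-gene reproducibility survives reordering.
    """
    species = model.species_multree
    # species-node entry times (time before present measured from leaves = 0)
    entry: Dict[int, float] = {}
    for node in species.postorder():
        if node.is_leaf:
            entry[id(node)] = 0.0
        else:
            entry[id(node)] = max(
                entry[id(c)] + (c.length if c.length is not None else 0.0)
                for c in node.children)

    out: List[RootedMULTree] = []
    for gene in range(n):
        rng = np.random.default_rng([seed, gene])
        times: Dict[int, float] = {}

        def sim(node: TreeNode) -> List[TreeNode]:
            if node.is_leaf:
                lineages = []
                for _ in range(model.samples_per_leaf):
                    tip = TreeNode(label=node.label)
                    times[id(tip)] = 0.0
                    lineages.append(tip)
            else:
                lineages = []
                for c in node.children:
                    lineages.extend(sim(c))
            duration = node.length if node.parent is not None else None
            survivors, _ = _coalesce_in_branch(
                lineages, entry[id(node)], duration, rng, times)
            return survivors

        roots = sim(species.root)
        assert len(roots) == 1
        root = roots[0]
        for v in root.preorder():
            if v.parent is not None:
                v.length = times[id(v.parent)] - times[id(v)]
        out.append(RootedMULTree(root))
    return out


def perturb_nni(tree: RootedMULTree, k: int, seed: int) -> RootedMULTree:
    """Apply k uniformly-chosen rooted NNI moves to a copy of the tree."""
    if k < 0:
        raise ValueError("k must be >= 0")
    result = tree.copy()
    if k == 0:
        return result
    if not result.is_binary():
        raise ValueError("NNI requires a binary tree")
    rng = np.random.default_rng(seed)
    for _ in range(k):
        candidates = [v for v in result.preorder()
                      if v.parent is not None and not v.is_leaf]
        if not candidates:
            raise ValueError("tree too small for NNI")
        v = candidates[int(rng.integers(len(candidates)))]
        u = v.parent
        c = v.children[int(rng.integers(2))]
        siblings = [x for x in u.children if x is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        vi, ui = v.children.index(c), u.children.index(s)
        v.children[vi], u.children[ui] = s, c
        s.parent, c.parent = v, u
    return result


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

# 5-taxon scenarios with 1-3 reticulations, and a 13-taxon 3-reticulation
# scenario. Branch lengths are in coalescent units; internal branches near 1
# give moderate discordance and are rescaled per ILS level.
_PRESETS: Dict[str, str] = {
    "D": "((((B:1,(E:1)#H1:1):1,(C:1,#H1:1):1):1,D:3):1,A:4);",
    "E": "((((B:1,(E:1)#H1:1):1,(C:1,#H1:1):1):2,(D:1)#H2:1):1,(A:3,#H2:2):1);",
    "F": ("(((((A:1,(B:1)#H1:1):1,C:2):1,(D:1)#H2:1):1,(E:3)#H3:1):1,"
          "((#H1:1,#H2:1):1,#H3:2):1);"),
    "J": ("(((((B:1,(E:1)#H1:1):1,(C:1,#H1:1):1):1,"
          "((F:1,(G:1)#H2:1):1,(H:1,#H2:1):1):1):1,"
          "(((I:1,(J:1)#H3:1):1,(K:1,#H3:1):1):1,L:4):1):1,"
          "(D:5,(M:4,A:4):1):1);"),
}

# Scale factors for internal branches, calibrated so that the mean
# species-vs-gene-tree rooted RF lands near 0 / ~0.15 / ~0.4.
ILS_LEVELS: Dict[str, float] = {"low": 8.0, "moderate": 1.4, "high": 0.6}

PRESET_NAMES = tuple(sorted(_PRESETS))


def scale_branch_lengths(tree: RootedMULTree, factor: float) -> None:
    for node in tree.preorder():
        if node.length is not None:
            node.length *= factor


def preset_scenario(name: str, ils_level: str = "moderate",
                    seed: int = 0) -> Tuple[PhyloNetwork, MSCModel]:
    """Ground-truth network and its unfolded MSC model for a named scenario."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {', '.join(PRESET_NAMES)}")
    if ils_level not in ILS_LEVELS:
        raise ValueError(
            f"unknown ILS level {ils_level!r}; options: {', '.join(sorted(ILS_LEVELS))}")
    network = parse_enewick(_PRESETS[name])
    multree = unfold(network)
    scale_branch_lengths(multree, ILS_LEVELS[ils_level])
    log.info("preset %s at %s ILS: %d taxa, %d reticulations, scale %.2f",
             name, ils_level, len(network.leaves()), len(network.reticulations()),
             ILS_LEVELS[ils_level])
    return network, MSCModel(multree)


# ---------------------------------------------------------------------------
# Random topology generators (testing / validation)
# ---------------------------------------------------------------------------

def random_binary_multree(rng: np.random.Generator, labels: Sequence[str],
                          max_copies: int = 1) -> RootedMULTree:
    """Random binary MUL-tree; each label gets 1..max_copies leaf copies."""
    leaves: List[TreeNode] = []
    for label in labels:
        copies = 1 if max_copies == 1 else int(rng.integers(1, max_copies + 1))
        leaves.extend(TreeNode(label=label) for _ in range(copies))
    if len(leaves) == 1:
        return RootedMULTree(leaves[0])
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = TreeNode()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return RootedMULTree(nodes[0])


def _net_subtree_ids(node: NetNode) -> set:
    seen = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if id(n) in seen:
            continue
        seen.add(id(n))
        stack.extend(n.children)
    return seen


def random_network(rng: np.random.Generator, labels: Sequence[str],
                   n_reticulations: int) -> PhyloNetwork:
    """Random network whose reticulation subtrees are pairwise non-nested.

    Built by adding second parents to disjoint clades of a random binary
    tree, so that both parents of every reticulation subtend identical
    subtrees after unfolding — the class on which folding at delta=0 is an
    exact inverse of unfolding.
    """
    base = random_binary_multree(rng, labels, max_copies=1)

    def to_net(node: TreeNode) -> NetNode:
        net = NetNode(label=node.label)
        for c in node.children:
            child = to_net(c)
            net.children.append(child)
            child.parents.append(net)
        return net

    root = to_net(base.root)
    all_nodes = [n for n in _iter_net(root)]
    non_root = [n for n in all_nodes if n.parents]
    rng.shuffle(non_root)
    chosen: List[NetNode] = []
    blocked: set = set()
    for cand in non_root:
        sub = _net_subtree_ids(cand)
        if id(cand) in blocked or (sub & {id(c) for c in chosen}):
            continue
        if any(id(c) in sub for c in chosen):
            continue
        chosen.append(cand)
        blocked |= sub
        if len(chosen) == n_reticulations:
            break

    retics: List[NetNode] = []
    forbidden: set = set()
    for c in chosen:
        forbidden |= _net_subtree_ids(c)
    for c in chosen:
        p = c.parents[0]
        r = NetNode()
        p.children[p.children.index(c)] = r
        r.parents.append(p)
        r.children.append(c)
        c.parents = [r]
        retics.append(r)
    retic_ids = {id(r) for r in retics}
    for r in retics:
        edges = [(x, y) for x in _iter_net(root) for y in x.children
                 if id(y) not in forbidden and id(y) not in retic_ids]
        if not edges:
            raise ValueError("no attachment edge available")
        x, y = edges[int(rng.integers(len(edges)))]
        z = NetNode()
        x.children[x.children.index(y)] = z
        z.parents.append(x)
        z.children.append(y)
        y.parents[y.parents.index(x)] = z
        z.children.append(r)
        r.parents.append(z)

    net = PhyloNetwork(root)
    net.validate()
    return net


def _iter_net(root: NetNode):
    seen = set()
    stack = [root]
    while stack:
        n = stack.pop()
        if id(n) in seen:
            continue
        seen.add(id(n))
        yield n
        stack.extend(n.children)
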