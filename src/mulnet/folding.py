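"""Folding a MUL-tree into a phylogenetic network.

Clades are compared bottom-up-canonical isomorphism codes first, then (when
codes differ but clusters agree) by normalized graph edit distance against a
near-isomorphism threshold delta. Processing runs root-height downward over
per-height FIFO queues; each batch of near-isomorphic clades is merged into
the representative with the highest gene-tree-supported score, under a new
reticulation node. Parallel edges into a reticulation are permitted (they
arise when two merged clades share a parent) and are what make
fold(unfold(N)) invert exactly.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

from .clusters import ClusterFrequencyMap, clade_clusters
from .phylo import (Multiset, NetNode, PhyloNetwork, RootedMULTree, TreeNode,
                    node_heights)

__all__ = [
    "assign_codes",
    "normalized_ged",
    "are_near_isomorphic",
    "compute_clade_score",
    "fold",
    "binarize_reticulations",
    "DEFAULT_DELTA",
    "DEFAULT_GED_EXACT_CAP",
]

log = logging.getLogger(__name__)

DEFAULT_DELTA = 0.3
DEFAULT_GED_EXACT_CAP = 12


def assign_codes(tree: RootedMULTree) -> Dict[TreeNode, str]:
    """Canonical code per node: equal codes iff clades are isomorphic."""
    codes: Dict[TreeNode, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            codes[node] = node.label
        else:
            codes[node] = "(" + ",".join(sorted(codes[c] for c in node.children)) + ")"
    return codes


def _clade_graph(node: TreeNode) -> Tuple[nx.DiGraph, int]:
    g = nx.DiGraph()
    counter = [0]

    def add(n: TreeNode) -> int:
        idx = counter[0]
        counter[0] += 1
        g.add_node(idx, label=n.label)
        for c in n.children:
            cidx = add(c)
            g.add_edge(idx, cidx)
        return idx

    root = add(node)
    return g, root


def _unit_node_subst(a, b) -> float:
    return 0.0 if a.get("label") == b.get("label") else 1.0


def normalized_ged(
    clade1: TreeNode,
    clade2: TreeNode,
    exact_cap: int = DEFAULT_GED_EXACT_CAP,
) -> float:
    """Graph edit distance, unit costs, normalized to [0, 1].

    Node substitution costs 1 when leaf labels differ (internal nodes are
    unlabeled, cost 0); inserts/deletes of nodes and edges cost 1. The
    denominator |V1|+|E1|+|V2|+|E2| is the cost of deleting one clade and
    inserting the other. Exact A* search up to ``exact_cap`` nodes per clade;
    beyond that, the first solution of the anytime optimizer (an upper
    bound).
    """
    g1, r1 = _clade_graph(clade1)
    g2, r2 = _clade_graph(clade2)
    denom = g1.number_of_nodes() + g1.number_of_edges() \
        + g2.number_of_nodes() + g2.number_of_edges()
    if denom == 0:
        return 0.0
    kwargs = dict(node_subst_cost=_unit_node_subst, roots=(r1, r2))
    if max(g1.number_of_nodes(), g2.number_of_nodes()) <= exact_cap:
        dist = nx.graph_edit_distance(g1, g2, **kwargs)
    else:
        dist = next(nx.optimize_graph_edit_distance(g1, g2,
                                                    node_subst_cost=_unit_node_subst))
    return min(1.0, dist / denom)


def clade_cluster(node: TreeNode) -> Multiset:
    return Multiset(leaf.label for leaf in node.leaves())


def are_near_isomorphic(
    u: TreeNode,
    v: TreeNode,
    delta: float,
    codes: Optional[Dict[TreeNode, str]] = None,
    exact_cap: int = DEFAULT_GED_EXACT_CAP,
) -> bool:
    """Same-cluster gate, then exact code match, then GED within delta."""
    if clade_cluster(u) != clade_cluster(v):
        return False
    if codes is not None and codes.get(u) is not None and codes[u] == codes[v]:
        return True
    if codes is None:
        cu, cv = assign_codes(RootedMULTree(u)), assign_codes(RootedMULTree(v))
        if cu[u] == cv[v]:
            return True
    if delta <= 0:
        return False
    return normalized_ged(u, v, exact_cap=exact_cap) <= delta


def compute_clade_score(node: TreeNode, s: ClusterFrequencyMap) -> float:
    """Doubled-multiplicity support score over the clade's cluster census.

    Per (C, m) in the census: 2*m*s(C, 2m), falling back to m*s(C, m) when
    that is zero.
    """
    total = 0.0
    for cluster, m in clade_clusters(node):
        score = 2 * m * s.get(cluster, 2 * m)
        if score == 0:
            score = m * s.get(cluster, m)
        total += score
    return total


def _mirror_tree(tree: RootedMULTree) -> Tuple[NetNode, Dict[int, TreeNode]]:
    """NetNode copy of the tree plus a map back to the source clades."""
    back: Dict[int, TreeNode] = {}

    def rec(node: TreeNode) -> NetNode:
        net = NetNode(label=node.label, name=node.name)
        back[id(net)] = node
        for c in node.children:
            child = rec(c)
            net.children.append(child)
            child.parents.append(net)
        return net

    return rec(tree.root), back


def fold(
    tree: RootedMULTree,
    delta: float = DEFAULT_DELTA,
    s: Optional[ClusterFrequencyMap] = None,
    exact_cap: int = DEFAULT_GED_EXACT_CAP,
    binarize: bool = False,
) -> PhyloNetwork:
    """Merge near-isomorphic equal-cluster clades into reticulations.

    Heights are fixed from the input tree; queues are processed from the root
    height down to the leaves. In every batch the clade with the highest
    score is the representative (later discovery order wins ties); the
    others are pruned and their parent edges redirected onto a fresh
    reticulation above the representative. Children of pruned clades are
    never enqueued.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    if s is None:
        s = ClusterFrequencyMap()

    heights = node_heights(tree)
    codes = assign_codes(tree)
    clusters: Dict[TreeNode, Multiset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clusters[node] = Multiset([node.label])
        else:
            acc = Multiset()
            for c in node.children:
                acc = acc + clusters[c]
            clusters[node] = acc

    root_net, back = _mirror_tree(tree)
    H = heights[tree.root]
    queues: List[deque] = [deque() for _ in range(H + 1)]
    queues[H].append(root_net)

    def near(u: NetNode, v: NetNode) -> bool:
        tu, tv = back[id(u)], back[id(v)]
        if clusters[tu] != clusters[tv]:
            return False
        if codes[tu] == codes[tv]:
            return True
        if delta <= 0:
            return False
        d = normalized_ged(tu, tv, exact_cap=exact_cap)
        log.debug("GED(%s, %s) = %.4f (delta=%.2f)", codes[tu], codes[tv], d, delta)
        return d <= delta

    for h in range(H, -1, -1):
        D = queues[h]
        while D:
            u = D.popleft()
            batch: List[NetNode] = []
            survivors = deque()
            for v in D:
                if near(u, v):
                    if not batch:
                        batch.append(u)
                    batch.append(v)
                else:
                    survivors.append(v)
            if batch:
                queues[h] = D = survivors
                rep = _merge(batch, s, back, heights, clusters, log_height=h)
                enqueue_from = rep
            else:
                enqueue_from = u
            for child in enqueue_from.children:
                queues[heights[back[id(child)]]].append(child)

    network = PhyloNetwork(root_net)
    if binarize:
        binarize_reticulations(network)
    network.validate()
    return network


def _merge(batch: List[NetNode], s: ClusterFrequencyMap,
           back: Dict[int, TreeNode], heights, clusters, log_height: int) -> NetNode:
    """Merge a batch of clades; return the representative clade root."""
    max_support = 0.0
    rep = None
    for v in batch:
        support = compute_clade_score(back[id(v)], s)
        if support >= max_support:
            max_support = support
            rep = v
    log.info("merge at height %d: %d clades, cluster %r, best score %.3g",
             log_height, len(batch), clusters[back[id(rep)]], max_support)

    reticulation = NetNode()
    parent = rep.parents[0]
    parent.children[parent.children.index(rep)] = reticulation
    reticulation.parents.append(parent)
    reticulation.children.append(rep)
    rep.parents = [reticulation]
    for v in batch:
        if v is rep:
            continue
        pv = v.parents[0]
        pv.children[pv.children.index(v)] = reticulation
        reticulation.parents.append(pv)
    return rep


def binarize_reticulations(network: PhyloNetwork) -> None:
    """Rewrite in-degree-k>2 reticulations as left-leaning binary chains."""
    for node in network.nodes():
        while len(node.parents) > 2:
            upper = NetNode()
            p1, p2 = node.parents[0], node.parents[1]
            for p in (p1, p2):
                p.children[p.children.index(node)] = upper
                upper.parents.append(p)
            upper.children.append(node)
            node.parents = [upper] + node.parents[2:]
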