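"""Greedy consensus MUL-tree construction from selected clusters.

Clusters are realized on *instances*: for a target multiset L, label x with
count k contributes distinguishable copies (x,1)..(x,k). A (cluster, m)
record is inserted by finding m pairwise-disjoint instance sets, each a
one-to-one instantiation of the cluster, all set-compatible (nested or
disjoint) with everything realized so far. The realized laminar family
defines the consensus tree; multifurcations are then resolved by
maximum-weight binary refinement. Instance identity is an internal device
and is erased on output.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .clusters import (ClusterFrequencyMap, ClusterRecord, compute_sorted_clusters,
                       filter_by_frequency, record_sort_key)
from .phylo import Multiset, RootedMULTree, TreeNode
from .selection import DEFAULT_ALPHA, build_graph, node_weight, solve_ilp

__all__ = [
    "Instance",
    "GrowingConsensus",
    "build_star",
    "try_insert_cluster",
    "build_consensus",
    "refine_node",
    "refine_tree",
    "infer_leaf_multiset",
    "DEFAULT_BACKTRACK_BUDGET",
]

log = logging.getLogger(__name__)

Instance = Tuple[str, int]  # (label, copy index starting at 1)

DEFAULT_BACKTRACK_BUDGET = 100_000


@dataclass
class GrowingConsensus:
    """A star tree over leaf instances, progressively grouped by clusters."""

    L: Multiset
    instances: Tuple[Instance, ...]
    accepted: List[Tuple[Multiset, int]] = field(default_factory=list)
    realization: Dict[Tuple[Multiset, int], List[FrozenSet[Instance]]] = field(
        default_factory=dict)
    sets: List[FrozenSet[Instance]] = field(default_factory=list)  # laminar

    @property
    def universe(self) -> FrozenSet[Instance]:
        return frozenset(self.instances)

    def tree(self) -> RootedMULTree:
        """Materialize the laminar family as a tree with bare leaf labels."""
        ordered = sorted(set(self.sets), key=lambda s: (-len(s), sorted(s)))
        nodes: Dict[FrozenSet[Instance], TreeNode] = {}
        root = TreeNode()
        universe = self.universe
        nodes[universe] = root

        def parent_set(s: FrozenSet[Instance]) -> FrozenSet[Instance]:
            best = universe
            for t in ordered:
                if t is not s and len(t) > len(s) and s < t and len(t) < len(best):
                    best = t
            return best

        for s in ordered:
            nodes[s] = TreeNode()
        for s in ordered:
            nodes[parent_set(s)].add_child(nodes[s])
        for inst in sorted(self.instances):
            owner = universe
            for t in ordered:
                if inst in t and len(t) < len(owner):
                    owner = t
            nodes[owner].add_child(TreeNode(label=inst[0]))
        return RootedMULTree(root)


def build_star(L: Multiset) -> GrowingConsensus:
    """Star tree: one leaf instance per element of L, counted with multiplicity."""
    if not L:
        raise ValueError("empty leaf multiset")
    instances = tuple((label, i + 1) for label, count in sorted(L.counts().items())
                      for i in range(count))
    return GrowingConsensus(L=L, instances=instances)


def _set_compatible(a: FrozenSet[Instance], b: FrozenSet[Instance]) -> bool:
    return a <= b or b <= a or not (a & b)


class _Budget:
    __slots__ = ("left",)

    def __init__(self, n: int):
        self.left = n

    def spend(self) -> bool:
        self.left -= 1
        return self.left >= 0


def try_insert_cluster(
    state: GrowingConsensus,
    record: ClusterRecord,
    budget: int = DEFAULT_BACKTRACK_BUDGET,
) -> bool:
    """Attempt to realize (cluster, multiplicity) on the growing tree.

    Searches, with backtracking capped at ``budget`` expansions, for
    ``multiplicity`` pairwise-disjoint instantiations of the cluster that are
    each nested-or-disjoint with every set already realized. On success the
    state is mutated and True returned; any failure leaves it untouched.
    """
    C, m = record.cluster, record.multiplicity
    if not C.scaled(m) <= state.L:
        raise ValueError(f"cluster {C!r} x{m} does not fit in L={state.L!r}")

    labels = C.support()
    need = C.counts()
    by_label: Dict[str, List[Instance]] = {}
    for inst in state.instances:
        by_label.setdefault(inst[0], []).append(inst)
    existing = state.sets
    budget_ctr = _Budget(budget)

    def ancestor_depth(group: FrozenSet[Instance]) -> int:
        # number of accepted sets containing the whole group: deeper shared
        # ancestry ranks higher in the search order
        return sum(1 for s in existing if group <= s)

    def choose_for_label(pool: Sequence[Instance], count: int,
                         partial: FrozenSet[Instance]) -> List[Tuple[Instance, ...]]:
        if partial:
            ranked = sorted(pool, key=lambda x: (-ancestor_depth(partial | {x}), x))
        else:
            ranked = sorted(pool)
        return list(itertools.combinations(ranked, count))

    solutions: List[FrozenSet[Instance]] = []

    def build_instantiation(label_idx: int, chosen: FrozenSet[Instance],
                            used: FrozenSet[Instance]) -> Optional[FrozenSet[Instance]]:
        if not budget_ctr.spend():
            return None
        if label_idx == len(labels):
            for s in existing:
                if not _set_compatible(chosen, s):
                    return None
            return chosen
        label = labels[label_idx]
        pool = [x for x in by_label.get(label, ()) if x not in used and x not in chosen]
        count = need[label]
        if len(pool) < count:
            return None
        for combo in choose_for_label(pool, count, chosen):
            result = build_instantiation(label_idx + 1, chosen | set(combo), used)
            if result is not None:
                return result
            if budget_ctr.left < 0:
                return None
        return None

    def search(k: int, used: FrozenSet[Instance]) -> bool:
        if k == m:
            return True
        inst_set = build_instantiation(0, frozenset(), used)
        if inst_set is None:
            return False
        solutions.append(inst_set)
        if search(k + 1, used | inst_set):
            return True
        solutions.pop()
        # try alternatives for this instantiation by excluding the failed one:
        # exhaustive alternative enumeration is bounded by the budget
        return _search_alternatives(k, used, {inst_set})

    def _search_alternatives(k: int, used: FrozenSet[Instance],
                             tried: set) -> bool:
        while budget_ctr.left > 0:
            alt = _next_instantiation(used, tried)
            if alt is None:
                return False
            solutions.append(alt)
            if search(k + 1, used | alt):
                return True
            solutions.pop()
            tried.add(alt)
        return False

    def _next_instantiation(used: FrozenSet[Instance], tried: set
                            ) -> Optional[FrozenSet[Instance]]:
        # exhaustive product over per-label combinations, skipping tried sets
        pools = []
        for label in labels:
            pool = [x for x in by_label.get(label, ()) if x not in used]
            combos = list(itertools.combinations(sorted(pool), need[label]))
            if not combos:
                return None
            pools.append(combos)
        for parts in itertools.product(*pools):
            if not budget_ctr.spend():
                return None
            cand = frozenset(itertools.chain.from_iterable(parts))
            if cand in tried:
                continue
            if all(_set_compatible(cand, s) for s in existing):
                return cand
        return None

    ok = search(0, frozenset())
    if not ok:
        if budget_ctr.left < 0:
            log.info("insertion budget exhausted for %r x%d", C, m)
        return False
    for s in solutions:
        if s not in state.sets and 1 < len(s) < len(state.instances):
            state.sets.append(s)
    state.accepted.append((C, m))
    state.realization[(C, m)] = list(solutions)
    return True


def _instantiations(C: Multiset, by_label: Dict[str, List[Instance]],
                    family: List[FrozenSet[Instance]], forbidden: FrozenSet[Instance],
                    budget: _Budget):
    """Lazily enumerate instance sets realizing C, compatible with `family`.

    ``forbidden`` holds instances claimed by sibling copies of the same
    record (copies must be pairwise disjoint).
    """
    pools = []
    for label, count in sorted(C.counts().items()):
        pool = [x for x in by_label.get(label, ()) if x not in forbidden]
        if len(pool) < count:
            return
        pools.append(list(itertools.combinations(sorted(pool), count)))
    for parts in itertools.product(*pools):
        if not budget.spend():
            return
        cand = frozenset(itertools.chain.from_iterable(parts))
        if all(_set_compatible(cand, s) for s in family):
            yield cand


def realize_all(
    records: Sequence[Tuple[Multiset, int]],
    L: Multiset,
    instances: Tuple[Instance, ...],
    budget: int = DEFAULT_BACKTRACK_BUDGET,
) -> Optional[Dict[Tuple[Multiset, int], List[FrozenSet[Instance]]]]:
    """Joint realization of a cluster collection on L, or None.

    Full backtracking across records (largest clusters first), so an
    unfortunate instantiation of one record can be revised when a later
    record needs it — the cross-record search that incremental insertion
    lacks. Bounded by ``budget`` expansions.
    """
    by_label: Dict[str, List[Instance]] = {}
    for inst in instances:
        by_label.setdefault(inst[0], []).append(inst)
    order = sorted(set(records), key=lambda cm: (-len(cm[0]), cm[0].sort_key(), cm[1]))
    budget_ctr = _Budget(budget)
    family: List[FrozenSet[Instance]] = []
    realization: Dict[Tuple[Multiset, int], List[FrozenSet[Instance]]] = {}

    def place(idx: int) -> bool:
        if idx == len(order):
            return True
        C, m = order[idx]
        chosen: List[FrozenSet[Instance]] = []

        def copies(k: int, forbidden: FrozenSet[Instance]) -> bool:
            if budget_ctr.left < 0:
                return False
            if k == m:
                realization[(C, m)] = list(chosen)
                family.extend(chosen)
                if place(idx + 1):
                    return True
                del family[len(family) - len(chosen):]
                realization.pop((C, m), None)
                return False
            for inst_set in _instantiations(C, by_label, family + chosen,
                                            forbidden, budget_ctr):
                # canonical copy order kills permutation symmetry
                if chosen and sorted(inst_set) <= sorted(chosen[-1]):
                    continue
                chosen.append(inst_set)
                if copies(k + 1, forbidden | inst_set):
                    return True
                chosen.pop()
            return False

        return copies(0, frozenset())

    if place(0):
        return realization
    return None


# ---------------------------------------------------------------------------
# Refinement of multifurcations
# ---------------------------------------------------------------------------

def _binary_shapes(k: int):
    """All rooted binary shapes over leaves 0..k-1 as nested pairs.

    The first shape yielded is the left-to-right caterpillar, which therefore
    wins all-zero-weight ties under strict-improvement scanning.
    """
    def insertions(shape, leaf):
        yield (shape, leaf)
        if isinstance(shape, tuple):
            l, r = shape
            for s in insertions(l, leaf):
                yield (s, r)
            for s in insertions(r, leaf):
                yield (l, s)

    def rec(n):
        if n == 1:
            yield 0
            return
        if n == 2:
            yield (0, 1)
            return
        for s in rec(n - 1):
            yield from insertions(s, n - 1)

    yield from rec(k)


EXHAUSTIVE_REFINE_CAP = 6


def _cluster_weight_lookup(records: Sequence[ClusterRecord], alpha: float
                           ) -> Dict[Multiset, float]:
    out: Dict[Multiset, float] = {}
    for r in records:
        w = node_weight(r, alpha)
        if w > out.get(r.cluster, 0.0):
            out[r.cluster] = w
    return out


def refine_node(node: TreeNode, records: Sequence[ClusterRecord],
                alpha: float = DEFAULT_ALPHA) -> None:
    """Resolve one multifurcation into the maximum-weight binary subtree.

    Exhaustive over all (2d-3)!! shapes for degree d <= 6, greedy pairwise
    agglomeration beyond; the weight of a grouping is the best node weight of
    its induced cluster among ``records`` (0 if unseen).
    """
    d = len(node.children)
    if d < 3:
        return
    lookup = _cluster_weight_lookup(records, alpha)
    children = list(node.children)
    child_clusters = [Multiset(leaf.label for leaf in c.leaves()) for c in children]

    def group_weight(cluster: Multiset) -> float:
        return lookup.get(cluster, 0.0)

    if d <= EXHAUSTIVE_REFINE_CAP:
        best_shape, best_score = None, -1.0
        for shape in _binary_shapes(d):
            score = 0.0

            def walk(s) -> Multiset:
                nonlocal score
                if isinstance(s, int):
                    return child_clusters[s]
                left, right = walk(s[0]), walk(s[1])
                union = left + right
                if len(union) < sum(len(c) for c in child_clusters):
                    score += group_weight(union)
                return union

            walk(shape)
            if score > best_score:
                best_shape, best_score = shape, score

        def build(s) -> TreeNode:
            if isinstance(s, int):
                return children[s]
            new = TreeNode()
            new.add_child(build(s[0]))
            new.add_child(build(s[1]))
            return new

        resolved = build(best_shape)
    else:
        groups: List[Tuple[Multiset, TreeNode]] = list(zip(child_clusters, children))
        while len(groups) > 2:
            best = None
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    union = groups[i][0] + groups[j][0]
                    cand = (-group_weight(union), union.sort_key(), i, j)
                    if best is None or cand < best:
                        best = cand
            _, _, i, j = best
            ci, ni = groups[i]
            cj, nj = groups[j]
            merged = TreeNode()
            merged.add_child(ni)
            merged.add_child(nj)
            groups = ([g for k, g in enumerate(groups) if k not in (i, j)]
                      + [(ci + cj, merged)])
        resolved = TreeNode()
        for _, n in groups:
            resolved.add_child(n)

    node.children = []
    if resolved.is_leaf or resolved.label is not None:
        node.add_child(resolved)  # cannot happen for d >= 3; defensive
    else:
        for c in resolved.children:
            node.add_child(c)


def refine_tree(tree: RootedMULTree, records: Sequence[ClusterRecord],
                alpha: float = DEFAULT_ALPHA) -> None:
    """Refine every multifurcating node, bottom-up."""
    for node in list(tree.postorder()):
        if len(node.children) > 2:
            refine_node(node, records, alpha)


# ---------------------------------------------------------------------------
# Full pipeline: census -> ILP selection -> greedy insertion -> refinement
# ---------------------------------------------------------------------------

def infer_leaf_multiset(gene_trees: Sequence[RootedMULTree]) -> Multiset:
    """Default target multiset: per-label maximum multiplicity over all trees."""
    maxima: Dict[str, int] = {}
    for t in gene_trees:
        for label, count in t.leaf_multiset().counts().items():
            maxima[label] = max(maxima.get(label, 0), count)
    return Multiset(maxima)


def build_consensus(
    gene_trees: Sequence[RootedMULTree],
    L: Optional[Multiset] = None,
    alpha: float = DEFAULT_ALPHA,
    tau: int = 1,
    symmetric: bool = True,
    time_limit: Optional[float] = None,
    budget: int = DEFAULT_BACKTRACK_BUDGET,
    report: Optional[dict] = None,
) -> Tuple[RootedMULTree, ClusterFrequencyMap]:
    """Consensus MUL-tree on L from a gene-tree collection.

    Pipeline: cluster census, frequency filter at ``tau``, compatibility
    graph, exact ILP selection, greedy insertion in sorted order, then
    maximum-weight binary refinement of multifurcations (against the full
    filtered census, not only the ILP selection).
    """
    trees = list(gene_trees)
    if not trees:
        raise ValueError("no gene trees")
    records, freq = compute_sorted_clusters(trees)
    if L is None:
        L = infer_leaf_multiset(trees)
    filtered = filter_by_frequency(records, tau)
    graph = build_graph(filtered, L, alpha=alpha, symmetric=symmetric)
    solution = solve_ilp(graph, time_limit=time_limit)
    selected = sorted((graph.records[i] for i in solution.selected),
                      key=record_sort_key)
    state = build_star(L)
    inserted = 0
    for rec in selected:
        if try_insert_cluster(state, rec, budget=budget):
            inserted += 1
            continue
        # incremental insertion can wedge itself on an unlucky earlier
        # instantiation; retry with a joint search over everything accepted
        attempt = state.accepted + [(rec.cluster, rec.multiplicity)]
        realization = realize_all(attempt, L, state.instances, budget=budget)
        if realization is not None:
            state.accepted = list(attempt)
            state.realization = realization
            state.sets = [s for sets in realization.values() for s in sets
                          if 1 < len(s) < len(state.instances)]
            inserted += 1
    tree = state.tree()
    refine_tree(tree, filtered, alpha)
    if report is not None:
        report.update(
            n_gene_trees=len(trees),
            n_records=len(records),
            n_filtered=len(filtered),
            n_graph_vertices=graph.n,
            ilp_objective=solution.total_weight,
            n_selected=len(solution.selected),
            n_inserted=inserted,
        )
    return tree, freq
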