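"""Maximum-weight selection of approximately compatible clusters.

Two (cluster, multiplicity) records drawn from a target label multiset L are
*approximately compatible* when one base cluster contains the other, or when
removing all copies of one from L still leaves room for all copies of the
other. Selecting a maximum-weight mutually-compatible subset — at most one
multiplicity per base cluster — is a maximum-weight clique problem, solved
here exactly as an ILP (HiGHS via scipy), with an exhaustive oracle for
cross-validation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .clusters import ClusterRecord
from .phylo import Multiset

__all__ = [
    "CompatibilityGraph",
    "Solution",
    "approx_compatible",
    "node_weight",
    "build_graph",
    "solve_ilp",
    "solve_bruteforce",
    "verify_solution",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.65


def node_weight(record: ClusterRecord, alpha: float = DEFAULT_ALPHA) -> float:
    """w = multiplicity * frequency * |cluster|**alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return record.multiplicity * record.frequency * len(record.cluster) ** alpha


def approx_compatible(
    r1: ClusterRecord,
    r2: ClusterRecord,
    L: Multiset,
    symmetric: bool = True,
) -> bool:
    """Approximate-compatibility test on a target multiset L.

    Conditions: C1 <= C2, C1 >= C2 (bare base clusters), or
    L - m1*C1 >= m2*C2. The last condition is directional as written; by
    default it is evaluated in both directions so the relation is symmetric
    (set ``symmetric=False`` for the strict one-directional reading).
    """
    c1, m1 = r1.cluster, r1.multiplicity
    c2, m2 = r2.cluster, r2.multiplicity
    for c, m in ((c1, m1), (c2, m2)):
        if not c.scaled(m) <= L:
            raise ValueError(f"cluster {c!r} x{m} does not fit in L={L!r}")
    if c1 <= c2 or c2 <= c1:
        return True
    if c2.scaled(m2) <= L - c1.scaled(m1):
        return True
    if symmetric and c1.scaled(m1) <= L - c2.scaled(m2):
        return True
    return False


@dataclass
class CompatibilityGraph:
    """Weighted graph over cluster records with compatibility edges.

    ``groups`` partitions vertex indices by base cluster (constraint: at most
    one multiplicity per base cluster may be selected).
    """

    records: List[ClusterRecord]
    weights: np.ndarray
    adjacency: np.ndarray  # symmetric boolean, irreflexive
    groups: List[List[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.records)
        self.weights = np.asarray(self.weights, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not self.groups:
            by_cluster: Dict[Multiset, List[int]] = {}
            for i, r in enumerate(self.records):
                by_cluster.setdefault(r.cluster, []).append(i)
            self.groups = list(by_cluster.values())

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Solution:
    selected: Tuple[int, ...]
    total_weight: float


def build_graph(
    records: Sequence[ClusterRecord],
    L: Multiset,
    alpha: float = DEFAULT_ALPHA,
    symmetric: bool = True,
) -> CompatibilityGraph:
    """One vertex per record that fits in L; edges by pairwise compatibility.

    Records whose scaled cluster does not fit inside L are dropped with a
    warning rather than rejected.
    """
    kept: List[ClusterRecord] = []
    for r in records:
        if r.cluster.scaled(r.multiplicity) <= L:
            kept.append(r)
        else:
            log.warning("dropping record %r x%d: does not fit in L", r.cluster,
                        r.multiplicity)
    n = len(kept)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if approx_compatible(kept[i], kept[j], L, symmetric=symmetric):
                adj[i, j] = adj[j, i] = True
    weights = np.array([node_weight(r, alpha) for r in kept])
    return CompatibilityGraph(kept, weights, adj)


def _feasible(graph: CompatibilityGraph, subset: Sequence[int]) -> bool:
    for i, j in itertools.combinations(subset, 2):
        if not graph.adjacency[i, j]:
            return False
    chosen = set(subset)
    for group in graph.groups:
        if len(chosen.intersection(group)) > 1:
            return False
    return True


def solve_ilp(graph: CompatibilityGraph, time_limit: Optional[float] = None) -> Solution:
    """Exact maximum-weight selection via mixed-integer programming.

    Binary x_k per vertex; maximize sum w_k x_k subject to at most one vertex
    per base-cluster group and x_i + x_j <= 1 for every non-edge.
    """
    n = graph.n
    if n == 0:
        return Solution((), 0.0)
    rows: List[np.ndarray] = []
    for group in graph.groups:
        if len(group) > 1:
            row = np.zeros(n)
            row[list(group)] = 1.0
            rows.append(row)
    nonedges = [(i, j) for i in range(n) for j in range(i + 1, n)
                if not graph.adjacency[i, j]]
    for i, j in nonedges:
        row = np.zeros(n)
        row[i] = row[j] = 1.0
        rows.append(row)
    constraints = []
    if rows:
        A = csr_matrix(np.vstack(rows))
        constraints.append(LinearConstraint(A, -np.inf, 1.0))
    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=-graph.weights,
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
        constraints=constraints,
        options=options,
    )
    if not res.success:
        raise RuntimeError(f"ILP solver failed: {res.message} (status {res.status})")
    selected = tuple(int(i) for i in np.flatnonzero(np.round(res.x) > 0.5))
    return Solution(selected, float(graph.weights[list(selected)].sum()))


BRUTEFORCE_CAP = 20


def solve_bruteforce(graph: CompatibilityGraph) -> Solution:
    """Exhaustive oracle over all feasible subsets (<= 20 vertices).

    Bitmask enumeration of every subset; fully independent of the ILP path.
    Ties among maximum-weight subsets break toward the lexicographically
    smallest selected index tuple.
    """
    n = graph.n
    if n > BRUTEFORCE_CAP:
        raise ValueError(f"brute force capped at {BRUTEFORCE_CAP} vertices, got {n}")
    adj_masks = [0] * n
    for i in range(n):
        for j in range(n):
            if graph.adjacency[i, j]:
                adj_masks[i] |= 1 << j
    group_masks = []
    for group in graph.groups:
        gm = 0
        for i in group:
            gm |= 1 << i
        group_masks.append(gm)
    weights = [float(w) for w in graph.weights]

    best_w = 0.0
    best_subset: Tuple[int, ...] = ()
    for mask in range(1, 1 << n):
        ok = True
        for gm in group_masks:
            if (mask & gm).bit_count() > 1:
                ok = False
                break
        if not ok:
            continue
        m = mask
        w = 0.0
        subset = []
        while m:
            i = (m & -m).bit_length() - 1
            if (mask & ~(1 << i)) & ~adj_masks[i]:
                ok = False
                break
            w += weights[i]
            subset.append(i)
            m &= m - 1
        if not ok:
            continue
        if w > best_w + 1e-12:
            best_w, best_subset = w, tuple(subset)
        elif abs(w - best_w) <= 1e-12 and best_subset and tuple(subset) < best_subset:
            best_subset = tuple(subset)
    return Solution(best_subset, best_w)


def verify_solution(graph: CompatibilityGraph, solution: Solution) -> bool:
    """Post-hoc feasibility check, independent of any solver."""
    return _feasible(graph, solution.selected)
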