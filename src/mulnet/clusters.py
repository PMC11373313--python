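"""Cluster census of gene-tree collections.

A *cluster* is the multiset of leaf labels below an internal node. Within one
tree the same cluster may be induced by several nodes (its *multiplicity*);
across the collection, the *frequency* of a (cluster, multiplicity) pair is
the number of trees whose census contains that cluster at exactly that
multiplicity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .phylo import Multiset, RootedMULTree, TreeNode

__all__ = [
    "ClusterRecord",
    "ClusterFrequencyMap",
    "clusters_of_tree",
    "clade_clusters",
    "compute_sorted_clusters",
    "filter_by_frequency",
    "record_sort_key",
    "write_cluster_table",
]


@dataclass(frozen=True)
class ClusterRecord:
    """A (cluster, multiplicity) pair with its cross-tree frequency."""

    cluster: Multiset
    multiplicity: int
    frequency: int

    def key(self) -> Tuple[Multiset, int]:
        return (self.cluster, self.multiplicity)


class ClusterFrequencyMap:
    """Lookup of frequencies keyed by (cluster, multiplicity); absent -> 0."""

    def __init__(self, entries: Dict[Tuple[Multiset, int], int] | None = None):
        self._entries: Dict[Tuple[Multiset, int], int] = dict(entries or {})

    def get(self, cluster: Multiset, multiplicity: int) -> int:
        return self._entries.get((cluster, multiplicity), 0)

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)


def clade_clusters(node: TreeNode) -> List[Tuple[Multiset, int]]:
    """(cluster, multiplicity) census over the internal nodes of a clade.

    The clade root itself counts as internal (unless it is a leaf); leaves
    never contribute (their singleton clusters are trivial).
    """
    below: Dict[int, Multiset] = {}
    counts: Dict[Multiset, int] = {}
    for n in node.postorder():
        if n.is_leaf:
            below[id(n)] = Multiset([n.label])
        else:
            acc = Multiset()
            for c in n.children:
                acc = acc + below[id(c)]
            below[id(n)] = acc
            counts[acc] = counts.get(acc, 0) + 1
    return list(counts.items())


def clusters_of_tree(tree: RootedMULTree) -> List[Tuple[Multiset, int]]:
    """Per-tree census: one entry per distinct internal-node cluster."""
    return clade_clusters(tree.root)


def record_sort_key(record: ClusterRecord) -> Tuple:
    """Descending frequency, then multiplicity, then size; ascending labels."""
    return (-record.frequency, -record.multiplicity, -len(record.cluster),
            record.cluster.sort_key())


def compute_sorted_clusters(
    gene_trees: Iterable[RootedMULTree],
) -> Tuple[List[ClusterRecord], ClusterFrequencyMap]:
    """Census the whole collection; exact-multiplicity frequency semantics.

    A tree contributes to the frequency of (C, m) only when C appears in it
    exactly m times.
    """
    trees = list(gene_trees)
    if not trees:
        raise ValueError("empty gene-tree collection")
    freq: Dict[Tuple[Multiset, int], int] = {}
    for tree in trees:
        for cluster, mult in clusters_of_tree(tree):
            key = (cluster, mult)
            freq[key] = freq.get(key, 0) + 1
    records = [ClusterRecord(c, m, s) for (c, m), s in freq.items()]
    records.sort(key=record_sort_key)
    return records, ClusterFrequencyMap(freq)


def filter_by_frequency(records: List[ClusterRecord], tau: int) -> List[ClusterRecord]:
    """Keep records with frequency >= tau, preserving order."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    return [r for r in records if r.frequency >= tau]


def write_cluster_table(records: List[ClusterRecord], alpha: float = 0.65) -> str:
    """TSV of the sorted cluster table: cluster, multiplicity, frequency, weight."""
    from .selection import node_weight

    out = io.StringIO()
    out.write("cluster\tmultiplicity\tfrequency\tweight\n")
    for r in records:
        labels = ",".join(r.cluster)
        out.write(f"{labels}\t{r.multiplicity}\t{r.frequency}\t{node_weight(r, alpha):.6g}\n")
    return out.getvalue()
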