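"""Core phylogeny data model: multisets, MUL-trees, networks, Newick I/O.

Trees may be *multilabeled* (several leaves carrying the same taxon label);
uniquely-labeled trees are the special case where every label count is 1.
Networks are rooted DAGs whose reticulation nodes (in-degree >= 2) have
out-degree exactly 1 and whose leaves are uniquely labeled.

Branch lengths are carried through parsing, writing and unfolding but are
ignored by every inference operation; only the simulator consumes them.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "Multiset",
    "TreeNode",
    "RootedMULTree",
    "NetNode",
    "PhyloNetwork",
    "NewickError",
    "parse_newick",
    "write_newick",
    "parse_enewick",
    "write_enewick",
    "node_heights",
    "unfold",
    "validate_label",
]

_FORBIDDEN = set(" \t\n,();:#")


def validate_label(name: str) -> str:
    """Check a taxon label for Newick-hostile characters; return it."""
    if not name:
        raise ValueError("empty taxon label")
    bad = _FORBIDDEN.intersection(name)
    if bad:
        raise ValueError(f"label {name!r} contains forbidden characters {sorted(bad)}")
    return name


class Multiset:
    """Immutable, hashable multiset of taxon labels.

    Supports the multiset arithmetic needed by approximate compatibility:
    containment (``<=``), floored subtraction (``-``) and scalar
    multiplication (``m * C`` as ``C.scaled(m)``).
    """

    __slots__ = ("_items", "_size", "_hash")

    def __init__(self, items: Iterable[str] | Dict[str, int] = ()):  # noqa: D107
        counts: Dict[str, int] = {}
        if isinstance(items, dict):
            for k, v in items.items():
                if v < 0:
                    raise ValueError("negative multiplicity")
                if v:
                    counts[k] = counts.get(k, 0) + int(v)
        else:
            for k in items:
                counts[k] = counts.get(k, 0) + 1
        self._items: Tuple[Tuple[str, int], ...] = tuple(sorted(counts.items()))
        self._size = sum(c for _, c in self._items)
        self._hash = hash(self._items)

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return self._size

    def __bool__(self) -> bool:
        return self._size > 0

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Multiset) and self._items == other._items

    def __iter__(self) -> Iterator[str]:
        for label, count in self._items:
            for _ in range(count):
                yield label

    def __repr__(self) -> str:
        inner = ",".join(f"{l}:{c}" if c > 1 else l for l, c in self._items)
        return "{" + inner + "}"

    # -- queries --------------------------------------------------------
    def count(self, label: str) -> int:
        for l, c in self._items:
            if l == label:
                return c
        return 0

    def counts(self) -> Dict[str, int]:
        return dict(self._items)

    def support(self) -> Tuple[str, ...]:
        return tuple(l for l, _ in self._items)

    def sort_key(self) -> Tuple[str, ...]:
        """Lexicographic key: the sorted label sequence with multiplicity."""
        return tuple(self)

    # -- multiset algebra -----------------------------------------------
    def __le__(self, other: "Multiset") -> bool:
        """Multiset containment: every label's count here <= count there."""
        theirs = dict(other._items)
        return all(theirs.get(l, 0) >= c for l, c in self._items)

    def __ge__(self, other: "Multiset") -> bool:
        return other.__le__(self)

    def __sub__(self, other: "Multiset") -> "Multiset":
        """Floored multiset difference."""
        theirs = dict(other._items)
        return Multiset({l: c - theirs.get(l, 0) for l, c in self._items
                         if c - theirs.get(l, 0) > 0})

    def __add__(self, other: "Multiset") -> "Multiset":
        merged = dict(self._items)
        for l, c in other._items:
            merged[l] = merged.get(l, 0) + c
        return Multiset(merged)

    def scaled(self, m: int) -> "Multiset":
        """m disjoint copies of this multiset, as one multiset."""
        if m < 0:
            raise ValueError("negative scale")
        return Multiset({l: c * m for l, c in self._items})

    def disjoint(self, other: "Multiset") -> bool:
        theirs = dict(other._items)
        return all(l not in theirs for l, _ in self._items)


# ---------------------------------------------------------------------------
# MUL-trees
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted (possibly multilabeled) tree."""

    __slots__ = ("parent", "children", "label", "length", "name")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None,
                 name: Optional[str] = None):
        self.parent: Optional[TreeNode] = None
        self.children: List[TreeNode] = []
        self.label = label          # taxon label; leaves only
        self.length = length        # branch length to parent, optional
        self.name = name            # internal node name, cosmetic

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: List[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class RootedMULTree:
    """Rooted tree whose leaves carry possibly-repeated taxon labels."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def leaves(self) -> List[TreeNode]:
        return self.root.leaves()

    def internal_nodes(self) -> List[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def leaf_multiset(self) -> Multiset:
        return Multiset(leaf.label for leaf in self.leaves())

    def is_uniquely_labeled(self) -> bool:
        return all(c == 1 for c in self.leaf_multiset().counts().values())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def validate(self) -> None:
        for node in self.preorder():
            if node.is_leaf and node.label is None:
                raise ValueError("unlabeled leaf")
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("broken parent pointer")
        if self.root.parent is not None:
            raise ValueError("root has a parent")

    def copy(self) -> "RootedMULTree":
        def dup(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length, node.name)
            for child in node.children:
                new.add_child(dup(child))
            return new
        return RootedMULTree(dup(self.root))

    def __repr__(self) -> str:
        return f"RootedMULTree({write_newick(self)!r})"


def node_heights(tree: RootedMULTree) -> Dict[TreeNode, int]:
    """Topological height: 0 at leaves, 1 + max over children elsewhere."""
    heights: Dict[TreeNode, int] = {}
    for node in tree.postorder():
        heights[node] = 0 if node.is_leaf else 1 + max(heights[c] for c in node.children)
    return heights


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

class NewickError(ValueError):
    """Parse error carrying the character offset where it was detected."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class _Scanner:
    """Shared cursor for the recursive-descent Newick/eNewick parsers."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def advance(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def skip_ws(self) -> None:
        while self.peek() and self.peek() in " \t\r\n":
            self.pos += 1
        # bracketed comments are ignored wholesale
        while self.peek() == "[":
            start = self.pos
            while self.peek() not in ("]", ""):
                self.pos += 1
            if self.peek() != "]":
                raise NewickError("unterminated comment", start)
            self.pos += 1
            while self.peek() and self.peek() in " \t\r\n":
                self.pos += 1

    def read_label(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in ",():;[ \t\r\n":
            self.pos += 1
        return self.text[start:self.pos], start

    def read_length(self) -> Optional[float]:
        self.skip_ws()
        if self.peek() != ":":
            return None
        self.advance()
        start = self.pos
        if not self.peek():
            raise NewickError("missing branch length after ':'", start)
        while self.peek() and self.peek() in "0123456789.eE+-":
            self.pos += 1
        raw = self.text[start:self.pos]
        try:
            return float(raw)
        except ValueError:
            raise NewickError(f"bad branch length {raw!r}", start) from None


def parse_newick(text: str) -> RootedMULTree:
    """Parse one rooted Newick expression (repeated leaf labels allowed)."""
    sc = _Scanner(text)

    def subtree() -> TreeNode:
        sc.skip_ws()
        node = TreeNode()
        if sc.peek() == "(":
            open_at = sc.pos
            sc.advance()
            while True:
                node.add_child(subtree())
                sc.skip_ws()
                ch = sc.peek()
                if ch == ",":
                    sc.advance()
                elif ch == ")":
                    sc.advance()
                    break
                else:
                    raise NewickError("unbalanced parentheses", open_at)
            sc.skip_ws()
            name, _ = sc.read_label()
            if name:
                node.name = name
        else:
            label, at = sc.read_label()
            if not label:
                raise NewickError("empty label", at)
            node.label = validate_label(label)
        node.length = sc.read_length()
        return node

    sc.skip_ws()
    root = subtree()
    sc.skip_ws()
    if sc.peek() != ";":
        raise NewickError("expected ';'", sc.pos)
    sc.advance()
    sc.skip_ws()
    if sc.pos != len(text):
        raise NewickError("trailing content after ';'", sc.pos)
    tree = RootedMULTree(root)
    tree.validate()
    return tree


def write_newick(tree: RootedMULTree, lengths: bool = True) -> str:
    """Serialize; children in stored order, branch lengths iff present."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            out = node.label or ""
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                out += node.name
        if lengths and node.length is not None:
            out += f":{node.length:g}"
        return out

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Phylogenetic networks (rooted DAGs with reticulations)
# ---------------------------------------------------------------------------

class NetNode:
    """Node of a rooted phylogenetic network.

    Edge lengths, when present, live on the child keyed by parent (a
    reticulation's two incoming edges may differ in length).
    """

    __slots__ = ("parents", "children", "label", "name", "edge_lengths")

    def __init__(self, label: Optional[str] = None, name: Optional[str] = None):
        self.parents: List[NetNode] = []
        self.children: List[NetNode] = []
        self.label = label
        self.name = name
        self.edge_lengths: Dict[int, float] = {}  # id(parent) -> length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_reticulation(self) -> bool:
        return len(self.parents) >= 2

    def length_from(self, parent: "NetNode") -> Optional[float]:
        return self.edge_lengths.get(id(parent))


class PhyloNetwork:
    """Rooted DAG; reticulation nodes have in-degree >= 2 and out-degree 1."""

    def __init__(self, root: NetNode):
        self.root = root

    def nodes(self) -> List[NetNode]:
        seen: Dict[int, NetNode] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen[id(node)] = node
            stack.extend(node.children)
        return list(seen.values())

    def edges(self) -> List[Tuple[NetNode, NetNode]]:
        return [(n, c) for n in self.nodes() for c in n.children]

    def leaves(self) -> List[NetNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def reticulations(self) -> List[NetNode]:
        return [n for n in self.nodes() if n.is_reticulation]

    def validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels are not unique")
        if any(l is None for l in labels):
            raise ValueError("unlabeled leaf")
        for node in self.nodes():
            for child in node.children:
                if node not in child.parents:
                    raise ValueError("asymmetric edge record")
            if node.is_reticulation and len(node.children) != 1:
                raise ValueError("reticulation with out-degree != 1")
        # acyclicity: DAG check by DFS colors
        WHITE, GRAY, BLACK = 0, 1, 2
        color: Dict[int, int] = {}

        def dfs(node: NetNode) -> None:
            color[id(node)] = GRAY
            for child in node.children:
                st = color.get(id(child), WHITE)
                if st == GRAY:
                    raise ValueError("cycle detected")
                if st == WHITE:
                    dfs(child)
            color[id(node)] = BLACK

        dfs(self.root)

    def is_tree(self) -> bool:
        return not self.reticulations()


def _connect(parent: NetNode, child: NetNode, length: Optional[float] = None) -> None:
    parent.children.append(child)
    child.parents.append(parent)
    if length is not None:
        child.edge_lengths[id(parent)] = length


_HYBRID_MARK = "#"


def parse_enewick(text: str) -> PhyloNetwork:
    """Parse extended Newick with ``#H<k>`` hybrid tags.

    The reticulation's subtree is written at exactly one occurrence (the
    definition); every other occurrence is a bare tag reference.
    """
    sc = _Scanner(text)
    by_tag: Dict[str, NetNode] = {}
    defined: Dict[str, bool] = {}  # tag -> has a defining occurrence

    def subtree() -> Tuple[NetNode, Optional[float]]:
        sc.skip_ws()
        children: List[Tuple[NetNode, Optional[float]]] = []
        has_children = False
        open_at = sc.pos
        if sc.peek() == "(":
            has_children = True
            sc.advance()
            while True:
                children.append(subtree())
                sc.skip_ws()
                ch = sc.peek()
                if ch == ",":
                    sc.advance()
                elif ch == ")":
                    sc.advance()
                    break
                else:
                    raise NewickError("unbalanced parentheses", open_at)
        sc.skip_ws()
        raw, at = sc.read_label()
        tag = None
        label = raw
        if _HYBRID_MARK in raw:
            label, _, tag = raw.partition(_HYBRID_MARK)
            if not tag:
                raise NewickError("empty hybrid tag", at)
        length = sc.read_length()

        if tag is not None:
            node = by_tag.get(tag)
            if node is None:
                node = NetNode()
                by_tag[tag] = node
                defined[tag] = False
            if has_children or label:
                if defined[tag]:
                    raise NewickError(f"hybrid tag #{tag} defined twice", at)
                defined[tag] = True
                if label:
                    node.label = validate_label(label)
        else:
            node = NetNode()
            if label:
                if has_children:
                    node.name = label
                else:
                    node.label = validate_label(label)
            elif not has_children:
                raise NewickError("empty label", at)

        for child, child_len in children:
            _connect(node, child, child_len)
        return node, length

    root, _ = subtree()
    sc.skip_ws()
    if sc.peek() != ";":
        raise NewickError("expected ';'", sc.pos)
    sc.advance()
    for tag, node in by_tag.items():
        if not defined[tag] and node.label is None and not node.children:
            raise NewickError(f"hybrid tag #{tag} referenced but never defined", 0)
    net = PhyloNetwork(root)
    net.validate()
    return net


def write_enewick(network: PhyloNetwork) -> str:
    """Serialize; each reticulation written in full once, then by tag."""
    tags: Dict[int, str] = {}
    next_tag = [1]
    written: set = set()

    def fmt(node: NetNode, parent: Optional[NetNode]) -> str:
        suffix = ""
        length = node.length_from(parent) if parent is not None else None
        if length is not None:
            suffix = f":{length:g}"
        if node.is_reticulation:
            if id(node) not in tags:
                tags[id(node)] = f"H{next_tag[0]}"
                next_tag[0] += 1
            tag = tags[id(node)]
            if id(node) in written:
                return f"#{tag}{suffix}"
            written.add(id(node))
            body = _body(node)
            return f"{body}#{tag}{suffix}"
        return _body(node) + suffix

    def _body(node: NetNode) -> str:
        if node.is_leaf:
            return node.label or ""
        inner = "(" + ",".join(fmt(c, node) for c in node.children) + ")"
        return inner + (node.label or node.name or "")

    return fmt(network.root, None) + ";"


def unfold(network: PhyloNetwork) -> RootedMULTree:
    """Expand every reticulation into independent copies of its subtree.

    The multiplicity of label x in the result equals the number of directed
    root-to-x paths in the network. Reticulation nodes themselves (out-degree
    1) are contracted; their incoming edge length is added to the edge below.
    """

    def expand(node: NetNode, length: Optional[float]) -> TreeNode:
        if node.is_reticulation:
            child = node.children[0]
            below = child.edge_lengths.get(id(node))
            combined = None
            if length is not None or below is not None:
                combined = (length or 0.0) + (below or 0.0)
            return expand(child, combined)
        new = TreeNode(node.label, length, node.name)
        for child in node.children:
            new.add_child(expand(child, child.length_from(node)))
        return new

    root = network.root
    if root.is_reticulation:
        raise ValueError("root cannot be a reticulation")
    return RootedMULTree(expand(root, None))
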