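"""Rooted phylogenetic trees: model, Newick I/O, canonical form, tree algebra.

Two representations are used throughout the package:

* :class:`PhyloTree` — a mutable, *unordered* rooted tree whose leaves carry
  positive-integer labels.  This is the editing surface: pruning, grafting and
  node suppression operate here.

* *shapes* — immutable nested tuples encoding a tree in **canonical form**: a
  leaf is its integer label, an internal node is the tuple of its children
  ordered ascending by *virtual label* (the minimum leaf label in the subtree).
  Two trees are isomorphic iff their canonical shapes are equal, which makes
  shapes hashable dictionary keys for the mining engine.  :class:`CanonicalTree`
  wraps a shape with cached traversal data (IDFT leaf sequence, rightmost leaf,
  rightmost-leaf-parent depth and child count).

Newick reading is delegated to dendropy; branch lengths, internal node labels
and comments are discarded on ingest, and unifurcations (including root
chains) are suppressed.  Taxon names are mapped to the integer universe
1..|L| through a :class:`LabelMap`.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional, Sequence, Union

import dendropy

from .errors import (
    DuplicateLeafError,
    InvalidTreeError,
    LeafNotFoundError,
    NewickParseError,
)

Shape = Union[int, tuple]

__all__ = [
    "Shape",
    "LabelMap",
    "Node",
    "PhyloTree",
    "CanonicalTree",
    "parse_newick",
    "tree_from_newick_ints",
    "write_newick",
    "read_collection",
    "write_collection_file",
    "canonicalize",
    "suppress_node",
    "prune_leaf",
    "graft_leaf",
    "idft_leaves",
    "prefix_tree",
    "heaviest_subtree",
    "restrict",
    "displays",
    "is_isomorphic",
    "shape_vlabel",
    "shape_leaves",
    "shape_leafset",
    "shape_nleaves",
    "shape_rightmost",
    "shape_prefix",
    "shape_newick",
    "restrict_shape",
    "displays_shape",
    "shape_rml_parent_info",
    "shape_sort_key",
]


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def shape_vlabel(shape: Shape) -> int:
    """Virtual label of a canonical shape: its minimum (= leftmost) leaf."""
    while isinstance(shape, tuple):
        shape = shape[0]
    return shape


def shape_leaves(shape: Shape) -> tuple[int, ...]:
    """Leaf labels in inorder depth-first (IDFT, left-to-right) order."""
    out: list[int] = []
    stack = [shape]
    while stack:
        s = stack.pop()
        if isinstance(s, tuple):
            stack.extend(reversed(s))
        else:
            out.append(s)
    return tuple(out)


def shape_leafset(shape: Shape) -> frozenset[int]:
    return frozenset(shape_leaves(shape))


def shape_nleaves(shape: Shape) -> int:
    return len(shape_leaves(shape))


def shape_rightmost(shape: Shape) -> int:
    """The last leaf of the IDFT: follow last children down."""
    while isinstance(shape, tuple):
        shape = shape[-1]
    return shape


def _sorted_children(children: Sequence[Shape]) -> tuple[Shape, ...]:
    keyed = sorted(children, key=shape_vlabel)
    for a, b in zip(keyed, keyed[1:]):
        if shape_vlabel(a) == shape_vlabel(b):
            # sibling leaf-descendant sets are disjoint, so this is unreachable
            # for a well-formed tree; it means a duplicated leaf label
            raise DuplicateLeafError(
                f"duplicate leaf label {shape_vlabel(a)} among siblings"
            )
    return tuple(keyed)


def restrict_shape(shape: Shape, keep: frozenset[int]) -> Optional[Shape]:
    """Canonical shape of the restriction to ``keep``; None if disjoint.

    The minimal homeomorphic subtree: leaves outside ``keep`` are removed,
    resulting single-child nodes are suppressed, and the root becomes the LCA
    of ``keep`` (single-child chains above it collapse automatically).
    """
    if isinstance(shape, int):
        return shape if shape in keep else None
    kids = []
    for c in shape:
        r = restrict_shape(c, keep)
        if r is not None:
            kids.append(r)
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return _sorted_children(kids)


def shape_prefix(shape: Shape) -> Shape:
    """Prune the rightmost (last IDFT) leaf; the result stays canonical."""
    if isinstance(shape, int):
        raise InvalidTreeError("prefix of a single leaf is undefined")
    last = shape[-1]
    if isinstance(last, int):
        rest = shape[:-1]
        return rest[0] if len(rest) == 1 else rest
    sub = shape_prefix(last)
    return shape[:-1] + (sub,)


def shape_heaviest(shape: Shape) -> Shape:
    """Subtree rooted at the parent of the rightmost leaf."""
    if isinstance(shape, int):
        raise InvalidTreeError("heaviest subtree of a single leaf is undefined")
    node = shape
    while isinstance(node[-1], tuple):
        node = node[-1]
    return node


def shape_rml_parent_info(shape: Shape) -> tuple[int, int]:
    """(depth, number of children) of the parent of the rightmost leaf."""
    if isinstance(shape, int):
        raise InvalidTreeError("single leaf has no rightmost-leaf parent")
    depth = 0
    node = shape
    while isinstance(node[-1], tuple):
        node = node[-1]
        depth += 1
    return depth, len(node)


def displays_shape(big: Shape, small: Shape) -> bool:
    """True iff the tree with canonical shape ``big`` displays ``small``."""
    small_leaves = shape_leafset(small)
    if not small_leaves <= shape_leafset(big):
        return False
    return restrict_shape(big, small_leaves) == small


def shape_newick(shape: Shape, int_to_name: Optional[dict[int, str]] = None) -> str:
    def render(s: Shape) -> str:
        if isinstance(s, int):
            return int_to_name[s] if int_to_name else str(s)
        return "(" + ",".join(render(c) for c in s) + ")"

    return render(shape) + ";"


def shape_sort_key(shape: Shape) -> str:
    """A deterministic total order over shapes (their integer Newick string)."""
    return shape_newick(shape)


# ---------------------------------------------------------------------------
# LabelMap
# ---------------------------------------------------------------------------

class LabelMap:
    """Bijection between taxon names and the integer label universe 1..|L|.

    Integers are assigned by lexicographic sort of the name set, so the
    mapping is deterministic given the names.  New names added later are
    sorted among themselves and appended after the existing range.
    """

    def __init__(self) -> None:
        self.name_to_int: dict[str, int] = {}
        self.int_to_name: dict[int, str] = {}

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "LabelMap":
        lm = cls()
        lm.extend(names)
        return lm

    def extend(self, names: Iterable[str]) -> None:
        new = sorted(set(names) - self.name_to_int.keys())
        start = len(self.name_to_int)
        for offset, name in enumerate(new, start=1):
            i = start + offset
            self.name_to_int[name] = i
            self.int_to_name[i] = name

    def __len__(self) -> int:
        return len(self.name_to_int)

    def __getitem__(self, name: str) -> int:
        return self.name_to_int[name]

    def to_tsv(self) -> str:
        lines = [f"{name}\t{i}" for name, i in sorted(self.name_to_int.items(), key=lambda kv: kv[1])]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "LabelMap":
        lm = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            name, i = line.split("\t")
            lm.name_to_int[name] = int(i)
            lm.int_to_name[int(i)] = name
        return lm


# ---------------------------------------------------------------------------
# mutable PhyloTree
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("label", "children", "parent")

    def __init__(self, label: Optional[int] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node leaf={self.label}>" if self.is_leaf else f"<Node {len(self.children)} children>"


class PhyloTree:
    """A mutable unordered rooted tree with integer-labeled leaves."""

    def __init__(self, root: Node):
        self.root = root

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_shape(cls, shape: Shape) -> "PhyloTree":
        def build(s: Shape) -> Node:
            if isinstance(s, int):
                return Node(s)
            n = Node()
            for c in s:
                n.add_child(build(c))
            return n

        return cls(build(shape))

    @classmethod
    def single_leaf(cls, label: int) -> "PhyloTree":
        return cls(Node(label))

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(n.label)
            for c in n.children:
                m.add_child(dup(c))
            return m

        return PhyloTree(dup(self.root))

    # -- queries -----------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def leaf_nodes(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def leaf_labels(self) -> frozenset[int]:
        return frozenset(n.label for n in self.leaf_nodes())

    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def find_leaf(self, label: int) -> Node:
        for n in self.iter_nodes():
            if n.is_leaf and n.label == label:
                return n
        raise LeafNotFoundError(f"leaf {label} not in tree")

    def validate(self) -> None:
        labels = [n.label for n in self.leaf_nodes()]
        if len(labels) != len(set(labels)):
            raise DuplicateLeafError("duplicate leaf labels")
        if any(lbl is None for lbl in labels):
            raise InvalidTreeError("unlabeled leaf")
        for n in self.iter_nodes():
            if n.children and len(n.children) < 2:
                raise InvalidTreeError("internal node with a single child")

    # -- edits -------------------------------------------------------------

    def suppress_node(self, node: Node) -> None:
        """Contract the edge above a single-child internal node."""
        if node is self.root:
            raise InvalidTreeError("cannot suppress the root")
        if len(node.children) != 1:
            raise InvalidTreeError("can only suppress a node with exactly one child")
        child = node.children[0]
        parent = node.parent
        assert parent is not None
        node.remove_child(child)
        parent.remove_child(node)
        parent.add_child(child)

    def prune_leaf(self, label: int) -> None:
        """Delete a leaf; suppress the parent if it drops to one child.

        A root left with a single child is deleted and its child becomes the
        new root.  A multifurcating parent just loses the leaf.
        """
        if self.n_leaves() < 2:
            raise InvalidTreeError("cannot prune the last leaf")
        leaf = self.find_leaf(label)
        parent = leaf.parent
        if parent is None:
            raise InvalidTreeError("cannot prune a root leaf")
        parent.remove_child(leaf)
        if len(parent.children) == 1:
            if parent is self.root:
                self.root = parent.children[0]
                self.root.parent = None
            else:
                self.suppress_node(parent)

    def graft_leaf(
        self,
        label: int,
        *,
        on_node: Optional[Node] = None,
        on_edge: Optional[Node] = None,
        on_top: bool = False,
    ) -> None:
        """Graft a new leaf: on a node, on the edge above ``on_edge``, or on
        top of the root (a new root with the old root and the leaf as
        children).  Exactly one attachment must be given."""
        if label in self.leaf_labels():
            raise DuplicateLeafError(f"leaf {label} already present")
        if sum(x is not None for x in (on_node, on_edge)) + int(on_top) != 1:
            raise InvalidTreeError("exactly one attachment point required")
        leaf = Node(label)
        if on_top:
            new_root = Node()
            new_root.add_child(self.root)
            new_root.add_child(leaf)
            self.root = new_root
        elif on_node is not None:
            if on_node.is_leaf:
                raise InvalidTreeError("cannot graft on a leaf node")
            on_node.add_child(leaf)
        else:
            assert on_edge is not None
            parent = on_edge.parent
            if parent is None:
                raise InvalidTreeError("no edge above the root; use on_top")
            mid = Node()
            parent.remove_child(on_edge)
            parent.add_child(mid)
            mid.add_child(on_edge)
            mid.add_child(leaf)


# ---------------------------------------------------------------------------
# CanonicalTree
# ---------------------------------------------------------------------------

class CanonicalTree:
    """Immutable canonical-form tree (shape + cached traversal data)."""

    __slots__ = ("shape", "_idft")

    def __init__(self, shape: Shape):
        self.shape = shape
        self._idft: Optional[tuple[int, ...]] = None

    # -- cached traversals -------------------------------------------------

    @property
    def idft(self) -> tuple[int, ...]:
        if self._idft is None:
            self._idft = shape_leaves(self.shape)
        return self._idft

    @property
    def rightmost(self) -> int:
        return self.idft[-1]

    @property
    def leaf_set(self) -> frozenset[int]:
        return frozenset(self.idft)

    @property
    def n_leaves(self) -> int:
        return len(self.idft)

    def rml_parent_info(self) -> tuple[int, int]:
        return shape_rml_parent_info(self.shape)

    # -- algebra -----------------------------------------------------------

    def prefix(self) -> "CanonicalTree":
        return CanonicalTree(shape_prefix(self.shape))

    def heaviest_subtree(self) -> "CanonicalTree":
        return CanonicalTree(shape_heaviest(self.shape))

    def restrict(self, labels: Iterable[int]) -> "CanonicalTree":
        keep = frozenset(labels)
        missing = keep - self.leaf_set
        if missing:
            raise LeafNotFoundError(f"labels {sorted(missing)} not in tree")
        out = restrict_shape(self.shape, keep)
        assert out is not None
        return CanonicalTree(out)

    def displays(self, other: "CanonicalTree") -> bool:
        return displays_shape(self.shape, other.shape)

    def newick(self, label_map: Optional[LabelMap] = None) -> str:
        return shape_newick(self.shape, label_map.int_to_name if label_map else None)

    def to_phylo(self) -> PhyloTree:
        return PhyloTree.from_shape(self.shape)

    # -- identity ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CanonicalTree) and self.shape == other.shape

    def __hash__(self) -> int:
        return hash(self.shape)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CanonicalTree({self.newick()!r})"


TreeLike = Union[PhyloTree, CanonicalTree, tuple, int]


def canonicalize(tree: TreeLike) -> CanonicalTree:
    """Canonical form: children ordered ascending by virtual label everywhere.

    Idempotent; preserves the isomorphism class; validates that every internal
    node has >= 2 children and that leaf labels are unique.
    """
    if isinstance(tree, CanonicalTree):
        return tree
    if isinstance(tree, (tuple, int)):
        tree = PhyloTree.from_shape(tree)

    seen: set[int] = set()

    def build(n: Node) -> Shape:
        if n.is_leaf:
            if n.label is None:
                raise InvalidTreeError("unlabeled leaf")
            if n.label in seen:
                raise DuplicateLeafError(f"duplicate leaf label {n.label}")
            seen.add(n.label)
            return n.label
        if len(n.children) < 2:
            raise InvalidTreeError("internal node with a single child")
        return _sorted_children([build(c) for c in n.children])

    return CanonicalTree(build(tree.root))


# ---------------------------------------------------------------------------
# module-level operation wrappers (functional surface of the tree algebra)
# ---------------------------------------------------------------------------

def suppress_node(tree: PhyloTree, node: Node) -> PhyloTree:
    tree.suppress_node(node)
    return tree


def prune_leaf(tree: TreeLike, label: int) -> CanonicalTree:
    """Prune a leaf and return the canonical result (input not mutated)."""
    ct = canonicalize(tree)
    if label not in ct.leaf_set:
        raise LeafNotFoundError(f"leaf {label} not in tree")
    if ct.n_leaves < 2:
        raise InvalidTreeError("cannot prune the last leaf")
    out = restrict_shape(ct.shape, ct.leaf_set - {label})
    assert out is not None
    return CanonicalTree(out)


def graft_leaf(
    tree: PhyloTree,
    label: int,
    *,
    on_node: Optional[Node] = None,
    on_edge: Optional[Node] = None,
    on_top: bool = False,
) -> PhyloTree:
    tree.graft_leaf(label, on_node=on_node, on_edge=on_edge, on_top=on_top)
    return tree


def idft_leaves(tree: TreeLike) -> tuple[int, ...]:
    return canonicalize(tree).idft


def prefix_tree(tree: TreeLike) -> CanonicalTree:
    return canonicalize(tree).prefix()


def heaviest_subtree(tree: TreeLike) -> CanonicalTree:
    return canonicalize(tree).heaviest_subtree()


def restrict(tree: TreeLike, labels: Iterable[int]) -> CanonicalTree:
    return canonicalize(tree).restrict(labels)


def displays(big: TreeLike, small: TreeLike) -> bool:
    return canonicalize(big).displays(canonicalize(small))


def is_isomorphic(t1: TreeLike, t2: TreeLike) -> bool:
    return canonicalize(t1).shape == canonicalize(t2).shape


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _dendropy_parse(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise DuplicateLeafError(str(exc)) from exc
        raise NewickParseError(str(exc)) from exc


def _convert(dtree: dendropy.Tree, name_to_int: dict[str, int]) -> PhyloTree:
    def build(dn) -> Node:
        kids = dn.child_nodes()
        if not kids:
            if dn.taxon is None or dn.taxon.label is None:
                raise InvalidTreeError("leaf without a taxon name")
            return Node(name_to_int[dn.taxon.label])
        if len(kids) == 1:
            # suppress unifurcations (including root chains) on ingest
            return build(kids[0])
        n = Node()
        for k in kids:
            n.add_child(build(k))
        return n

    tree = PhyloTree(build(dtree.seed_node))
    tree.validate()
    return tree


def _leaf_names(dtree: dendropy.Tree) -> list[str]:
    names = []
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise InvalidTreeError("leaf without a taxon name")
        names.append(leaf.taxon.label)
    if len(names) != len(set(names)):
        raise DuplicateLeafError("duplicate leaf name within one tree")
    return names


def parse_newick(text: str, label_map: Optional[LabelMap] = None) -> PhyloTree:
    """Parse one rooted Newick tree.

    Branch lengths, internal labels and comments are discarded; quoted labels
    are supported; the trailing semicolon is optional.  ``label_map`` is
    extended in place with unseen names (sorted among themselves, so the
    assignment is deterministic given the name set).
    """
    if label_map is None:
        label_map = LabelMap()
    dtree = _dendropy_parse(text)
    label_map.extend(_leaf_names(dtree))
    return _convert(dtree, label_map.name_to_int)


def tree_from_newick_ints(text: str) -> CanonicalTree:
    """Parse a Newick string whose leaf names are the integer labels themselves."""
    dtree = _dendropy_parse(text)
    names = _leaf_names(dtree)
    mapping = {name: int(name) for name in names}
    return canonicalize(_convert(dtree, mapping))


def write_newick(tree: TreeLike, label_map: Optional[LabelMap] = None) -> str:
    """Serialize in canonical child order; round-trips through parse_newick."""
    return canonicalize(tree).newick(label_map)


def read_collection(source: Union[str, io.TextIOBase, Iterable[str]]) -> tuple[list[PhyloTree], LabelMap]:
    """Read a newline-delimited Newick collection.

    The label map is built from the lexicographically sorted union of taxon
    names across the whole collection (two passes), so tree order does not
    affect the integer assignment.
    """
    if isinstance(source, str):
        lines = [ln for ln in source.splitlines() if ln.strip()]
    else:
        lines = [ln for ln in source if ln.strip()]
    if not lines:
        raise NewickParseError("empty tree collection")
    dtrees = [_dendropy_parse(ln) for ln in lines]
    label_map = LabelMap.from_names(
        name for dt in dtrees for name in _leaf_names(dt)
    )
    return [_convert(dt, label_map.name_to_int) for dt in dtrees], label_map


def write_collection_file(
    trees: Sequence[TreeLike], path: str, label_map: Optional[LabelMap] = None
) -> None:
    """Write newline-delimited Newick plus a ``<path>.labels.tsv`` sidecar."""
    if not trees:
        raise InvalidTreeError("refusing to write an empty collection")
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, label_map) + "\n")
    if label_map is not None:
        with open(path + ".labels.tsv", "w") as fh:
            fh.write(label_map.to_tsv())
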