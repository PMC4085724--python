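"""Pairwise joins: constant-time per-tree classification, support, construction.

Every (k)-leaf frequent subtree T corresponds to a unique ordered pair
(T_x, T_y) of (k-1)-leaf frequent subtrees sharing a common prefix: T_x and
T_y are obtained by pruning the last and second-to-last IDFT leaf of T.
Conversely the pair can combine in at most four ways ("join types"), and
which way a given input tree supports is decided from

* the topology the input tree displays on {r, x, y} — r the rightmost leaf of
  the common prefix, x and y the rightmost leaves of T_x and T_y — read from
  the precomputed LCA-depth table, and
* the depths of the rightmost-leaf parents *inside* T_x and T_y (stored with
  each frequent subtree, never recomputed from the input tree).

With a support threshold above m/2 at most one join type can reach the
threshold, so the joined tree on a given leaf set is unique when it exists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import JoinConsistencyError
from .lca_index import LcaDepthTable, SupportSet
from .trees import (
    CanonicalTree,
    Node,
    PhyloTree,
    canonicalize,
)

__all__ = [
    "JoinType",
    "FrequentSubtree",
    "JoinOutcome",
    "classify_join_in_tree",
    "join_support",
    "construct_join",
]


class JoinType(enum.IntEnum):
    NONE = 0
    TYPE1 = 1  # x and y become siblings under the same (kept) parent
    TYPE2 = 2  # x and y become a cherry one level below their shared depth
    TYPE3 = 3  # p_y becomes the parent of p_x
    TYPE4 = 4  # y attaches strictly above x on the rightmost path


@dataclass
class FrequentSubtree:
    """A canonical tree with its support and rightmost-leaf-parent metadata."""

    tree: CanonicalTree
    support: SupportSet
    depth_p_rml: int  # depth of the parent of the rightmost leaf, inside tree
    nchild_p_rml: int  # that parent's number of children
    rightmost: int

    @classmethod
    def from_tree(cls, tree: CanonicalTree, support: SupportSet) -> "FrequentSubtree":
        depth, nchild = tree.rml_parent_info()
        return cls(tree, support, depth, nchild, tree.rightmost)


@dataclass
class JoinOutcome:
    join_type: JoinType
    support: SupportSet
    joined: Optional[FrequentSubtree]

    @property
    def exists(self) -> bool:
        return self.join_type is not JoinType.NONE


def classify_join_in_tree(
    table: LcaDepthTable,
    r: int,
    x: int,
    y: int,
    depth_px: int,
    depth_py: int,
) -> JoinType:
    """Join type the given input tree supports for the ordered pair, assuming
    the tree displays both operands.

    ``depth_px``/``depth_py`` are the rightmost-leaf-parent depths inside T_x
    and T_y (not inside the input tree).  A tree lacking r, x or y cannot
    support the join and yields NONE.
    """
    if not table.has(r, x, y):
        return JoinType.NONE
    drx = table.lca_depth(r, x)
    dry = table.lca_depth(r, y)
    dxy = table.lca_depth(x, y)
    if depth_px == depth_py:
        if drx == dry == dxy:  # (r, x, y) star
            return JoinType.TYPE1 if x < y else JoinType.NONE
        if dxy > drx and drx == dry:  # (r, (x, y))
            return JoinType.TYPE2 if x < y else JoinType.NONE
        if drx > dry and dry == dxy:  # ((r, x), y)
            return JoinType.TYPE3
        return JoinType.NONE  # ((r, y), x): only joinable on the reversed pair
    if depth_px > depth_py:
        if drx > dry and dry == dxy:  # ((r, x), y)
            return JoinType.TYPE4
    # depth_py > depth_px: T_x cannot be the prefix of any join
    return JoinType.NONE


def join_support(
    Tx: FrequentSubtree,
    Ty: FrequentSubtree,
    r: int,
    tables: Sequence[LcaDepthTable],
    threshold: int,
) -> JoinOutcome:
    """Classify every tree in the support intersection and return the unique
    join type whose per-type support reaches the threshold (at most one can,
    since the threshold exceeds m/2).

    TYPE3 additionally requires the second operand's rightmost-leaf parent to
    have exactly two children; trees classified TYPE3 otherwise support no
    join of this ordered pair.
    """
    x, y = Tx.rightmost, Ty.rightmost
    dpx, dpy = Tx.depth_p_rml, Ty.depth_p_rml
    type3_ok = Ty.nchild_p_rml == 2
    inter = Tx.support & Ty.support
    m = inter.m
    if inter.count < threshold:
        return JoinOutcome(JoinType.NONE, SupportSet.empty(m), None)
    masks = [0, 0, 0, 0, 0]
    remaining = inter.count
    agreement_mode = threshold >= len(tables)  # f = 1: one dissent aborts
    for idx in inter.indices():
        jt = classify_join_in_tree(tables[idx], r, x, y, dpx, dpy)
        if jt is JoinType.TYPE3 and not type3_ok:
            jt = JoinType.NONE
        remaining -= 1
        if jt is JoinType.NONE:
            if agreement_mode:
                return JoinOutcome(JoinType.NONE, SupportSet.empty(m), None)
            continue
        masks[jt] |= 1 << idx
        if agreement_mode and masks[jt] != inter.mask & ((2 << idx) - 1):
            # a second distinct type appeared; no type can reach m
            return JoinOutcome(JoinType.NONE, SupportSet.empty(m), None)
    best = max(range(1, 5), key=lambda k: masks[k].bit_count())
    if masks[best].bit_count() < threshold:
        return JoinOutcome(JoinType.NONE, SupportSet.empty(m), None)
    jt = JoinType(best)
    support = SupportSet(masks[best], m)
    joined = construct_join(Tx, Ty, jt)
    return JoinOutcome(jt, support, FrequentSubtree.from_tree(joined, support))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _rightmost_path(tree: PhyloTree) -> list[Node]:
    """Root-to-rightmost-leaf path (last-child chain of the canonical order)."""
    path = [tree.root]
    while not path[-1].is_leaf:
        path.append(path[-1].children[-1])
    return path


def construct_join(Tx: FrequentSubtree, Ty: FrequentSubtree, jt: JoinType) -> CanonicalTree:
    """Build the joined canonical tree for a classified ordered pair.

    The construction grafts y into T_x relative to the rightmost path:

    * TYPE1 — y becomes a new child of p_x;
    * TYPE2 — y subdivides the edge (p_x, x), forming the cherry (x, y);
    * TYPE3 — y subdivides the edge entering p_x (a new root if p_x is the
      root), so the new node plays the role of p_y above p_x;
    * TYPE4 — y is attached to T_x exactly as it was attached to the shared
      core in T_y: as a child of the rightmost-path node at depth
      depth_p_rml(T_y) if that parent kept other children, else by
      subdividing the rightmost-path edge at that depth (grafting on top of
      the root when the depth is 0).

    The result is canonicalized and verified defensively: it must have T_x as
    its prefix, display T_y, and have y as its rightmost leaf.  A failure
    signals a classification bug, not bad input.
    """
    if jt is JoinType.NONE:
        raise JoinConsistencyError("cannot construct a NONE join")
    y = Ty.rightmost
    pt = Tx.tree.to_phylo()
    path = _rightmost_path(pt)
    x_leaf = path[-1]
    p_x = path[-2]

    if jt is JoinType.TYPE1:
        pt.graft_leaf(y, on_node=p_x)
    elif jt is JoinType.TYPE2:
        pt.graft_leaf(y, on_edge=x_leaf)
    elif jt is JoinType.TYPE3:
        if p_x is pt.root:
            pt.graft_leaf(y, on_top=True)
        else:
            pt.graft_leaf(y, on_edge=p_x)
    else:  # TYPE4
        dpy = Ty.depth_p_rml
        if Ty.nchild_p_rml >= 3:
            pt.graft_leaf(y, on_node=path[dpy])
        elif dpy == 0:
            pt.graft_leaf(y, on_top=True)
        else:
            pt.graft_leaf(y, on_edge=path[dpy])

    joined = canonicalize(pt)
    if (
        joined.rightmost != y
        or joined.prefix() != Tx.tree
        or not joined.displays(Ty.tree)
    ):
        raise JoinConsistencyError(
            f"{jt.name} join of {Tx.tree.newick()} and {Ty.tree.newick()} "
            f"produced {joined.newick()}, violating the join contract"
        )
    return joined
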