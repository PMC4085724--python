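"""Brute-force ground truth by exhaustive leaf-subset enumeration.

Deliberately naive: for every leaf subset S of the universe, each input tree
containing S is restricted to S and the canonical restrictions are tallied.
A topology reaching the support threshold on S is the (unique, for thresholds
above m/2) frequent subtree on S; maximality is then a pairwise display
filter.  This module is the independent test bed for the mining engine —
nothing in it shares code paths with the join/pruning machinery.

A guard refuses universes above 16 leaves, where 2^|L| enumeration stops
being honest desk-scale work.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

from .errors import ConfigError
from .joins import FrequentSubtree, JoinType
from .lca_index import SupportSet
from .trees import (
    CanonicalTree,
    Shape,
    TreeLike,
    canonicalize,
    displays_shape,
    restrict_shape,
    shape_leafset,
    shape_nleaves,
    shape_prefix,
    shape_rightmost,
    shape_sort_key,
)

__all__ = [
    "subtree_tallies",
    "brute_force_fsts",
    "brute_force_mfsts",
    "brute_force_masts",
    "reference_join_classify",
]

SUBSET_GUARD = 16


def _canon_collection(collection: Sequence[TreeLike]) -> list[CanonicalTree]:
    return [canonicalize(t) for t in collection]


def subtree_tallies(
    collection: Sequence[TreeLike],
    min_leaves: int = 3,
    max_leaves: Optional[int] = None,
) -> dict[frozenset[int], dict[Shape, int]]:
    """For every leaf subset, the map restriction-shape -> support bitmask.

    Computed once per collection and reusable across thresholds.
    """
    canon = _canon_collection(collection)
    universe = sorted(set().union(*(ct.leaf_set for ct in canon)))
    if len(universe) > SUBSET_GUARD:
        raise ConfigError(
            f"oracle refuses |L| = {len(universe)} > {SUBSET_GUARD} leaves"
        )
    top = len(universe) if max_leaves is None else min(max_leaves, len(universe))
    tallies: dict[frozenset[int], dict[Shape, int]] = {}
    for size in range(min_leaves, top + 1):
        for combo in combinations(universe, size):
            keep = frozenset(combo)
            per_shape: dict[Shape, int] = {}
            for idx, ct in enumerate(canon):
                if not keep <= ct.leaf_set:
                    continue
                shape = restrict_shape(ct.shape, keep)
                per_shape[shape] = per_shape.get(shape, 0) | (1 << idx)
            if per_shape:
                tallies[keep] = per_shape
    return tallies


def brute_force_fsts(
    collection: Sequence[TreeLike],
    threshold: int,
    min_leaves: int = 3,
    max_leaves: Optional[int] = None,
    tallies: Optional[dict[frozenset[int], dict[Shape, int]]] = None,
) -> dict[frozenset[int], tuple[Shape, SupportSet]]:
    """All frequent subtrees: leaf set -> (canonical shape, SupportSet)."""
    m = len(collection)
    if tallies is None:
        tallies = subtree_tallies(collection, min_leaves, max_leaves)
    out: dict[frozenset[int], tuple[Shape, SupportSet]] = {}
    for keep, per_shape in tallies.items():
        for shape, mask in per_shape.items():
            if mask.bit_count() >= threshold:
                out[keep] = (shape, SupportSet(mask, m))
                break
    return out


def brute_force_mfsts(
    fsts: dict[frozenset[int], tuple[Shape, SupportSet]],
) -> list[tuple[Shape, SupportSet]]:
    """Filter the FST map down to the display-maximal ones."""
    items = sorted(fsts.items(), key=lambda kv: (len(kv[0]), shape_sort_key(kv[1][0])))
    out = []
    for keep, (shape, sup) in items:
        dominated = any(
            keep < other_keep and restrict_shape(other_shape, keep) == shape
            for other_keep, (other_shape, _s) in fsts.items()
            if len(other_keep) > len(keep)
        )
        if not dominated:
            out.append((shape, sup))
    out.sort(key=lambda pair: (-shape_nleaves(pair[0]), shape_sort_key(pair[0])))
    return out


def brute_force_masts(collection: Sequence[TreeLike]) -> list[Shape]:
    """Maximum-cardinality agreement subtrees (threshold = m)."""
    m = len(collection)
    fsts = brute_force_fsts(collection, threshold=m)
    if not fsts:
        return []
    best = max(len(keep) for keep in fsts)
    shapes = [shape for keep, (shape, _s) in fsts.items() if len(keep) == best]
    shapes.sort(key=shape_sort_key)
    return shapes


def reference_join_classify(
    input_tree: TreeLike,
    Tx: FrequentSubtree,
    Ty: FrequentSubtree,
) -> JoinType:
    """Linear-time restriction-based join classification (the test oracle).

    Restrict the input tree to the union of the operands' leaves, canonicalize
    the restriction and pattern-match it against the four join shapes: it must
    have T_x as prefix and display T_y (else NONE); then x, y siblings under a
    binary parent is the cherry type (2), siblings under a wider parent is
    type 1, and otherwise the operand depths separate type 3 (equal) from
    type 4 (x deeper).
    """
    big = canonicalize(input_tree)
    union = Tx.tree.leaf_set | Ty.tree.leaf_set
    if not union <= big.leaf_set:
        return JoinType.NONE
    joined = restrict_shape(big.shape, union)
    if shape_rightmost(joined) != Ty.rightmost:
        return JoinType.NONE
    if shape_prefix(joined) != Tx.tree.shape:
        return JoinType.NONE
    if not displays_shape(joined, Ty.tree.shape):
        return JoinType.NONE

    x, y = Tx.rightmost, Ty.rightmost

    def parent_children(shape: Shape, leaf: int) -> Optional[tuple[Shape, ...]]:
        if isinstance(shape, int):
            return None
        if leaf in shape:
            return shape
        for child in shape:
            if isinstance(child, tuple) and leaf in shape_leafset(child):
                return parent_children(child, leaf)
        return None

    p_y = parent_children(joined, y)
    assert p_y is not None
    if x in p_y:
        return JoinType.TYPE2 if len(p_y) == 2 else JoinType.TYPE1
    if Tx.depth_p_rml == Ty.depth_p_rml:
        return JoinType.TYPE3
    assert Tx.depth_p_rml > Ty.depth_p_rml
    return JoinType.TYPE4
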