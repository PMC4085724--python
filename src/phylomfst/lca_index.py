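"""Per-tree LCA-depth tables, triplet topologies, frequent-triplet enumeration.

One-time preprocessing for the miner: for every input tree a flat table of
depth(LCA(u, v)) over all unordered leaf pairs (quadratic per tree, built in a
single depth-first pass), from which the topology any leaf triple displays is
read off with three lookups.  Frequent triplets — triples on which at least
``threshold`` of the m input trees display the same topology — seed the
enumeration, and their supports are the first support sets.

Support sets are bit-indexed over tree indices 0..m-1 (one bit per input
tree), so intersection and subset tests are single integer operations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Optional, Sequence

from .errors import ConfigError, LeafNotFoundError
from .trees import CanonicalTree, Shape, TreeLike, canonicalize

__all__ = [
    "SupportSet",
    "LcaDepthTable",
    "TripletTopology",
    "FrequentTripletTable",
    "build_lca_depth_table",
    "triplet_topology",
    "triplet_shape",
    "enumerate_frequent_triplets",
]


class SupportSet:
    """Bit-indexed set of input-tree indices (the bitmap support list)."""

    __slots__ = ("mask", "m")

    def __init__(self, mask: int, m: int):
        self.mask = mask
        self.m = m

    @classmethod
    def empty(cls, m: int) -> "SupportSet":
        return cls(0, m)

    @classmethod
    def full(cls, m: int) -> "SupportSet":
        return cls((1 << m) - 1, m)

    @classmethod
    def from_indices(cls, indices: Iterable[int], m: int) -> "SupportSet":
        mask = 0
        for i in indices:
            if not 0 <= i < m:
                raise ValueError(f"tree index {i} out of range 0..{m - 1}")
            mask |= 1 << i
        return cls(mask, m)

    @property
    def count(self) -> int:
        return self.mask.bit_count()

    def indices(self) -> Iterator[int]:
        mask = self.mask
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def __contains__(self, i: int) -> bool:
        return bool(self.mask >> i & 1)

    def __and__(self, other: "SupportSet") -> "SupportSet":
        return SupportSet(self.mask & other.mask, self.m)

    def issubset(self, other: "SupportSet") -> bool:
        return self.mask & ~other.mask == 0

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SupportSet)
            and self.mask == other.mask
            and self.m == other.m
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.m))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SupportSet({sorted(self.indices())}, m={self.m})"


class TripletTopology(enum.Enum):
    """Rooted topology of a sorted leaf triple a < b < c."""

    STAR = "star"  # (a,b,c)
    AB_C = "ab_c"  # ((a,b),c)
    AC_B = "ac_b"  # ((a,c),b)
    BC_A = "bc_a"  # (a,(b,c))


@dataclass(frozen=True)
class LcaDepthTable:
    """depth(LCA(u, v)) for all unordered leaf pairs of one input tree."""

    tree_index: int
    leaves: frozenset[int]
    depth: dict[tuple[int, int], int]

    def has(self, *labels: int) -> bool:
        return all(lbl in self.leaves for lbl in labels)

    def lca_depth(self, u: int, v: int) -> int:
        key = (u, v) if u < v else (v, u)
        try:
            return self.depth[key]
        except KeyError:
            raise LeafNotFoundError(f"leaf pair {key} not in tree {self.tree_index}")


def build_lca_depth_table(tree: TreeLike, tree_index: int = 0) -> LcaDepthTable:
    """Quadratic-time table build: at each internal node of depth d, every
    leaf pair split across two of its child subtrees has LCA depth d."""
    ct = canonicalize(tree)
    depth_of: dict[tuple[int, int], int] = {}

    def walk(shape: Shape, depth: int) -> list[int]:
        if isinstance(shape, int):
            return [shape]
        groups = [walk(c, depth + 1) for c in shape]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for u in groups[i]:
                    for v in groups[j]:
                        key = (u, v) if u < v else (v, u)
                        depth_of[key] = depth
        merged: list[int] = []
        for g in groups:
            merged.extend(g)
        return merged

    walk(ct.shape, 0)
    return LcaDepthTable(tree_index, ct.leaf_set, depth_of)


def triplet_topology(table: LcaDepthTable, a: int, b: int, c: int) -> TripletTopology:
    """Topology of {a, b, c} (sorted internally) via three LCA-depth lookups.

    On a rooted tree exactly two of the three pairwise LCA depths are equal
    and not larger than the third; the deep pair is the cherry.
    """
    a, b, c = sorted((a, b, c))
    if not table.has(a, b, c):
        raise LeafNotFoundError(f"triple ({a},{b},{c}) not in tree {table.tree_index}")
    dab = table.lca_depth(a, b)
    dac = table.lca_depth(a, c)
    dbc = table.lca_depth(b, c)
    if dab == dac == dbc:
        return TripletTopology.STAR
    if dab > dac:
        assert dac == dbc
        return TripletTopology.AB_C
    if dac > dab:
        assert dab == dbc
        return TripletTopology.AC_B
    assert dbc > dab and dab == dac
    return TripletTopology.BC_A


def triplet_shape(a: int, b: int, c: int, topo: TripletTopology) -> Shape:
    """Canonical shape of the 3-leaf tree on sorted a < b < c."""
    a, b, c = sorted((a, b, c))
    if topo is TripletTopology.STAR:
        return (a, b, c)
    if topo is TripletTopology.AB_C:
        return ((a, b), c)
    if topo is TripletTopology.AC_B:
        return ((a, c), b)
    return (a, (b, c))


@dataclass
class FrequentTripletTable:
    """sorted triple -> (canonical 3-leaf shape, SupportSet); threshold used.

    With threshold > m/2 at most one topology per triple can reach the
    threshold, so storage of a single winner per triple is lossless.
    """

    threshold: int
    m: int
    entries: dict[tuple[int, int, int], tuple[Shape, SupportSet]]

    def get(self, a: int, b: int, c: int) -> Optional[tuple[Shape, SupportSet]]:
        key: tuple[int, int, int] = tuple(sorted((a, b, c)))  # type: ignore[assignment]
        return self.entries.get(key)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self) -> str:
        lines = []
        for (a, b, c), (shape, sup) in sorted(self.entries.items()):
            from .trees import shape_newick

            lines.append(f"{a}\t{b}\t{c}\t{shape_newick(shape)}\t{sup.count}")
        return "\n".join(lines) + ("\n" if lines else "")


def enumerate_frequent_triplets(
    tables: Sequence[LcaDepthTable],
    threshold: int,
    universe: Optional[Iterable[int]] = None,
) -> FrequentTripletTable:
    """Tally the topology of every leaf triple across all trees containing it
    and keep the (unique) topology reaching ``threshold``.

    A tree votes on a triple only if it contains all three leaves; the
    frequency denominator remains the collection size m.
    """
    m = len(tables)
    if not threshold > m / 2:
        raise ConfigError(f"threshold {threshold} must exceed m/2 = {m / 2}")
    if universe is None:
        labels = sorted(set().union(*(t.leaves for t in tables)))
    else:
        labels = sorted(set(universe))

    entries: dict[tuple[int, int, int], tuple[Shape, SupportSet]] = {}
    for a, b, c in combinations(labels, 3):
        tally: dict[TripletTopology, int] = {}
        for table in tables:
            if not table.has(a, b, c):
                continue
            topo = triplet_topology(table, a, b, c)
            tally[topo] = tally.get(topo, 0) | (1 << table.tree_index)
        for topo, mask in tally.items():
            if mask.bit_count() >= threshold:
                entries[(a, b, c)] = (triplet_shape(a, b, c, topo), SupportSet(mask, m))
                break  # at most one topology can reach a >m/2 threshold
    return FrequentTripletTable(threshold=threshold, m=m, entries=entries)
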