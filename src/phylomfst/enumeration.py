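"""Enumeration-tree traversal: equivalence classes, pruning, MFST emission.

The space of frequent subtrees (FSTs) is organised into an enumeration tree:
canonical trees sharing a common *prefix* (the tree left after pruning the
rightmost IDFT leaf) form an equivalence class whose *core* is that prefix.
The classes over 3-leaf FSTs — the frequent triplets — are the roots of the
traversal; expanding a class joins every ordered pair of its members, and a
member whose own class comes up empty is a leaf of the enumeration tree whose
core is a *candidate* maximal FST (MFST).

Because exponentially more FSTs than MFSTs can exist, branches whose every
descendant is displayed inside another branch are pruned:

* sibling rule — the ordered join T_xy existing with a non-cherry type (or a
  cherry type whose witnesses extend to frequent triplets [x, y, z] for every
  sibling continuation z), with the pruned core's support nested in the
  pruner's, kills the whole sibling branch;
* cousin rule — a cherry-type T_xy together with a non-cherry T_yz (supports
  nested) kills the branch below T_yz;
* pruner-lists — cases the two rules cannot certify are recorded as
  (label, support) entries on the would-be-pruned class and verified lazily:
  an empty class holding an entry, or a class all of whose members carry an
  entry for a common label with the right support intersection, is pruned.

Pruning only skips work: with all pruning disabled the emitted set (after the
maximality filter) is unchanged, and every FST is materialised exactly once
via its unique ordered parent pair.

Emission passes through a final pairwise maximality filter (default on):
candidates displayed by another candidate are removed.  The sibling/cousin
machinery only relates classes below a common parent class, so domination
across different triplet-level branches is caught here rather than during the
traversal; the removal counter is reported for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

from .errors import ConfigError, InvalidTreeError, MiningLimitError
from .joins import FrequentSubtree, JoinOutcome, JoinType, join_support
from .lca_index import (
    FrequentTripletTable,
    LcaDepthTable,
    SupportSet,
    build_lca_depth_table,
    enumerate_frequent_triplets,
)
from .trees import (
    CanonicalTree,
    TreeLike,
    canonicalize,
    shape_sort_key,
)

__all__ = [
    "MiningConfig",
    "Member",
    "EquivalenceClass",
    "MiningResult",
    "threshold_count",
    "initial_classes",
    "check_prunes_sibling",
    "check_prunes_cousin",
    "update_pruner_list",
    "check_pruned_by_pruner_lists",
    "enumerate_node",
    "finalize_maximal",
    "mine",
]


def threshold_count(m: int, f: Union[Fraction, float, str, int]) -> int:
    """Smallest integer >= f*m, by exact cross-multiplied comparison.

    f must lie in (1/2, 1]: a majority threshold conveys confidence and makes
    the frequent subtree on a given leaf set unique.
    """
    if m < 1:
        raise ConfigError("need at least one input tree")
    frac = Fraction(f) if not isinstance(f, Fraction) else f
    if not (2 * frac.numerator > frac.denominator and frac <= 1):
        raise ConfigError(f"support fraction f={frac} must satisfy 1/2 < f <= 1")
    num, den = frac.numerator, frac.denominator
    return -(-num * m // den)  # ceil(num*m/den) without floats


@dataclass
class MiningConfig:
    f: Fraction
    m: int
    mode: str = "mfst"  # "mfst" | "mxst"
    enable_pruning: bool = True
    safety_maximality_filter: bool = True
    max_nodes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("mfst", "mxst"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "mxst" and self.f != 1:
            raise ConfigError("mxst mode requires f = 1")
        self.threshold = threshold_count(self.m, self.f)


@dataclass
class Member:
    """A frequent subtree inside its equivalence class, together with the
    pruner-list and pruned flag of the class it will core."""

    fst: FrequentSubtree
    pruner: dict[int, SupportSet] = field(default_factory=dict)
    branch_pruned: bool = False

    @property
    def rightmost(self) -> int:
        return self.fst.rightmost


@dataclass
class EquivalenceClass:
    """A core tree, the members sharing it as prefix, and the class's own
    pruner-list (inherited from the member that created it)."""

    core: FrequentSubtree
    members: list[Member]
    pruner: dict[int, SupportSet] = field(default_factory=dict)

    def member_by_rightmost(self, label: int) -> Member:
        for mem in self.members:
            if mem.rightmost == label:
                return mem
        raise KeyError(label)


@dataclass
class MiningResult:
    mfsts: list[tuple[CanonicalTree, SupportSet]]
    counters: dict[str, int]
    config: MiningConfig

    def newick_lines(self, label_map=None) -> list[str]:
        return [t.newick(label_map) for t, _ in self.mfsts]


class _Context:
    def __init__(
        self,
        tables: Sequence[LcaDepthTable],
        triplets: FrequentTripletTable,
        config: MiningConfig,
    ):
        self.tables = tables
        self.triplets = triplets
        self.config = config
        self.candidates: list[tuple[CanonicalTree, SupportSet]] = []
        self.counters: dict[str, int] = {
            "nodes_visited": 0,
            "joins_attempted": 0,
            "joins_existing": 0,
            "materialized": 0,
            "pruned_sibling": 0,
            "pruned_cousin": 0,
            "pruned_pruner_list": 0,
            "suppressed_empty_pruner": 0,
            "candidates_emitted": 0,
            "safety_filter_removed": 0,
        }


# ---------------------------------------------------------------------------
# initial classes
# ---------------------------------------------------------------------------

def initial_classes(
    triplets: FrequentTripletTable,
    tables: Sequence[LcaDepthTable],
) -> list[EquivalenceClass]:
    """Group the frequent-triplet trees into classes keyed by their 2-leaf
    prefix (the first two IDFT leaves).  Classes and members come out in a
    deterministic sorted order."""
    m = triplets.m
    grouped: dict[tuple[int, int], list[FrequentSubtree]] = {}
    for (_a, _b, _c), (shape, sup) in triplets.entries.items():
        ct = CanonicalTree(shape)
        fst = FrequentSubtree.from_tree(ct, sup)
        key = (ct.idft[0], ct.idft[1])
        grouped.setdefault(key, []).append(fst)

    classes: list[EquivalenceClass] = []
    for (i, j) in sorted(grouped):
        presence = 0
        for table in tables:
            if table.has(i, j):
                presence |= 1 << table.tree_index
        core = FrequentSubtree(
            tree=CanonicalTree((i, j)),
            support=SupportSet(presence, m),
            depth_p_rml=0,
            nchild_p_rml=2,
            rightmost=j,
        )
        members = [
            Member(fst)
            for fst in sorted(grouped[(i, j)], key=lambda f: f.rightmost)
        ]
        classes.append(EquivalenceClass(core=core, members=members))
    return classes


# ---------------------------------------------------------------------------
# pruning rules
# ---------------------------------------------------------------------------

def check_prunes_sibling(
    x: int,
    y: int,
    out_xy: JoinOutcome,
    Ymem: Member,
    outcomes: dict[tuple[int, int], JoinOutcome],
    triplets: FrequentTripletTable,
) -> bool:
    """Does the sibling branch of X prune the branch of Y?

    The rule certifies, for every possible descendant core S in Y's branch,
    a frequent counterpart on ℒ(S) ∪ {x} displaying S.  All trees backing S
    must display the same topology there, which holds exactly when every
    leaf triple involving x is pinned by a frequent witness whose support
    contains Y's (descendant supports are nested in Y's).  Since descendants
    extend Y only by leaves z with T_yz existing, the full set of conditions
    is:

    * T_xy exists and Y's support is nested in T_xy's support — pins
      {x, u, v} for u, v in the core plus y;
    * for every continuation z: a join of (x, z) exists in either order with
      Y's support nested in its support — pins {x, z, u} for u in the core —
      and the frequent triplet [x, y, z] exists with Y's support nested in
      its support;
    * for every pair of continuations z, z': the frequent triplet [x, z, z']
      exists with Y's support nested in its support.

    These are deliberately stronger than the classical sibling conditions,
    which leave cherry-stacked continuation pairs (and, for multifurcating
    inputs, star joins) unpinned and then demonstrably delete true maximal
    subtrees.  At f = 1 on well-resolved collections the extra witnesses are
    usually present and the rule fires as often as the classical one.

    (Note x itself can never extend Y's branch: T_xy and T_yx are two
    topologies on one leaf set, and a majority threshold admits only one.)
    """
    if not out_xy.exists:
        return False
    Ysup = Ymem.fst.support
    if not Ysup.issubset(out_xy.support):
        return False
    conts = [
        z for (yy, z), o in outcomes.items() if yy == y and z != x and o.exists
    ]
    for z in conts:
        trip = triplets.get(x, y, z)
        if trip is None or not Ysup.issubset(trip[1]):
            return False
        out_xz = outcomes.get((x, z)) or outcomes.get((z, x))
        if out_xz is None or not Ysup.issubset(out_xz.support):
            return False
    for i, z in enumerate(conts):
        for z2 in conts[i + 1:]:
            trip = triplets.get(x, z, z2)
            if trip is None or not Ysup.issubset(trip[1]):
                return False
    return True


def check_prunes_cousin(out_xy: JoinOutcome, out_yz: JoinOutcome) -> bool:
    """First-cousin rule: a cherry-type T_xy prunes the branch below a
    non-cherry T_yz whose support is nested in T_xy's."""
    return (
        out_xy.exists
        and out_xy.join_type is JoinType.TYPE2
        and out_yz.exists
        and out_yz.join_type is not JoinType.TYPE2
        and out_yz.support.issubset(out_xy.support)
    )


def update_pruner_list(
    target: Member,
    x: int,
    y: int,
    out_xy: JoinOutcome,
    sup_xz: Optional[SupportSet],
    triplets: FrequentTripletTable,
    threshold: int,
) -> None:
    """Record label x on the class of the joined member T_yz when the prune
    could not be certified outright (new-entry conditions).

    An entry (x, S) certifies that a frequent subtree on the extended leaf
    set displays T_yz on every tree in S intersected with T_yz's support.
    That subtree exists only if every leaf triple of the extended set is
    pinned by a frequent witness, so beyond the join T_xy the entry requires
    the frequent triplet [x, y, z] and an existing join of (x, z) in either
    order (``sup_xz``), and intersects all three supports.  The entry is
    stored only if the result still meets the threshold on T_yz's trees.
    """
    if sup_xz is None:
        return
    trip = triplets.get(x, y, target.rightmost)
    if trip is None:
        return
    entry_sup = out_xy.support & trip[1] & sup_xz
    if (entry_sup & target.fst.support).count >= threshold:
        target.pruner.setdefault(x, entry_sup)


def inherit_pruner_entries(
    joined: Member,
    Ymem: Member,
    Zmem: Member,
    triplets: FrequentTripletTable,
    threshold: int,
) -> None:
    """Inheritance: labels present in both parents' pruner-lists descend with
    the intersected supports, kept only if frequent on the child's trees.

    The two parent entries certify displaying subtrees on the core plus
    {y, w} and plus {z, w}; together with the join they fix every leaf triple
    of the extended set except {y, z, w} itself.  The entry therefore also
    requires the frequent triplet on {y, z, w} and intersects its support —
    without it the certified displaying subtree need not exist and true
    maximal subtrees would be suppressed.
    """
    y, z = Ymem.rightmost, Zmem.rightmost
    for w, sup_y in Ymem.pruner.items():
        sup_z = Zmem.pruner.get(w)
        if sup_z is None:
            continue
        trip = triplets.get(y, z, w)
        if trip is None:
            continue
        s = sup_y & sup_z & trip[1]
        if (s & joined.fst.support).count >= threshold:
            joined.pruner.setdefault(w, s)


def check_pruned_by_pruner_lists(
    cls: EquivalenceClass, triplets: FrequentTripletTable
) -> list[Member]:
    """Lazy verification over a class's members' pruner-lists.

    For a label a carried by *every* member, the intersection S of the
    recorded supports — further intersected with the frequent-triplet
    supports [a, b, b'] over every pair of member rightmost leaves, which pin
    the cross-member triples the per-member certificates do not cover —
    certifies the branch below any member whose own support equals S; those
    members are returned (and flagged pruned).  An empty class is handled by
    the caller via its own pruner-list.
    """
    if not cls.members:
        return []
    common = set(cls.members[0].pruner)
    for mem in cls.members[1:]:
        common &= set(mem.pruner)
    rightmosts = [mem.rightmost for mem in cls.members]
    pruned: list[Member] = []
    for a in sorted(common):
        inter_mask = None
        for mem in cls.members:
            s = mem.pruner[a]
            inter_mask = s.mask if inter_mask is None else inter_mask & s.mask
        for i, b in enumerate(rightmosts):
            for b2 in rightmosts[i + 1:]:
                trip = triplets.get(a, b, b2)
                if trip is None:
                    inter_mask = 0
                    break
                inter_mask &= trip[1].mask
            if not inter_mask:
                break
        for mem in cls.members:
            if not mem.branch_pruned and inter_mask and mem.fst.support.mask == inter_mask:
                mem.branch_pruned = True
                pruned.append(mem)
    return pruned


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------

def enumerate_node(cls: EquivalenceClass, ctx: _Context) -> None:
    """Expand one equivalence class: join ordered member pairs, apply the
    pruning rules, emit cores of empty unpruned child classes, recurse."""
    cfg = ctx.config
    ctx.counters["nodes_visited"] += 1
    if cfg.max_nodes is not None and ctx.counters["nodes_visited"] > cfg.max_nodes:
        raise MiningLimitError(
            f"enumeration exceeded max_nodes={cfg.max_nodes}; raise the cap "
            f"or lower |L| / raise f"
        )

    if cfg.enable_pruning:
        ctx.counters["pruned_pruner_list"] += len(
            check_pruned_by_pruner_lists(cls, ctx.triplets)
        )

    r = cls.core.rightmost
    members = cls.members
    outcomes: dict[tuple[int, int], JoinOutcome] = {}
    for X in members:
        for Y in members:
            if X is Y:
                continue
            ctx.counters["joins_attempted"] += 1
            out = join_support(X.fst, Y.fst, r, ctx.tables, cfg.threshold)
            if out.exists:
                outcomes[(X.rightmost, Y.rightmost)] = out
                ctx.counters["joins_existing"] += 1
                ctx.counters["materialized"] += 1

    # child classes: members of the class cored by each X, in sorted order
    children: dict[int, list[Member]] = {X.rightmost: [] for X in members}
    joined_members: dict[tuple[int, int], Member] = {}
    for (x, y), out in sorted(outcomes.items()):
        mem = Member(out.joined)
        if cfg.enable_pruning:
            inherit_pruner_entries(
                mem,
                cls.member_by_rightmost(x),
                cls.member_by_rightmost(y),
                ctx.triplets,
                cfg.threshold,
            )
        children[x].append(mem)
        joined_members[(x, y)] = mem

    if cfg.enable_pruning:
        # sibling rule
        for (x, y), out in sorted(outcomes.items()):
            Ymem = cls.member_by_rightmost(y)
            if Ymem.branch_pruned:
                continue
            if check_prunes_sibling(x, y, out, Ymem, outcomes, ctx.triplets):
                Ymem.branch_pruned = True
                ctx.counters["pruned_sibling"] += 1
        # cousin rule
        for (x, y), out_xy in sorted(outcomes.items()):
            if out_xy.join_type is not JoinType.TYPE2:
                continue
            for (yy, z), out_yz in sorted(outcomes.items()):
                if yy != y or z == x:
                    continue
                tgt = joined_members[(y, z)]
                if not tgt.branch_pruned and check_prunes_cousin(out_xy, out_yz):
                    tgt.branch_pruned = True
                    ctx.counters["pruned_cousin"] += 1
        # new pruner-list entries where no rule fired
        for (x, y), out_xy in sorted(outcomes.items()):
            Ymem = cls.member_by_rightmost(y)
            if Ymem.branch_pruned:
                continue
            for (yy, z), out_yz in sorted(outcomes.items()):
                if yy != y or z == x:
                    continue
                tgt = joined_members[(y, z)]
                if tgt.branch_pruned:
                    continue
                out_xz = outcomes.get((x, z)) or outcomes.get((z, x))
                sup_xz = out_xz.support if out_xz is not None else None
                update_pruner_list(
                    tgt, x, y, out_xy, sup_xz, ctx.triplets, cfg.threshold
                )

    for X in members:
        if cfg.enable_pruning and X.branch_pruned:
            continue
        kids = children[X.rightmost]
        if not kids:
            if cfg.enable_pruning and X.pruner:
                ctx.counters["suppressed_empty_pruner"] += 1
                continue
            ctx.candidates.append((X.fst.tree, X.fst.support))
            ctx.counters["candidates_emitted"] += 1
        else:
            enumerate_node(
                EquivalenceClass(core=X.fst, members=kids, pruner=X.pruner), ctx
            )


def finalize_maximal(
    candidates: Sequence[tuple[CanonicalTree, SupportSet]],
    counters: dict[str, int],
    safety_filter: bool = True,
) -> list[tuple[CanonicalTree, SupportSet]]:
    """Drop candidates displayed by another candidate; sort the survivors by
    (leaf count desc, Newick).  The number removed is recorded — nonzero
    removals mean the traversal emitted non-maximal cores that only the
    filter caught."""
    uniq: dict = {}
    for ct, sup in candidates:
        if ct.shape in uniq:
            counters["duplicate_candidates"] = counters.get("duplicate_candidates", 0) + 1
            continue
        uniq[ct.shape] = (ct, sup)
    items = list(uniq.values())
    if safety_filter:
        kept = []
        for ct, sup in items:
            if any(
                other.n_leaves > ct.n_leaves and other.displays(ct)
                for other, _ in items
                if other.shape != ct.shape
            ):
                counters["safety_filter_removed"] += 1
            else:
                kept.append((ct, sup))
        items = kept
    items.sort(key=lambda pair: (-pair[0].n_leaves, shape_sort_key(pair[0].shape)))
    return items


def mine(
    trees: Sequence[TreeLike],
    f: Union[Fraction, float, str],
    mode: str = "mfst",
    enable_pruning: bool = True,
    safety_maximality_filter: bool = True,
    max_nodes: Optional[int] = None,
) -> MiningResult:
    """End-to-end mining of all maximal frequent subtrees.

    ``trees`` is a collection of rooted trees over integer leaf labels (use
    :func:`phylomfst.trees.read_collection` for Newick files); every tree must
    have at least 3 leaves.  ``f`` is the support fraction in (1/2, 1] —
    decimal strings like ``"0.75"`` are converted to exact fractions.  In
    ``mxst`` mode f is forced to 1 and the result is the set of maximal
    agreement subtrees.
    """
    if not trees:
        raise ConfigError("empty tree collection")
    frac = Fraction(f) if not isinstance(f, Fraction) else f
    if mode == "mxst":
        frac = Fraction(1)
    config = MiningConfig(
        f=frac,
        m=len(trees),
        mode=mode,
        enable_pruning=enable_pruning,
        safety_maximality_filter=safety_maximality_filter,
        max_nodes=max_nodes,
    )
    canon = [canonicalize(t) for t in trees]
    for ct in canon:
        if ct.n_leaves < 3:
            raise InvalidTreeError("collection trees must have at least 3 leaves")
    tables = [build_lca_depth_table(ct, i) for i, ct in enumerate(canon)]
    triplets = enumerate_frequent_triplets(tables, config.threshold)
    ctx = _Context(tables, triplets, config)
    for cls in initial_classes(triplets, tables):
        ctx.counters["materialized"] += len(cls.members)
        enumerate_node(cls, ctx)
    mfsts = finalize_maximal(
        ctx.candidates, ctx.counters, safety_filter=config.safety_maximality_filter
    )
    return MiningResult(mfsts=mfsts, counters=ctx.counters, config=config)
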