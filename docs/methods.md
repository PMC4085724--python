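# Methods

## Model and definitions

A phylogenetic tree here is a rooted, unordered tree whose leaves are
bijectively labeled and whose internal nodes have at least two children
(multifurcations are allowed and meaningful: they encode unresolved
relationships). Taxon names are mapped to the integer universe 1..|L| by
lexicographic sort of the union of names across the collection, so the
mapping is deterministic and independent of tree order. Branch lengths and
internal labels are read and discarded — only topology matters.

The restriction T|ℒ′ is the minimal homeomorphic subtree connecting ℒ′,
rooted at the LCA of ℒ′ with all unary chains suppressed. T *displays* T′
when ℒ(T′) ⊆ ℒ(T) and T|ℒ(T′) ≡ T′. For m input trees and a support
fraction f ∈ (1/2, 1], a topology on a leaf subset is an f-frequent subtree
(FST) when at least ⌈f·m⌉ input trees display it; with a majority threshold
at most one topology per leaf subset qualifies. A maximal FST (MFST) is
displayed by no other FST. At f = 1 MFSTs are the maximal agreement
subtrees; the maximum agreement subtrees (MASTs) are the largest of them.

Trees with partially overlapping leaf sets are accepted: a tree votes on a
candidate only if it contains all the candidate's leaves, while the
frequency denominator stays m. This is the strict reading of "a fraction f
of the input trees"; a per-candidate denominator would make support
non-monotone under leaf addition and break the uniqueness argument.

## Canonical form and the enumeration tree

Canonical form orders the children of every node ascending by *virtual
label* (the minimum leaf label in the subtree). Sibling virtual labels are
necessarily distinct, so no tie-break exists; canonical equality is
isomorphism, and canonical trees are stored as nested tuples usable as
dictionary keys. The *rightmost leaf* is the last leaf of the left-to-right
depth-first traversal; pruning it (the *prefix*) or the second-to-last leaf
provably preserves canonical form, which the test suite re-checks at random.

FSTs sharing a prefix form an equivalence class whose *core* is that prefix.
Classes over the frequent 3-leaf topologies (frequent triplets) are the
roots of the traversal; three leaves is the smallest unit of phylogenetic
signal, so 2-leaf agreements are not reported. Each k-leaf FST is the join
of a unique ordered pair of (k−1)-leaf FSTs in one class, so with pruning
disabled every FST is materialised exactly once — an invariant the tests
count against the oracle.

## Joins and support

For an ordered pair (T_x, T_y) with common prefix whose rightmost leaf is r,
the joined tree (when it exists) takes one of four shapes, decided per input
tree from the topology of the triple {r, x, y} plus the depths of the
rightmost-leaf parents *inside the operands*: siblings under a shared wider
parent (type 1, the star case), a new cherry (x, y) one level deeper
(type 2), the second operand's parent adopting the first's (type 3, which
additionally requires that parent to be binary), or y attaching strictly
above x on the rightmost path (type 4). Triple topologies come from a
per-tree table of depth(LCA(u, v)) over all leaf pairs, built once in
quadratic time per tree; a flat table beats asymptotically optimal LCA
structures at these access patterns. Supports are bit-vectors over tree
indices, so intersection and subset tests are single integer operations, and
a join exists when one type's tally reaches the threshold — at most one can.
Join construction grafts y into T_x at the position the type dictates and
then verifies defensively that the result is canonical, has T_x as its
prefix and displays T_y; a verification failure is raised as an internal
error, never silently repaired.

## Pruning

Exponentially more FSTs than MFSTs can exist, so branches whose every
descendant is displayed inside another branch are cut:

* **Sibling rule.** The branch below sibling Y is pruned when the join T_xy
  exists with Y's support contained in its, and, for the continuations z of
  Y (the leaves whose joins T_yz exist — precisely the leaves any descendant
  of Y can add), every triple a descendant's counterpart needs is pinned by
  a frequent witness containing Y's support: the triplet [x, y, z] and a
  join of (x, z) in either order, per continuation, and the triplet
  [x, z, z'] per continuation pair.
* **Cousin rule.** A cherry-type T_xy prunes the branch below a non-cherry
  T_yz whose support is contained in T_xy's.
* **Pruner-lists.** Cases the rules cannot certify are recorded as
  (label, support) entries on the would-be-pruned class and verified lazily:
  an empty class holding an entry is not emitted, and a class all of whose
  members carry an entry for a common label — with the intersected entry
  supports equal to a member's support — has that member's branch cut.

Two design points deserve emphasis. First, every pruning condition follows
one proof principle: a branch may be cut only when, for each of its possible
descendant cores, a frequent *counterpart* displaying that core provably
exists, and the counterpart exists exactly when every leaf triple of its
topology is pinned by a frequent witness whose support covers the
descendant's. A rooted topology is determined by its triple restrictions,
so trees that agree on all pinned triples agree on the counterpart. The
join witnesses pin triples inside the operands; the explicit triplet
witnesses pin the remainder (continuation pairs for the sibling rule, the
{x, y, z} and cross-member triples for pruner-list entries, the {y, z, w}
triple for inheritance). Weaker, superficially natural conditions — support
containment in a sibling core instead of the join, dropping the
continuation-pair triplets, or trusting a pair of cherry- or star-type
joins to determine their combined topology — each demonstrably delete true
maximal subtrees on randomized collections, including fully binary ones at
f = 1, because two trees can display both witnessing joins yet resolve an
unpinned triple differently.

Second, sibling/cousin/pruner-list reasoning only relates classes below a
*common parent class*. Domination across different triplet-level classes
(e.g. every input displaying (1,(2,(3,4))) also displays (2,(3,4)), whose
class sits under a different initial prefix) is invisible to the traversal.
The final pairwise maximality filter (on by default) therefore is not a
safety net but an integral step: it removes candidates displayed by another
candidate, at O(k²·|L|) for k candidates, and its removal count is reported
in the run counters. Pruning itself never removes output — disabling it
entirely reproduces the identical MFST set, only slower, and the tests
assert this.

## Synthetic collections

The generator emulates bootstrap-replicate collections: a uniformly random
base topology (sequential leaf attachment) perturbed per replicate. The
perturbation unit is a **leaf prune-and-regraft** — one taxon re-placed at a
random node, edge, or above the root — because single-taxon instability is
precisely the failure mode agreement methods are meant to survive, and it
makes the planted guarantee exact: the base restricted to a replicate's
untouched leaves is displayed by that replicate, by construction, and the
per-replicate move log is returned so tests can assert it. Options add
rogue taxa (re-placed in *every* replicate), multifurcations (independent
edge collapses with a given probability), and partial overlap (each
replicate restricted to a random leaf fraction, never below 3 leaves). One
seeded RNG stream drives each call, so a spec plus seed reproduces the
collection byte-for-byte.

Defaults (10 taxa, 10 replicates, 1 move, no rogues, binary, full overlap)
describe a mild, realistic bootstrap at desk scale. What the generator does
*not* emulate: sequence-level noise, correlated topological error, branch
lengths, or taxon sampling bias. Passing tests therefore demonstrate
algorithmic correctness — exact agreement with exhaustive enumeration under
controlled perturbation — not statistical behaviour on real bootstrap
samples.

## Numerical and procedural choices

* The support threshold is the smallest integer ≥ f·m computed by exact
  cross-multiplied fraction arithmetic; "0.55" parses to 11/20, so no
  floating-point boundary case can flip a threshold. f ≤ 1/2 is rejected.
* Traversal order is fully deterministic: classes by core serialization,
  members by rightmost label, output by (leaf count descending, Newick
  string). Identical inputs give byte-identical outputs; permuting the
  input trees permutes only the support indices.
* Degenerate inputs: unary root chains in Newick are suppressed on ingest;
  duplicate leaf names, trees with fewer than 3 leaves, and malformed
  Newick raise typed errors.
* The enumeration-node count can be capped (`max_nodes`); the pruner-list
  verification branches admit no polynomial bound in the number of MFSTs,
  so runaway instances fail loudly instead of hanging.
* The brute-force oracle refuses universes above 16 leaves, keeping its
  2^|L| enumeration honest about its scope.

## Validation scale

Correctness is asserted by exact set equality (topologies and support sets)
against the oracle on a seeded grid of 54 collections — 6/8/10 taxa, 5/10/20
trees, 0–2 moves, 0–1 rogue taxa — at f ∈ {0.51, 0.6, 0.75, 1}, with
pruning on and off, plus randomized grids with multifurcations and partial
overlap during development. Those sizes keep the full suite around fifteen
seconds while the subset oracle still enumerates every candidate leaf set;
the miner itself has no such size restriction.

## Known limitations

* Support fractions at or below 1/2 are unsupported by design: uniqueness
  per leaf set fails there and the enumeration invariants with it.
* Unrooted trees are not modelled; root placement changes the answer.
* Worst-case time is proportional to the number of FSTs enumerated for
  pruning verification, which can be exponential in |L| even when the MFST
  set is small.
* The maximality filter's quadratic cost in the candidate count is
  negligible at desk scale but untested against collections producing many
  thousands of maximal candidates.
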