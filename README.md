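# phylomfst

Exact enumeration of **maximal frequent subtrees** (MFSTs) — including
**maximal agreement subtrees** as the unanimous special case — in collections
of rooted phylogenetic trees.

## The problem

A phylogenetic analysis rarely ends with one tree: bootstrap replicates,
Bayesian posterior samples, or gene trees give a *collection* of rooted trees
on (largely) shared taxa. The classical summary, the maximum agreement
subtree (MAST), is brittle: a single "rogue" taxon that wanders between
replicates can shrink it drastically, and the MAST discards agreement that
happens to live on other taxon subsets. This package mines a richer summary.

For a collection of *m* rooted trees and a support fraction
*f* ∈ (1/2, 1], a subtree *T′* on a leaf subset is **f-frequent** (an FST)
if at least *f·m* of the input trees **display** it, i.e. equal *T′* when
restricted to its leaves (T|ℒ(T′) ≡ T′). Because *f* exceeds a majority, at
most one topology per leaf subset can be frequent. An FST is **maximal** (an
MFST) if no other FST displays it. The MFST set is a compact, non-redundant
summary: every FST is displayed by some MFST, and no MFST is displayed by
another. At *f* = 1 the FSTs are agreement subtrees and the MFSTs are the
maximal agreement subtrees, which include every MAST — and often more.

## The algorithm

Trees are held in a *canonical form*: each internal node carries a virtual
label (the minimum leaf label below it) and children are ordered ascending
by virtual label, so isomorphism becomes string equality. The space of FSTs
is organised into an *enumeration tree* of equivalence classes: canonical
trees sharing a *prefix* (the tree left after pruning the rightmost leaf of
the inorder depth-first traversal) form a class whose core is that prefix.
Every *k*-leaf FST is generated exactly once, as the *join* of the unique
ordered pair of (*k*−1)-leaf FSTs obtained by pruning its last and
second-to-last traversal leaves. Which of the four possible join shapes each
input tree supports is decided in constant time from a precomputed table of
leaf-pair LCA depths; supports are bit-vector intersections. Branches whose
every descendant is displayed inside another branch are pruned via
sibling/cousin rules and lazily verified *pruner-lists*, and a final
pairwise maximality filter guarantees the emitted set is exactly the MFSTs.
Everything is validated against a deliberately naive oracle that enumerates
all 2^|L| leaf subsets.

## Worked example

The classic rogue-taxon situation: two trees that agree on everything except
where taxon `e` goes.

```
$ cat rogue.nwk
(((a,b),(c,d)),e);
((a,b),((c,d),e));

$ phylomfst mine rogue.nwk --mode mxst -v
read 2 trees on 5 taxa
((a,b),(c,d));
((a,b),e);
((c,d),e);
3 maximal frequent subtrees (threshold 2/2)
```

The MAST is `((a,b),(c,d))` alone. The two extra maximal agreement subtrees
record that *wherever* `e` attaches, both trees agree it lies outside the
`(a,b)` and `(c,d)` clades — information no MAST or majority-rule tree
shows. A JSON run report (`--report-json`) exposes the collection size,
threshold and traversal counters, and `--support-tsv` writes each subtree's
supporting tree indices.

Synthetic bootstrap-like collections (a seeded base tree perturbed by leaf
prune-and-regraft moves, optional rogue taxa, multifurcations and partial
taxon overlap) come from the `synth` subcommand:

```
$ phylomfst synth -o coll.nwk --n-leaves 10 --m-trees 20 --moves 1 --seed 7
$ phylomfst mine coll.nwk -f 0.75 -o out.nwk
```

The `oracle` subcommand runs the brute-force reference on small inputs
(≤ 16 taxa).

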