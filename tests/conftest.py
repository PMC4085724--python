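"""Shared test helpers: integer-Newick parsing, random trees, join instances."""

from __future__ import annotations

import random

import pytest

from phylomfst import FrequentSubtree, SupportSet
from phylomfst.joins import JoinType
from phylomfst.synthgen import random_tree
from phylomfst.trees import CanonicalTree, canonicalize, tree_from_newick_ints


def T(text: str) -> CanonicalTree:
    """Canonical tree from a Newick string with literal integer leaf names."""
    return tree_from_newick_ints(text)


@pytest.fixture
def t():
    return T


def random_canonical(rng: random.Random, n_min: int = 4, n_max: int = 12,
                     multifurcation_prob: float = 0.0) -> CanonicalTree:
    n = rng.randint(n_min, n_max)
    return random_tree(range(1, n + 1), rng=rng, multifurcation_prob=multifurcation_prob)


def shuffled_copy(ct: CanonicalTree, rng: random.Random) -> "object":
    """A PhyloTree isomorphic to ct with children randomly permuted."""
    pt = ct.to_phylo()
    for node in pt.iter_nodes():
        rng.shuffle(node.children)
    return pt


def fst_of(ct: CanonicalTree, m: int = 1) -> FrequentSubtree:
    return FrequentSubtree.from_tree(ct, SupportSet.full(m))


def join_instances(n_instances: int, seed: int, n_max: int = 12):
    """Random (input tree, T_x, T_y, r) classification instances.

    Each instance is derived from a genuine k-leaf restriction J of a random
    tree: T_x and T_y prune the last and second-to-last IDFT leaves of J, so
    the input tree displays both operands and the pair joins back to J.  The
    reversed ordered pair is also yielded (often a NONE instance), and with
    probability ~1/3 the input tree is swapped for an independent random tree
    on the same universe when that tree still displays both operands.
    """
    rng = random.Random(seed)
    out = []
    while len(out) < n_instances:
        mf = rng.choice([0.0, 0.0, 0.4])
        big = random_canonical(rng, n_min=5, n_max=n_max, multifurcation_prob=mf)
        k = rng.randint(4, big.n_leaves)
        subset = rng.sample(sorted(big.leaf_set), k)
        J = big.restrict(subset)
        Tx = J.prefix()
        # second-to-last IDFT leaf pruned
        Ty = J.restrict(J.leaf_set - {J.idft[-2]})
        core = Tx.prefix()
        r = core.rightmost
        if Tx.rightmost == Ty.rightmost:
            continue
        tree = big
        if rng.random() < 0.34:
            alt = random_canonical(rng, n_min=big.n_leaves, n_max=big.n_leaves,
                                   multifurcation_prob=mf)
            if alt.displays(Tx) and alt.displays(Ty):
                tree = alt
        out.append((tree, fst_of(Tx), fst_of(Ty), r))
        if len(out) < n_instances:
            out.append((tree, fst_of(Ty), fst_of(Tx), core.rightmost))
    return out[:n_instances]
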