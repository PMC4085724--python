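"""Tree model, Newick I/O, canonical form and the core tree algebra."""

import random

import pytest

from phylomfst import (
    DuplicateLeafError,
    InvalidTreeError,
    LeafNotFoundError,
    LabelMap,
    canonicalize,
    displays,
    is_isomorphic,
    parse_newick,
    read_collection,
    write_newick,
)
from phylomfst.trees import (
    PhyloTree,
    prefix_tree,
    prune_leaf,
    restrict,
    shape_leaves,
    tree_from_newick_ints,
)

from conftest import T, random_canonical, shuffled_copy


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def test_parse_simple_tree():
    lm = LabelMap()
    tree = parse_newick("(1,(2,3));", lm)
    assert canonicalize(tree).newick(lm) == "(1,(2,3));"
    assert lm.name_to_int == {"1": 1, "2": 2, "3": 3}


def test_parse_strips_lengths_labels_and_comments():
    lm = LabelMap.from_names(["A", "B", "C"])
    tree = parse_newick("((A:0.1,B:0.2)x:0.3,C);", lm)
    assert canonicalize(tree).shape == ((1, 2), 3)


def test_parse_duplicate_leaf_is_error():
    with pytest.raises(DuplicateLeafError):
        parse_newick("(A,A);", LabelMap())


def test_parse_malformed_is_error():
    from phylomfst import NewickParseError

    with pytest.raises(NewickParseError):
        parse_newick("((1,2;", LabelMap())


def test_root_unifurcation_suppressed_on_ingest():
    tree = parse_newick("((1,(2,3)));", LabelMap())
    assert canonicalize(tree).shape == (1, (2, 3))


def test_write_single_leaf():
    assert write_newick(canonicalize(1)) == "1;"


def test_label_map_is_lexicographic_and_order_independent():
    trees_a, lm_a = read_collection("(b,(a,c));\n(c,(a,b));")
    trees_b, lm_b = read_collection("(c,(a,b));\n(b,(a,c));")
    assert lm_a.name_to_int == lm_b.name_to_int == {"a": 1, "b": 2, "c": 3}
    assert canonicalize(trees_a[0]).shape == canonicalize(trees_b[1]).shape


def test_newick_roundtrip_random_trees():
    rng = random.Random(11)
    for _ in range(200):
        ct = random_canonical(rng, multifurcation_prob=rng.choice([0.0, 0.5]))
        lm = LabelMap.from_names(f"x{lbl:03d}" for lbl in sorted(ct.leaf_set))
        back = parse_newick(ct.newick(lm), lm)
        assert canonicalize(back).shape == ct.shape


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        ("((5,3),(2,4),1);", "(1,(2,4),(3,5));"),
        ("(1,(2,3));", "(1,(2,3));"),
        ("((3,2),1);", "(1,(2,3));"),
    ],
)
def test_canonicalize_examples(raw, expected):
    assert T(raw).newick() == expected


def test_canonicalize_idempotent_and_isomorphism_invariant():
    rng = random.Random(23)
    for _ in range(300):
        ct = random_canonical(rng, multifurcation_prob=rng.choice([0.0, 0.4]))
        assert canonicalize(ct.shape).shape == ct.shape  # idempotence
        assert canonicalize(shuffled_copy(ct, rng)).shape == ct.shape


def test_isomorphism_examples():
    assert is_isomorphic(T("((3,2),1);"), T("(1,(2,3));"))
    assert not is_isomorphic(T("(1,(2,3));"), T("((1,2),3);"))


# ---------------------------------------------------------------------------
# IDFT / prefix / heaviest subtree
# ---------------------------------------------------------------------------

def test_idft_examples():
    assert T("(1,(2,4),(3,5));").idft == (1, 2, 4, 3, 5)
    assert T("(1,(2,3));").idft == (1, 2, 3)


def test_idft_starts_at_global_minimum():
    rng = random.Random(31)
    for _ in range(50):
        ct = random_canonical(rng)
        assert ct.idft[0] == min(ct.leaf_set)


def test_prefix_examples():
    assert T("(1,(2,4),(3,5));").prefix().newick() == "(1,(2,4),3);"
    assert T("(1,(2,3));").prefix().newick() == "(1,2);"
    assert T("((1,2),3,4);").prefix().prefix().newick() == "(1,2);"


def test_prefix_of_single_leaf_rejected():
    with pytest.raises(InvalidTreeError):
        canonicalize(1).prefix()


def test_pruning_last_two_idft_leaves_stays_canonical():
    # structural prune of the last or second-to-last IDFT leaf must equal the
    # (independently canonicalized) restriction without any re-sorting
    rng = random.Random(41)
    for _ in range(150):
        ct = random_canonical(rng, multifurcation_prob=rng.choice([0.0, 0.4]))
        for leaf in (ct.idft[-1], ct.idft[-2]):
            pruned = prune_leaf(ct, leaf)
            assert canonicalize(pruned.shape).shape == pruned.shape
            assert pruned.shape == ct.restrict(ct.leaf_set - {leaf}).shape


def test_heaviest_subtree_examples():
    assert T("((1,2),(3,4));").heaviest_subtree().newick() == "(3,4);"
    assert T("(1,2,3);").heaviest_subtree().newick() == "(1,2,3);"
    assert T("(1,(2,(3,4)));").heaviest_subtree().newick() == "(3,4);"


# ---------------------------------------------------------------------------
# prune / graft / suppress
# ---------------------------------------------------------------------------

def test_prune_examples():
    assert prune_leaf(T("(1,(2,3));"), 3).newick() == "(1,2);"
    assert prune_leaf(T("((1,2),3);"), 1).newick() == "(2,3);"
    assert prune_leaf(T("(1,2,3,4);"), 4).newick() == "(1,2,3);"


def test_prune_absent_leaf_is_error():
    with pytest.raises(LeafNotFoundError):
        prune_leaf(T("(1,(2,3));"), 9)


def test_graft_examples():
    base = T("((1,2),3);")

    pt = base.to_phylo()
    pt.graft_leaf(4, on_edge=pt.find_leaf(3))
    assert canonicalize(pt).newick() == "((1,2),(3,4));"

    pt = base.to_phylo()
    pt.graft_leaf(4, on_node=pt.root)
    assert canonicalize(pt).newick() == "((1,2),3,4);"

    pt = base.to_phylo()
    pt.graft_leaf(4, on_top=True)
    assert canonicalize(pt).newick() == "(((1,2),3),4);"


def test_graft_duplicate_leaf_is_error():
    pt = T("((1,2),3);").to_phylo()
    with pytest.raises(DuplicateLeafError):
        pt.graft_leaf(2, on_top=True)


def test_prune_inverts_graft_all_attachment_kinds():
    rng = random.Random(53)
    for _ in range(100):
        ct = random_canonical(rng, multifurcation_prob=rng.choice([0.0, 0.4]))
        new = max(ct.leaf_set) + 1
        pt = ct.to_phylo()
        internal = [n for n in pt.iter_nodes() if not n.is_leaf]
        non_root = [n for n in pt.iter_nodes() if n.parent is not None]
        for kwargs in (
            {"on_top": True},
            {"on_node": rng.choice(internal)},
            {"on_edge": rng.choice(non_root)},
        ):
            work = ct.to_phylo()
            # re-resolve the chosen node inside the working copy by position
            if "on_node" in kwargs:
                nodes = [n for n in work.iter_nodes() if not n.is_leaf]
                kwargs = {"on_node": rng.choice(nodes)}
            elif "on_edge" in kwargs:
                nodes = [n for n in work.iter_nodes() if n.parent is not None]
                kwargs = {"on_edge": rng.choice(nodes)}
            work.graft_leaf(new, **kwargs)
            work.validate()
            assert prune_leaf(work, new).shape == ct.shape


def test_suppress_node_contracts_unary_chain():
    pt = PhyloTree.from_shape((1, (2, 3)))
    inner = [n for n in pt.iter_nodes() if not n.is_leaf and n.parent is not None][0]
    with pytest.raises(InvalidTreeError):
        pt.suppress_node(inner)  # two children: not suppressible
    leaf2 = pt.find_leaf(2)
    inner.remove_child(leaf2)
    pt.suppress_node(inner)
    assert canonicalize(pt).shape == (1, 3)


# ---------------------------------------------------------------------------
# restrict / displays
# ---------------------------------------------------------------------------

def test_restrict_examples():
    assert restrict(T("(1,(2,(3,4)));"), {1, 3, 4}).newick() == "(1,(3,4));"
    ct = T("(1,(2,(3,4)));")
    assert ct.restrict(ct.leaf_set).shape == ct.shape
    # rooted at the LCA of the kept leaves
    assert restrict(T("(1,(2,(3,4)));"), {3, 4}).newick() == "(3,4);"


def test_restrict_missing_label_is_error():
    with pytest.raises(LeafNotFoundError):
        restrict(T("(1,(2,3));"), {1, 9})


def test_restrict_nesting_property():
    rng = random.Random(61)
    for _ in range(200):
        ct = random_canonical(rng, n_min=5, multifurcation_prob=rng.choice([0.0, 0.4]))
        leaves = sorted(ct.leaf_set)
        a = set(rng.sample(leaves, rng.randint(2, len(leaves))))
        b = set(rng.sample(sorted(a), rng.randint(1, len(a))))
        assert ct.restrict(a).restrict(b).shape == ct.restrict(b).shape


def test_displays_examples():
    big = T("(1,(2,(3,4)));")
    assert big.displays(big.restrict({1, 3, 4}))
    assert not displays(T("(1,(2,3));"), T("((1,2),3);"))
    # a star does not display a resolved triplet
    assert not displays(T("(1,2,3,4);"), T("(1,(2,3));"))


def test_every_internal_node_keeps_two_children():
    rng = random.Random(71)
    for _ in range(60):
        ct = random_canonical(rng, n_min=5, multifurcation_prob=rng.choice([0.0, 0.5]))
        sub = ct.restrict(rng.sample(sorted(ct.leaf_set), 3))
        for shape in (ct.prefix().shape, sub.shape):
            stack = [shape]
            while stack:
                s = stack.pop()
                if isinstance(s, tuple):
                    assert len(s) >= 2
                    stack.extend(s)
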