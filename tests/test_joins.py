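"""Join classification, support aggregation and construction."""

import pytest

from phylomfst import SupportSet, build_lca_depth_table
from phylomfst.joins import (
    FrequentSubtree,
    JoinType,
    classify_join_in_tree,
    construct_join,
    join_support,
)
from phylomfst.oracle import reference_join_classify

from conftest import T, fst_of, join_instances


def classify(tree_nk, r, Tx, Ty):
    tab = build_lca_depth_table(T(tree_nk))
    return classify_join_in_tree(
        tab, r, Tx.rightmost, Ty.rightmost, Tx.depth_p_rml, Ty.depth_p_rml
    )


@pytest.fixture
def pair_shallow():
    # common core ((1,2),3) with r=3; both operands attach at depth 0
    return fst_of(T("((1,2),3,4);")), fst_of(T("((1,2),3,5);"))


def test_classify_type1_and_type2(pair_shallow):
    Tx, Ty = pair_shallow
    assert classify("((1,2),3,4,5);", 3, Tx, Ty) is JoinType.TYPE1
    assert classify("((1,2),3,(4,5));", 3, Tx, Ty) is JoinType.TYPE2


def test_classify_type4():
    Tx = fst_of(T("((1,2),(3,4));"))  # depth of rightmost-leaf parent: 1
    Ty = fst_of(T("((1,2),3,5);"))  # depth 0
    assert classify("((1,2),(3,4),5);", 3, Tx, Ty) is JoinType.TYPE4


def test_classify_type3():
    Tx = fst_of(T("((1,2),(3,4));"))
    Ty = fst_of(T("((1,2),(3,5));"))
    assert classify("((1,2),((3,4),5));", 3, Tx, Ty) is JoinType.TYPE3


def test_classify_reversed_depths_is_none():
    # depth_py > depth_px: the pair can only join in the other order
    Tx = fst_of(T("((1,2),3,5);"))
    Ty = fst_of(T("((1,2),(3,4));"))
    assert classify("((1,2),(3,4),5);", 3, Tx, Ty) is JoinType.NONE


def test_classify_missing_leaf_is_none(pair_shallow):
    Tx, Ty = pair_shallow
    assert classify("((1,2),3,4,6);", 3, Tx, Ty) is JoinType.NONE


def test_classifier_matches_reference_on_random_instances():
    mismatches = 0
    for tree, Tx, Ty, r in join_instances(500, seed=2024):
        tab = build_lca_depth_table(tree)
        got = classify_join_in_tree(
            tab, r, Tx.rightmost, Ty.rightmost, Tx.depth_p_rml, Ty.depth_p_rml
        )
        if got is JoinType.TYPE3 and Ty.nchild_p_rml != 2:
            got = JoinType.NONE
        want = reference_join_classify(tree, Tx, Ty)
        mismatches += got is not want
    assert mismatches == 0


# -- join_support ------------------------------------------------------------

def _fsts(tx_nk, ty_nk, m):
    return (
        FrequentSubtree.from_tree(T(tx_nk), SupportSet.full(m)),
        FrequentSubtree.from_tree(T(ty_nk), SupportSet.full(m)),
    )


def test_join_support_majority_type1():
    newicks = ["((1,2),3,4,5);", "((1,2),3,4,5);", "((1,2),3,(4,5));"]
    tables = [build_lca_depth_table(T(nk), i) for i, nk in enumerate(newicks)]
    Tx, Ty = _fsts("((1,2),3,4);", "((1,2),3,5);", 3)
    out = join_support(Tx, Ty, 3, tables, threshold=2)
    assert out.join_type is JoinType.TYPE1
    assert sorted(out.support.indices()) == [0, 1]
    assert out.joined.tree.newick() == "((1,2),3,4,5);"

    assert join_support(Tx, Ty, 3, tables, threshold=3).join_type is JoinType.NONE


def test_join_support_unanimous():
    newicks = ["((1,2),3,4,5);"] * 3
    tables = [build_lca_depth_table(T(nk), i) for i, nk in enumerate(newicks)]
    Tx, Ty = _fsts("((1,2),3,4);", "((1,2),3,5);", 3)
    out = join_support(Tx, Ty, 3, tables, threshold=3)
    assert out.join_type is JoinType.TYPE1 and out.support.count == 3


def test_join_support_type3_needs_binary_parent():
    # the nested join requires the second operand's rightmost-leaf parent to
    # be binary; with a wider parent the same trees support no join
    newicks = ["((1,2),((3,4),5));"] * 2
    tables = [build_lca_depth_table(T(nk), i) for i, nk in enumerate(newicks)]
    Tx, Ty = _fsts("((1,2),(3,4));", "((1,2),(3,5));", 2)
    ok = join_support(Tx, Ty, 3, tables, threshold=2)
    assert ok.join_type is JoinType.TYPE3
    wide = FrequentSubtree(
        tree=Ty.tree, support=Ty.support, depth_p_rml=1, nchild_p_rml=3, rightmost=5
    )
    assert join_support(Tx, wide, 3, tables, threshold=2).join_type is JoinType.NONE


def test_join_support_subset_of_operand_supports():
    newicks = ["((1,2),3,4,5);", "((1,2),3,(4,5));", "(1,(2,3),4,5);"]
    tables = [build_lca_depth_table(T(nk), i) for i, nk in enumerate(newicks)]
    Tx = FrequentSubtree.from_tree(T("((1,2),3,4);"), SupportSet.from_indices([0, 1], 3))
    Ty = FrequentSubtree.from_tree(T("((1,2),3,5);"), SupportSet.from_indices([0, 1], 3))
    out = join_support(Tx, Ty, 3, tables, threshold=1)
    assert out.exists
    assert out.support.issubset(Tx.support & Ty.support)


# -- construct_join ----------------------------------------------------------

@pytest.mark.parametrize(
    "tx, ty, jt, expected",
    [
        ("((1,2),3,4);", "((1,2),3,5);", JoinType.TYPE1, "((1,2),3,4,5);"),
        ("((1,2),3,4);", "((1,2),3,5);", JoinType.TYPE2, "((1,2),3,(4,5));"),
        ("((1,2),(3,4));", "((1,2),(3,5));", JoinType.TYPE3, "((1,2),((3,4),5));"),
        ("((1,2),(3,4));", "((1,2),3,5);", JoinType.TYPE4, "((1,2),(3,4),5);"),
    ],
)
def test_construct_join_examples(tx, ty, jt, expected):
    joined = construct_join(fst_of(T(tx)), fst_of(T(ty)), jt)
    assert joined.newick() == expected
    assert joined.prefix().shape == T(tx).shape
    assert joined.displays(T(ty))


def test_constructed_joins_satisfy_join_contract_on_random_instances():
    # every join the classifier accepts must be canonical, extend the first
    # operand as prefix, and display the second operand
    checked = 0
    for tree, Tx, Ty, r in join_instances(400, seed=77):
        tab = build_lca_depth_table(tree)
        jt = classify_join_in_tree(
            tab, r, Tx.rightmost, Ty.rightmost, Tx.depth_p_rml, Ty.depth_p_rml
        )
        if jt is JoinType.NONE or (jt is JoinType.TYPE3 and Ty.nchild_p_rml != 2):
            continue
        joined = construct_join(Tx, Ty, jt)  # raises on contract violation
        from phylomfst import canonicalize

        assert canonicalize(joined.shape).shape == joined.shape
        assert joined.prefix().shape == Tx.tree.shape
        assert joined.displays(Ty.tree)
        assert joined.rightmost == Ty.rightmost
        checked += 1
    assert checked >= 100


def test_ordered_pair_completeness():
    # pruning the last / second-to-last IDFT leaves of any displayed subtree
    # yields a pair that joins back to it under some type
    import random

    from conftest import random_canonical

    rng = random.Random(13)
    for _ in range(60):
        big = random_canonical(rng, n_min=5, n_max=10)
        sub = big.restrict(rng.sample(sorted(big.leaf_set), rng.randint(4, big.n_leaves)))
        Tx = fst_of(sub.prefix())
        Ty = fst_of(sub.restrict(sub.leaf_set - {sub.idft[-2]}))
        if Tx.rightmost == Ty.rightmost:
            continue
        r = Tx.tree.prefix().rightmost
        tab = build_lca_depth_table(big)
        jt = classify_join_in_tree(
            tab, r, Tx.rightmost, Ty.rightmost, Tx.depth_p_rml, Ty.depth_p_rml
        )
        assert jt is not JoinType.NONE
        assert construct_join(Tx, Ty, jt).shape == sub.shape
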