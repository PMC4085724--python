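"""Deterministic generator of tree collections with planted agreement structure.

The generator emulates the kind of collection the miner targets: bootstrap
replicates of a phylogenetic analysis, i.e. many estimates of one underlying
topology in which a few taxa wander.  A base tree is drawn uniformly at
random (sequential leaf attachment), and each replicate applies a number of
*leaf prune-and-regraft* moves — the perturbation unit is a single taxon
re-placement, the failure mode agreement subtrees are designed to survive —
plus optional *rogue* taxa that are re-placed uniformly at random in every
replicate, optional multifurcations (random edge collapses), and optional
partial leaf-set overlap (each replicate restricted to a random fraction of
the universe).

A single seeded RNG stream drives each generator call, so the same spec and
seed always reproduce the identical collection.  The per-replicate move log
(which leaves were touched / dropped) is returned so tests can assert the
exact planted guarantee: the base tree restricted to a replicate's untouched
leaves is displayed by that replicate, by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ConfigError
from .trees import (
    CanonicalTree,
    LabelMap,
    Node,
    PhyloTree,
    canonicalize,
    write_collection_file,
)

__all__ = ["SynthSpec", "CollectionBundle", "random_tree", "perturb_collection", "write_collection"]


@dataclass
class SynthSpec:
    """Conditions for one synthetic collection.

    Defaults describe a mild bootstrap-like setting: ten binary replicates of
    a ten-taxon tree, one taxon re-placed per replicate, full leaf overlap.
    """

    n_leaves: int = 10
    m_trees: int = 10
    moves_per_tree: int = 1
    n_rogue: int = 0
    multifurcation_prob: float = 0.0
    overlap_frac: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3 or self.m_trees < 1:
            raise ConfigError("need n_leaves >= 3 and m_trees >= 1")
        if min(self.moves_per_tree, self.n_rogue) < 0:
            raise ConfigError("counts must be non-negative")
        if not (0.0 <= self.multifurcation_prob <= 1.0):
            raise ConfigError("multifurcation_prob must lie in [0, 1]")
        if not (0.0 < self.overlap_frac <= 1.0):
            raise ConfigError("overlap_frac must lie in (0, 1]")
        if round(self.overlap_frac * self.n_leaves) < 3:
            raise ConfigError("overlap_frac leaves fewer than 3 leaves per tree")
        if (self.moves_per_tree > 0 or self.n_rogue > 0) and self.n_leaves < 4:
            raise ConfigError("perturbations need at least 4 leaves")


@dataclass
class CollectionBundle:
    trees: list[CanonicalTree]
    base: CanonicalTree
    label_map: LabelMap
    # per replicate: labels whose placement was touched, and labels kept
    move_log: list[dict[str, frozenset[int]]] = field(default_factory=list)


def _graft_positions(tree: PhyloTree) -> list[tuple[str, Optional[Node]]]:
    """Deterministically ordered attachment points: every internal node, every
    edge, and the top of the root."""
    positions: list[tuple[str, Optional[Node]]] = [("top", None)]
    stack = [tree.root]
    while stack:
        n = stack.pop()
        if not n.is_leaf:
            positions.append(("node", n))
        if n.parent is not None:
            positions.append(("edge", n))
        stack.extend(reversed(n.children))
    return positions


def _graft_random(tree: PhyloTree, label: int, rng: random.Random) -> None:
    kind, node = rng.choice(_graft_positions(tree))
    if kind == "top":
        tree.graft_leaf(label, on_top=True)
    elif kind == "node":
        tree.graft_leaf(label, on_node=node)
    else:
        tree.graft_leaf(label, on_edge=node)


def random_tree(
    labels: Iterable[int],
    seed: Optional[int] = None,
    multifurcation_prob: float = 0.0,
    rng: Optional[random.Random] = None,
) -> CanonicalTree:
    """Uniform random binary topology by sequential leaf attachment, then
    independent edge collapses with the given probability (1.0 gives the
    star tree)."""
    labels = sorted(set(labels))
    if len(labels) < 3:
        raise ConfigError("need at least 3 labels")
    if rng is None:
        rng = random.Random(seed)
    order = labels[:]
    rng.shuffle(order)
    root = Node()
    root.add_child(Node(order[0]))
    root.add_child(Node(order[1]))
    tree = PhyloTree(root)
    for label in order[2:]:
        edges = [n for n in tree.iter_nodes() if n.parent is not None]
        choice = rng.randrange(len(edges) + 1)
        if choice == len(edges):
            tree.graft_leaf(label, on_top=True)
        else:
            tree.graft_leaf(label, on_edge=edges[choice])
    if multifurcation_prob > 0.0:
        internal = [
            n for n in tree.iter_nodes() if not n.is_leaf and n.parent is not None
        ]
        for n in internal:
            if rng.random() < multifurcation_prob:
                parent = n.parent
                for c in list(n.children):
                    n.remove_child(c)
                    parent.add_child(c)
                parent.remove_child(n)
    return canonicalize(tree)


def perturb_collection(spec: SynthSpec) -> CollectionBundle:
    """Generate the collection described by ``spec`` (see module docstring)."""
    rng = random.Random(spec.seed)
    labels = list(range(1, spec.n_leaves + 1))
    base = random_tree(labels, multifurcation_prob=spec.multifurcation_prob, rng=rng)
    rogues = frozenset(rng.sample(labels, spec.n_rogue)) if spec.n_rogue else frozenset()
    keep_size = max(3, round(spec.overlap_frac * spec.n_leaves))

    trees: list[CanonicalTree] = []
    move_log: list[dict[str, frozenset[int]]] = []
    for _ in range(spec.m_trees):
        rep = base.to_phylo()
        touched: set[int] = set()
        for rogue in sorted(rogues):
            rep.prune_leaf(rogue)
            _graft_random(rep, rogue, rng)
            touched.add(rogue)
        for _mv in range(spec.moves_per_tree):
            label = rng.choice(sorted(rep.leaf_labels()))
            rep.prune_leaf(label)
            _graft_random(rep, label, rng)
            touched.add(label)
        kept = frozenset(rep.leaf_labels())
        if keep_size < spec.n_leaves:
            kept = frozenset(rng.sample(sorted(kept), keep_size))
        rep_ct = canonicalize(rep).restrict(kept)
        trees.append(rep_ct)
        move_log.append({"touched": frozenset(touched), "kept": kept})

    label_map = LabelMap.from_names(f"t{label:03d}" for label in labels)
    return CollectionBundle(trees=trees, base=base, label_map=label_map, move_log=move_log)


def write_collection(
    bundle_or_trees, path: str, label_map: Optional[LabelMap] = None
) -> None:
    """Write a collection (bundle or plain sequence) as newline-delimited
    Newick with a label-map sidecar; round-trips through the Newick reader."""
    if isinstance(bundle_or_trees, CollectionBundle):
        trees: Sequence = bundle_or_trees.trees
        label_map = bundle_or_trees.label_map if label_map is None else label_map
    else:
        trees = bundle_or_trees
    write_collection_file(trees, path, label_map)
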