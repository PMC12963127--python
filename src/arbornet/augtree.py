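"""Augmented trees: unrooted trees with a {PLAIN, AUG} vertex marking.

An augmented tree is an unrooted (possibly partially subdivided) tree
together with a marking of its vertices.  Leaves are always PLAIN,
subdivision points are always AUG, and the remaining interior vertices may
carry either mark; the AUG non-subdivision vertices are the *augmentation
vertices*.  In the network setting (:mod:`arbornet.arboreal`) augmentation
vertices record reticulations — horizontal gene transfer recipients — of a
multi-rooted network whose directions have been forgotten.

The central construction here is :func:`induced_eqts`: the enhanced quartet
tree system (γ_T, ν_T) an augmented phylogenetic tree induces, which
encodes the tree uniquely (see :func:`arbornet.eqts.reconstruct_augmented_tree`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Iterable

from . import treecore
from .treecore import TreeError, TreeMode, UnrootedTree, median, write_newick

__all__ = [
    "Mark",
    "AugmentedTree",
    "validate_augmented",
    "read_augmented_newick",
    "write_augmented_newick",
    "augmentation_equivalent",
    "induced_eqts",
]

log = logging.getLogger(__name__)

AUG_LABEL = "AUG"


class Mark(Enum):
    PLAIN = "PLAIN"
    AUG = "AUG"

    def __invert__(self) -> "Mark":
        return Mark.AUG if self is Mark.PLAIN else Mark.PLAIN


class AugmentedTree:
    """An unrooted tree plus the vertex marking ν.

    ``aug`` is the set of AUG vertex ids.  Validation enforces that leaves
    are PLAIN and subdivision points AUG.
    """

    def __init__(self, tree: UnrootedTree, aug: Iterable[int]):
        self.tree = tree
        self.aug = frozenset(aug)
        validate_augmented(self)

    def mark(self, v: int) -> Mark:
        return Mark.AUG if v in self.aug else Mark.PLAIN

    def aug_vertices(self) -> FrozenSet[int]:
        """𝒜_𝒯: AUG vertices that are not subdivision points."""
        sub = set(self.tree.subdivision_points())
        return frozenset(v for v in self.aug if v not in sub)

    def augmentation_points(self) -> FrozenSet[int]:
        return frozenset(self.tree.subdivision_points())

    @property
    def taxa(self) -> FrozenSet[str]:
        return self.tree.taxa

    def __repr__(self) -> str:
        return f"<AugmentedTree {write_augmented_newick(self)}>"


def validate_augmented(cand: AugmentedTree) -> AugmentedTree:
    """Enforce the augmentation-map invariants, returning the tree or raising."""
    tree, aug = cand.tree, cand.aug
    for v in aug:
        if v not in tree.graph:
            raise TreeError(f"marked vertex {v} not in tree")
        if tree.is_leaf(v):
            raise TreeError(f"leaf vertex {v} ({tree.leaf_map[v]!r}) cannot be AUG")
    for v in tree.subdivision_points():
        if v not in aug:
            raise TreeError(f"subdivision point {v} must be AUG")
    return cand


# ---------------------------------------------------------------------------
# I/O: Newick dialect with internal label "AUG"
# ---------------------------------------------------------------------------


def read_augmented_newick(
    text: str, mode: TreeMode = TreeMode.PHYLOGENETIC
) -> AugmentedTree:
    """Read the marked dialect: internal label exactly ``AUG`` marks a vertex.

    Other internal labels are ignored (with a log message); leaves carry
    taxa only and must not be named ``AUG``.
    """
    tree, labels = treecore._read_newick_with_labels(text, mode)
    if AUG_LABEL in tree.taxa:
        raise TreeError(f"leaf taxon {AUG_LABEL!r} is reserved for marks")
    aug = set()
    for v, lab in labels.items():
        if lab == AUG_LABEL:
            aug.add(v)
        else:
            log.info("ignoring internal node label %r", lab)
    aug.update(tree.subdivision_points())
    return AugmentedTree(tree, aug)


def write_augmented_newick(t: AugmentedTree) -> str:
    labels = {v: AUG_LABEL for v in t.aug}
    return write_newick(t.tree, vertex_labels=labels)


def augmentation_equivalent(t1: AugmentedTree, t2: AugmentedTree) -> bool:
    """Taxon-preserving isomorphism that also preserves marks, via canonical forms."""
    if t1.taxa != t2.taxa:
        return False
    return write_augmented_newick(t1) == write_augmented_newick(t2)


# ---------------------------------------------------------------------------
# The induced enhanced quartet tree system (γ_T, ν_T)
# ---------------------------------------------------------------------------


def induced_eqts(t: AugmentedTree):
    """(γ_T, ν_T): the enhanced quartet tree system induced by an augmented tree.

    The support is the set of quartet trees displayed by the underlying
    phylogenetic tree.  For a displayed quartet xy|tz, γ counts the
    augmentation vertices strictly interior to the path connecting the
    path from x to y with the path from t to z — i.e. strictly between
    median(x,y,t) and median(t,z,x) — and the record's two marks are the
    marks of those two medians.

    Raises for star trees and fewer than 4 leaves, where no quartet exists.
    """
    from .eqts import EnhancedQuartetSystem, QuartetRecord

    tree = t.tree
    if tree.mode is not TreeMode.PHYLOGENETIC:
        raise TreeError("the induced system is defined for phylogenetic trees")
    if len(tree.taxa) < 4:
        raise TreeError("need at least 4 taxa")
    if tree.is_star():
        raise TreeError("a star tree displays no quartet tree")
    aug_vertices = t.aug_vertices()
    table: Dict[treecore.QuartetTree, QuartetRecord] = {}
    for q in treecore.displayed_quartets(tree):
        a, b = q.pair_1
        c, d = q.pair_2
        near = median(tree, a, b, c)
        far = median(tree, c, d, a)
        path = tree.path(near, far)
        gamma = sum(1 for v in path[1:-1] if v in aug_vertices)
        table[q] = QuartetRecord(
            gamma=gamma,
            nu_near=t.mark(near),
            nu_far=t.mark(far),
        )
    return EnhancedQuartetSystem(ground=tree.taxa, table=table)
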