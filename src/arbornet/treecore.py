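"""Unrooted phylogenetic trees and their split/quartet algebra.

This module provides the leaf-labelled tree machinery everything else in
:mod:`arbornet` builds on: unrooted trees held as undirected graphs, the
splits induced by their edges, the quartet trees they display, medians,
restrictions to leaf subsets, and the classical correspondence between
compatible split systems and trees (the Split-Equivalence Theorem) together
with the reconstruction of a tree's non-trivial splits from its displayed
quartets.

Taxa are plain strings.  Vertices are opaque integers; taxa live only on
leaves, and interior vertices are addressed externally through median
triples.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import dendropy
import networkx as nx

__all__ = [
    "TreeError",
    "TreeMode",
    "Split",
    "SplitSystem",
    "QuartetTree",
    "UnrootedTree",
    "check_taxon",
    "read_newick",
    "write_newick",
    "splits_of_tree",
    "is_compatible",
    "splits_compatible",
    "tree_from_splits",
    "displayed_quartets",
    "quartet_topology",
    "restrict_tree",
    "median",
    "splits_from_quartets",
    "quartets_of_split",
    "split_displays_quartet",
]

Taxon = str

_TAXON_RE = re.compile(r"^[A-Za-z0-9_.^-]+$")


class TreeError(ValueError):
    """Malformed tree, split system or Newick input."""


class TreeMode(Enum):
    PHYLOGENETIC = "phylogenetic"
    PARTIALLY_SUBDIVIDED = "partially_subdivided"


def check_taxon(label: str) -> str:
    """Validate a taxon label (no whitespace or Newick metacharacters)."""
    if not isinstance(label, str) or not _TAXON_RE.match(label):
        raise TreeError(f"invalid taxon label: {label!r}")
    return label


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """A (partial) split ``A|B``: two disjoint non-empty taxon sets on a ground set.

    Canonical form stores the part containing the lexicographically smallest
    taxon of ``A ∪ B`` as ``part_a``, so equal splits compare equal.
    """

    ground: FrozenSet[Taxon]
    part_a: FrozenSet[Taxon]
    part_b: FrozenSet[Taxon]

    def __init__(self, ground: Iterable[Taxon], part_a: Iterable[Taxon], part_b: Iterable[Taxon]):
        ground = frozenset(ground)
        a, b = frozenset(part_a), frozenset(part_b)
        if not a or not b:
            raise TreeError("split parts must be non-empty")
        if a & b:
            raise TreeError("split parts must be disjoint")
        if not (a | b) <= ground:
            raise TreeError("split parts must lie in the ground set")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "ground", ground)
        object.__setattr__(self, "part_a", a)
        object.__setattr__(self, "part_b", b)

    @property
    def is_full(self) -> bool:
        return self.part_a | self.part_b == self.ground

    @property
    def is_trivial(self) -> bool:
        return min(len(self.part_a), len(self.part_b)) == 1

    def __str__(self) -> str:
        fmt = lambda p: ",".join(sorted(p))
        return f"{fmt(self.part_a)}|{fmt(self.part_b)}"


@dataclass(frozen=True)
class SplitSystem:
    """A set of splits sharing one ground set."""

    ground: FrozenSet[Taxon]
    splits: FrozenSet[Split]

    def __init__(self, ground: Iterable[Taxon], splits: Iterable[Split]):
        ground = frozenset(ground)
        splits = frozenset(splits)
        for s in splits:
            if s.ground != ground:
                raise TreeError("all splits must share the system's ground set")
        object.__setattr__(self, "ground", ground)
        object.__setattr__(self, "splits", splits)

    def __iter__(self):
        return iter(self.splits)

    def __len__(self) -> int:
        return len(self.splits)

    def nontrivial(self) -> "SplitSystem":
        return SplitSystem(self.ground, (s for s in self.splits if not s.is_trivial))


# ---------------------------------------------------------------------------
# Quartet trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuartetTree:
    """The binary 4-leaf tree ``ab|cd`` separating ``{a,b}`` from ``{c,d}``.

    Canonical written form: each pair internally sorted, and ``pair_1`` is
    the pair containing the overall smallest taxon.
    """

    pair_1: Tuple[Taxon, Taxon]
    pair_2: Tuple[Taxon, Taxon]

    def __init__(self, a: Taxon, b: Taxon, c: Taxon, d: Taxon):
        if len({a, b, c, d}) != 4:
            raise TreeError(f"quartet needs 4 distinct taxa, got {a, b, c, d}")
        p1 = tuple(sorted((a, b)))
        p2 = tuple(sorted((c, d)))
        if p2[0] < p1[0]:
            p1, p2 = p2, p1
        object.__setattr__(self, "pair_1", p1)
        object.__setattr__(self, "pair_2", p2)

    @property
    def taxa(self) -> FrozenSet[Taxon]:
        return frozenset(self.pair_1) | frozenset(self.pair_2)

    def same_side(self, x: Taxon, y: Taxon) -> bool:
        return {x, y} == set(self.pair_1) or {x, y} == set(self.pair_2)

    def __str__(self) -> str:
        return f"{self.pair_1[0]}{self.pair_1[1]}|{self.pair_2[0]}{self.pair_2[1]}"

    @property
    def split(self) -> Split:
        """The quartet split induced by deleting the interior edge."""
        return Split(self.taxa, self.pair_1, self.pair_2)


# ---------------------------------------------------------------------------
# Unrooted trees
# ---------------------------------------------------------------------------


class UnrootedTree:
    """An unrooted leaf-labelled tree.

    Parameters
    ----------
    edges:
        Unordered vertex-id pairs.
    leaf_map:
        Mapping from leaf vertex id to taxon label; must cover exactly the
        degree-1 vertices.
    mode:
        ``PHYLOGENETIC`` forbids degree-2 vertices; ``PARTIALLY_SUBDIVIDED``
        allows them, but never adjacent to a leaf.
    """

    def __init__(
        self,
        edges: Iterable[Tuple[int, int]],
        leaf_map: Dict[int, Taxon],
        mode: TreeMode = TreeMode.PHYLOGENETIC,
    ):
        g = nx.Graph()
        g.add_edges_from(edges)
        if len(g) == 0:
            raise TreeError("empty tree")
        if not nx.is_tree(g):
            raise TreeError("edge set is not a tree (must be connected and acyclic)")
        self.graph = g
        self.leaf_map = dict(leaf_map)
        self.mode = mode
        self._validate()
        self.taxon_map = {t: v for v, t in self.leaf_map.items()}

    def _validate(self) -> None:
        g = self.graph
        deg = dict(g.degree())
        leaves = {v for v, d in deg.items() if d == 1}
        if set(self.leaf_map) != leaves:
            missing = leaves - set(self.leaf_map)
            extra = set(self.leaf_map) - leaves
            raise TreeError(
                f"leaf_map must label exactly the degree-1 vertices "
                f"(unlabelled: {sorted(missing)}, interior labelled: {sorted(extra)})"
            )
        taxa = list(self.leaf_map.values())
        for t in taxa:
            check_taxon(t)
        if len(set(taxa)) != len(taxa):
            raise TreeError("duplicate taxon label")
        deg2 = {v for v, d in deg.items() if d == 2}
        if self.mode is TreeMode.PHYLOGENETIC and deg2:
            raise TreeError(f"degree-2 vertex {sorted(deg2)} in a phylogenetic tree")
        for v in deg2:
            if any(nb in leaves for nb in g[v]):
                raise TreeError(f"subdivision point {v} adjacent to a leaf")

    # -- basic accessors ---------------------------------------------------

    @property
    def taxa(self) -> FrozenSet[Taxon]:
        return frozenset(self.leaf_map.values())

    def leaf_of(self, taxon: Taxon) -> int:
        try:
            return self.taxon_map[taxon]
        except KeyError:
            raise TreeError(f"taxon {taxon!r} not in tree") from None

    def degree(self, v: int) -> int:
        return self.graph.degree(v)

    def is_leaf(self, v: int) -> bool:
        return self.graph.degree(v) == 1

    def interior_vertices(self) -> List[int]:
        return [v for v in self.graph if self.graph.degree(v) > 1]

    def subdivision_points(self) -> List[int]:
        return [v for v in self.graph if self.graph.degree(v) == 2]

    def is_binary(self) -> bool:
        return all(self.graph.degree(v) in (1, 3) for v in self.graph)

    def is_star(self) -> bool:
        return len(self.interior_vertices()) <= 1

    def path(self, u: int, v: int) -> List[int]:
        return nx.shortest_path(self.graph, u, v)

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(self.graph.edges(), self.leaf_map, self.mode)

    def __repr__(self) -> str:
        return f"<UnrootedTree on {len(self.leaf_map)} taxa: {write_newick(self)}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _tree_from_dendropy(dtree: dendropy.Tree, mode: TreeMode):
    """Convert a dendropy tree into (UnrootedTree, vertex -> internal-label)."""
    ids: Dict[object, int] = {}
    edges: List[Tuple[int, int]] = []
    leaf_map: Dict[int, Taxon] = {}
    labels: Dict[int, str] = {}
    for nd in dtree.preorder_node_iter():
        ids[nd] = len(ids)
    for nd in dtree.preorder_node_iter():
        vid = ids[nd]
        if nd.parent_node is not None:
            edges.append((ids[nd.parent_node], vid))
        if nd.taxon is not None:
            leaf_map[vid] = check_taxon(str(nd.taxon.label).replace(" ", "_"))
        elif nd.label is not None:
            labels[vid] = str(nd.label)
    if len(ids) == 1:
        raise TreeError("tree must have at least one edge")
    g = nx.Graph(edges)
    # a rooted-style statement has a degree-2 top vertex: suppress it
    # (standard unrooted convention)
    seed_id = ids[dtree.seed_node]
    if g.degree(seed_id) == 2 and seed_id not in leaf_map:
        n1, n2 = g[seed_id]
        g.remove_node(seed_id)
        g.add_edge(n1, n2)
        labels.pop(seed_id, None)
        edges = list(g.edges())
    # a labelled node of degree > 1 would be an interior taxon
    for vid, taxon in leaf_map.items():
        if g.degree(vid) != 1:
            raise TreeError(f"taxon {taxon!r} on an interior vertex")
    tree = UnrootedTree(edges, leaf_map, mode)
    return tree, labels


def read_newick(text: str, mode: TreeMode = TreeMode.PHYLOGENETIC) -> UnrootedTree:
    """Parse a single Newick statement into an unrooted tree.

    The top-level vertex must have at least three children (the unrooted
    convention) unless the tree has at most three leaves.  Branch lengths
    are rejected; internal labels are ignored here (see
    :func:`arbornet.augtree.read_augmented_newick` for the marked dialect).
    """
    tree, _ = _read_newick_with_labels(text, mode)
    return tree


def _read_newick_with_labels(text: str, mode: TreeMode):
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick statement must end in ';'")
    if ":" in text:
        raise TreeError("branch lengths are not supported")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _tree_from_dendropy(dtree, mode)


def write_newick(tree: UnrootedTree, vertex_labels: Optional[Dict[int, str]] = None) -> str:
    """Serialize to canonical Newick.

    The tree is written from the interior vertex adjacent to the smallest
    taxon; at every vertex children are ordered by their smallest descendant
    taxon, which makes the output bit-stable for equivalent trees.
    """
    vertex_labels = vertex_labels or {}
    g = tree.graph
    taxa = sorted(tree.leaf_map.values())
    if len(taxa) == 1:
        (v,) = tree.leaf_map
        return f"{tree.leaf_map[v]};"
    root_leaf = tree.leaf_of(taxa[0])
    top = next(iter(g[root_leaf]))

    def render(v: int, parent: int) -> Tuple[str, Taxon]:
        if tree.is_leaf(v):
            return tree.leaf_map[v], tree.leaf_map[v]
        parts = [render(c, v) for c in g[v] if c != parent]
        parts.sort(key=lambda p: p[1])
        body = "(" + ",".join(p[0] for p in parts) + ")" + vertex_labels.get(v, "")
        return body, min(p[1] for p in parts)

    if len(taxa) == 2:
        return f"({','.join(taxa)});"
    parts = [render(c, top) for c in g[top]]
    parts.sort(key=lambda p: p[1])
    return "(" + ",".join(p[0] for p in parts) + ")" + vertex_labels.get(top, "") + ";"


# ---------------------------------------------------------------------------
# Splits of a tree / Split-Equivalence Theorem
# ---------------------------------------------------------------------------


def splits_of_tree(tree: UnrootedTree) -> SplitSystem:
    """Σ(T): one full split per edge, by deleting the edge."""
    if tree.mode is not TreeMode.PHYLOGENETIC:
        raise TreeError("splits are defined for phylogenetic trees")
    g = tree.graph
    splits = []
    for u, v in g.edges():
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        a = frozenset(t for lv, t in tree.leaf_map.items() if lv in comp)
        b = tree.taxa - a
        splits.append(Split(tree.taxa, a, b))
    return SplitSystem(tree.taxa, splits)


def splits_compatible(s1: Split, s2: Split) -> bool:
    """Two full splits are compatible iff some part of one misses some part of the other."""
    return any(
        not (p & q)
        for p in (s1.part_a, s1.part_b)
        for q in (s2.part_a, s2.part_b)
    )


def is_compatible(system: SplitSystem) -> bool:
    """Pairwise compatibility of a full split system."""
    splits = list(system.splits)
    for s in splits:
        if not s.is_full:
            raise TreeError("compatibility is defined for full splits only")
    return all(
        splits_compatible(s1, s2) for s1, s2 in itertools.combinations(splits, 2)
    )


def tree_from_splits(system: SplitSystem) -> UnrootedTree:
    """Build the unique phylogenetic tree T with Σ(T) = ``system``.

    The system must contain every trivial split of its ground set and be
    compatible (the Split-Equivalence Theorem).  The construction roots the
    clusters away from the smallest taxon and builds the Hasse diagram of
    the resulting laminar family.
    """
    X = sorted(system.ground)
    if len(X) < 2:
        raise TreeError("need at least 2 taxa")
    for t in X:
        if Split(system.ground, {t}, system.ground - {t}) not in system.splits:
            raise TreeError(f"missing trivial split for {t!r}")
    if not is_compatible(system):
        raise TreeError("incompatible split system")
    x0 = X[0]
    if len(X) == 2:
        return UnrootedTree([(0, 1)], {0: X[0], 1: X[1]})
    clusters = {s.part_b if x0 in s.part_a else s.part_a for s in system.splits}
    root_cluster = frozenset(system.ground - {x0})
    clusters.add(root_cluster)
    ordered = sorted(clusters, key=len, reverse=True)
    vid: Dict[FrozenSet[Taxon], int] = {c: i for i, c in enumerate(ordered)}
    edges: List[Tuple[int, int]] = []
    leaf_map: Dict[int, Taxon] = {}
    for i, c in enumerate(ordered):
        if len(c) == 1:
            leaf_map[vid[c]] = next(iter(c))
        if c == root_cluster:
            continue
        parent = min(
            (p for p in ordered if len(p) > len(c) and c < p),
            key=len,
        )
        edges.append((vid[parent], vid[c]))
    x0_id = len(ordered)
    leaf_map[x0_id] = x0
    edges.append((vid[root_cluster], x0_id))
    return UnrootedTree(edges, leaf_map)


# ---------------------------------------------------------------------------
# Medians, restriction, displayed quartets
# ---------------------------------------------------------------------------


def median(tree: UnrootedTree, x: Taxon, y: Taxon, z: Taxon) -> int:
    """The unique vertex on all three pairwise paths between leaves x, y, z."""
    if len({x, y, z}) != 3:
        raise TreeError("median needs three distinct taxa")
    lx, ly, lz = (tree.leaf_of(t) for t in (x, y, z))
    pxy = tree.path(lx, ly)
    pxz = set(tree.path(lx, lz))
    # walking from x, the last vertex of path(x,y) also on path(x,z)
    med = lx
    for v in pxy:
        if v in pxz:
            med = v
        else:
            break
    return med


def restrict_tree(
    tree: UnrootedTree, subset: Iterable[Taxon]
) -> Tuple[UnrootedTree, Dict[int, int]]:
    """``T|_Y``: the span of Y with degree-2 vertices suppressed.

    Returns the restricted tree together with the map from surviving span
    vertices to their ids in the restriction (suppressed vertices are
    absent), which lets medians be traced through restrictions.
    """
    Y = frozenset(subset)
    if not Y <= tree.taxa:
        raise TreeError("subset must consist of leaf taxa")
    if len(Y) < 2:
        raise TreeError("restriction needs at least 2 taxa")
    keep_leaves = {tree.leaf_of(t) for t in Y}
    span = tree.graph.copy()
    # peel leaves (of the shrinking span) that are not wanted
    changed = True
    while changed:
        changed = False
        for v in [v for v in span if span.degree(v) <= 1 and v not in keep_leaves]:
            span.remove_node(v)
            changed = True
    # suppress degree-2 vertices
    restricted = span.copy()
    for v in [v for v in span if span.degree(v) == 2]:
        n1, n2 = restricted[v]
        restricted.remove_node(v)
        restricted.add_edge(n1, n2)
    leaf_map = {tree.leaf_of(t): t for t in Y}
    sub = UnrootedTree(
        restricted.edges() if len(restricted) > 1 else [],
        leaf_map,
    )
    vmap = {v: v for v in restricted}
    return sub, vmap


def quartet_topology(
    tree: UnrootedTree, w: Taxon, x: Taxon, y: Taxon, z: Taxon
) -> Optional[QuartetTree]:
    """The quartet tree displayed by T on {w,x,y,z}, or None if unresolved."""
    m1 = median(tree, w, x, y)
    m2 = median(tree, w, x, z)
    m3 = median(tree, w, y, z)
    if m1 == m2 and m1 != m3:
        return QuartetTree(w, x, y, z)
    if m1 == m3 and m1 != m2:
        return QuartetTree(w, y, x, z)
    if m2 == m3 and m1 != m2:
        return QuartetTree(w, z, x, y)
    return None


def displayed_quartets(tree: UnrootedTree) -> Set[QuartetTree]:
    """𝒬(T): all quartet trees q with T|_{L(q)} equivalent to q."""
    taxa = sorted(tree.taxa)
    if len(taxa) < 4:
        raise TreeError("need at least 4 leaves to display quartets")
    out: Set[QuartetTree] = set()
    for quad in itertools.combinations(taxa, 4):
        q = quartet_topology(tree, *quad)
        if q is not None:
            out.add(q)
    return out


def quartets_of_split(split: Split) -> Set[QuartetTree]:
    """𝒬(σ): quartet trees displayed by a non-trivial full split."""
    out: Set[QuartetTree] = set()
    for a1, a2 in itertools.combinations(sorted(split.part_a), 2):
        for b1, b2 in itertools.combinations(sorted(split.part_b), 2):
            out.add(QuartetTree(a1, a2, b1, b2))
    return out


def split_displays_quartet(split: Split, q: QuartetTree) -> bool:
    p1, p2 = set(q.pair_1), set(q.pair_2)
    return (p1 <= split.part_a and p2 <= split.part_b) or (
        p1 <= split.part_b and p2 <= split.part_a
    )


# ---------------------------------------------------------------------------
# Splits from quartets (quartet amalgamation)
# ---------------------------------------------------------------------------


def splits_from_quartets(
    quartets: Iterable[QuartetTree], ground: Iterable[Taxon]
) -> SplitSystem:
    """Σ(𝒬): full non-trivial splits A|B all of whose cross-quartets are present.

    Each input quartet seeds a pair (A, B) that is greedily extended, adding
    a taxon to a part whenever every required cross-quartet a₁a₂|b₁b₂ is in
    the input, repeating until a fixed point.  For inputs of the form 𝒬(T)
    the maximal extension of any displayed quartet is a full split of X, so
    the result equals the non-trivial splits of T.
    """
    X = frozenset(ground)
    if len(X) < 4:
        raise TreeError("ground set must have at least 4 taxa")
    Q = set(quartets)
    for q in Q:
        if not q.taxa <= X:
            raise TreeError(f"quartet {q} not on the ground set")

    def can_join(x: Taxon, part: FrozenSet[Taxon], other: FrozenSet[Taxon]) -> bool:
        return all(
            QuartetTree(x, a, b1, b2) in Q
            for a in part
            for b1, b2 in itertools.combinations(sorted(other), 2)
        )

    found: Set[Split] = set()
    for q in Q:
        a: FrozenSet[Taxon] = frozenset(q.pair_1)
        b: FrozenSet[Taxon] = frozenset(q.pair_2)
        changed = True
        while changed:
            changed = False
            for x in sorted(X - a - b):
                if can_join(x, a, b):
                    a = a | {x}
                    changed = True
                elif can_join(x, b, a):
                    b = b | {x}
                    changed = True
        if a | b == X:
            found.add(Split(X, a, b))
    return SplitSystem(X, found)
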