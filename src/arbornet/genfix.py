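"""Seeded synthetic generators and the counterexample fixture library.

Generators produce random binary trees (uniform stepwise leaf addition),
random augmented trees (independent AUG marks on interior vertices) and
random arboreal networks (a forest of rooted binary trees joined by
transfer arcs along a random tree-of-trees).  All are deterministic given
their seed and keep no global random state.

The fixture library transcribes the nine enhanced-quartet-tree systems that
show the six defining properties A1–A6 to be mutually independent: each
fixture violates exactly its named property.  The two A5 and two A6
fixtures are read off small augmented trees with a prescribed (deliberately
non-induced) γ; the remainder are tiny explicit tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

from .arboreal import ArborealNetwork
from .augtree import AugmentedTree, Mark
from .eqts import EnhancedQuartetSystem, QuartetRecord
from .treecore import (
    QuartetTree,
    TreeError,
    UnrootedTree,
    displayed_quartets,
    median,
    read_newick,
)

__all__ = [
    "GenConfig",
    "random_binary_tree",
    "random_augmented_tree",
    "random_arboreal_network",
    "net9",
    "independence_fixtures",
    "FIXTURE_NAMES",
    "forbidden_fixture",
    "forbidden_fixture_repaired",
]


@dataclass(frozen=True)
class GenConfig:
    n_leaves: int
    p_aug: float = 0.3
    n_trees: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 4:
            raise TreeError("n_leaves must be >= 4")
        if self.n_trees < 1:
            raise TreeError("n_trees must be >= 1")
        if not 0.0 <= self.p_aug <= 1.0:
            raise TreeError("p_aug must be a probability")


# ---------------------------------------------------------------------------
# Random trees and networks
# ---------------------------------------------------------------------------


def random_binary_tree(
    n: int, seed: int, labels: Optional[List[str]] = None
) -> UnrootedTree:
    """Uniform stepwise-addition topology on n leaves (labels default 1..n)."""
    if n < 3:
        raise TreeError("need at least 3 leaves")
    labels = list(labels) if labels is not None else [str(i + 1) for i in range(n)]
    if len(labels) != n:
        raise TreeError("label count must equal n")
    rng = np.random.default_rng(seed)
    edges: List[Tuple[int, int]] = [(0, 1), (0, 2), (0, 3)]
    leaf_map = {1: labels[0], 2: labels[1], 3: labels[2]}
    next_id = 4
    for i in range(3, n):
        u, v = edges[int(rng.integers(len(edges)))]
        w, leaf = next_id, next_id + 1
        next_id += 2
        edges.remove((u, v))
        edges.extend([(u, w), (w, v), (w, leaf)])
        leaf_map[leaf] = labels[i]
    return UnrootedTree(edges, leaf_map)


def random_augmented_tree(
    n: int, p_aug: float, seed: int, labels: Optional[List[str]] = None
) -> AugmentedTree:
    """Random binary tree with interior vertices marked AUG with probability p_aug."""
    if n < 4:
        raise TreeError("need at least 4 leaves")
    tree = random_binary_tree(n, seed, labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1))
    aug = {
        v for v in tree.interior_vertices() if rng.random() < p_aug
    }
    return AugmentedTree(tree, aug)


def _random_rooted_tree(
    taxa: List[str], comp: int, rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """Rooted binary tree arcs on >= 2 taxa; interior names are t<comp>i<j>."""
    root = f"t{comp}r"
    arcs = [(root, taxa[0]), (root, taxa[1])]
    counter = 0
    for leaf in taxa[2:]:
        u, v = arcs[int(rng.integers(len(arcs)))]
        m = f"t{comp}i{counter}"
        counter += 1
        arcs.remove((u, v))
        arcs.extend([(u, m), (m, v), (m, leaf)])
    return arcs


def random_arboreal_network(
    n_leaves: int, n_trees: int, seed: int
) -> ArborealNetwork:
    """A forest of rooted binary trees joined by n_trees − 1 transfer arcs.

    The leaf set 1..n is partitioned into n_trees components of at least two
    leaves each; the components are connected along a random tree-of-trees,
    each connector arc subdividing a random arc of its donor component (a
    PLAIN transfer-donor vertex) and a random arc of its recipient component
    (a reticulation).  The result always validates, with exactly
    n_trees − 1 reticulations.
    """
    if n_trees < 1:
        raise TreeError("need at least 1 tree")
    if n_leaves < 2 * n_trees:
        raise TreeError("each component needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    taxa = [str(i + 1) for i in range(n_leaves)]
    order = [taxa[i] for i in rng.permutation(n_leaves)]
    sizes = [2] * n_trees
    for _ in range(n_leaves - 2 * n_trees):
        sizes[int(rng.integers(n_trees))] += 1
    parts: List[List[str]] = []
    pos = 0
    for s in sizes:
        parts.append(order[pos : pos + s])
        pos += s
    arcs: List[Tuple[str, str]] = []
    comp_of: Dict[str, int] = {}
    for ci, part in enumerate(parts):
        for u, v in _random_rooted_tree(part, ci, rng):
            comp_of.setdefault(u, ci)
            comp_of.setdefault(v, ci)
            arcs.append((u, v))

    def subdivide(comp: int, name: str) -> str:
        internal = [
            (u, v) for u, v in arcs if comp_of[u] == comp == comp_of[v]
        ]
        u, v = internal[int(rng.integers(len(internal)))]
        arcs.remove((u, v))
        arcs.extend([(u, name), (name, v)])
        comp_of[name] = comp
        return name

    for i in range(1, n_trees):
        j = int(rng.integers(i))
        donor, recipient = (i, j) if rng.random() < 0.5 else (j, i)
        tail = subdivide(donor, f"h{i}t")
        head = subdivide(recipient, f"h{i}r")
        arcs.append((tail, head))
    return ArborealNetwork(arcs)


def net9() -> ArborealNetwork:
    """The reference two-root, one-reticulation network on five taxa."""
    return random_arboreal_network(5, 2, 0)


# ---------------------------------------------------------------------------
# Independence fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("A1", "A2", "A3", "A4a", "A4b", "A5a", "A5b", "A6a", "A6b")

_P = Mark.PLAIN
_A = Mark.AUG


def _table_system(rows: Iterable[Tuple[str, str, str, str, int, Mark, Mark]],
                  ground: Iterable[str]) -> EnhancedQuartetSystem:
    table = {}
    for a, b, c, d, g, near, far in rows:
        q = QuartetTree(a, b, c, d)
        assert q.pair_1 == (a, b) and q.pair_2 == (c, d), f"row {a}{b}|{c}{d} not canonical"
        table[q] = QuartetRecord(gamma=g, nu_near=near, nu_far=far)
    return EnhancedQuartetSystem(ground=frozenset(ground), table=table)


def _marked_tree_system(
    newick: str,
    aug_triples: Iterable[Tuple[str, str, str]],
    gamma_of: Callable[[QuartetTree], int],
) -> EnhancedQuartetSystem:
    """System read off a tree: support = displayed quartets, marks from tree
    medians (AUG exactly at the medians of ``aug_triples``), γ prescribed."""
    tree = read_newick(newick)
    aug = {median(tree, *t) for t in aug_triples}
    table = {}
    for q in displayed_quartets(tree):
        (a, b), (c, d) = q.pair_1, q.pair_2
        near = median(tree, a, b, c)
        far = median(tree, c, d, a)
        table[q] = QuartetRecord(
            gamma=gamma_of(q),
            nu_near=_A if near in aug else _P,
            nu_far=_A if far in aug else _P,
        )
    return EnhancedQuartetSystem(ground=tree.taxa, table=table)


# Tree behind the two A5 fixtures: cherry {a,b}, f on the interior path,
# multi-cherry {c,d,e}; γ puts one subdivision point on ab|cd only.
_A5_TREE = "((a,b),f,(c,d,e));"

# Tree behind the two A6 fixtures: the caterpillar a,b | f | c | g | d,e;
# γ = 1 on the five quartets below, 0 on the rest of the displayed set.
_A6_TREE = "((a,b),f,(c,(g,(d,e))));"
_A6_PRIME = {
    QuartetTree("a", "b", "d", "e"),
    QuartetTree("a", "b", "c", "d"),
    QuartetTree("a", "c", "d", "e"),
    QuartetTree("b", "c", "d", "e"),
    QuartetTree("a", "b", "c", "e"),
}

_AB_CD = QuartetTree("a", "b", "c", "d")


def independence_fixtures(name: str) -> EnhancedQuartetSystem:
    """The nine systems showing A1–A6 mutually independent.

    ``check_properties`` on fixture ``Ak``/``Aka``/``Akb`` fails exactly
    property Ak and passes the other five.
    """
    X4 = ("a", "b", "c", "d")
    X5 = ("a", "b", "c", "d", "e")
    if name == "A1":
        # all three topologies of the single 4-set present
        return _table_system(
            [
                ("a", "b", "c", "d", 0, _P, _P),
                ("a", "c", "b", "d", 0, _P, _P),
                ("a", "d", "b", "c", 0, _P, _P),
            ],
            X4,
        )
    if name == "A2":
        # a lone quartet cannot extend by the fifth taxon
        return _table_system([("a", "b", "c", "d", 0, _P, _P)], X5)
    if name == "A3":
        # the median of {a,b,c} is AUG in ab|ce but PLAIN in its siblings
        return _table_system(
            [
                ("a", "b", "c", "d", 0, _P, _P),
                ("a", "b", "c", "e", 0, _A, _P),
                ("a", "b", "d", "e", 0, _P, _P),
            ],
            X5,
        )
    if name == "A4a":
        # an augmentation point with no possible witness pair
        return _table_system([("a", "b", "c", "d", 1, _P, _P)], X4)
    if name == "A4b":
        # witnesses exist combinatorially but every mark is PLAIN
        return _table_system(
            [
                ("a", "b", "c", "d", 1, _P, _P),
                ("a", "e", "c", "d", 1, _P, _P),
                ("b", "e", "c", "d", 1, _P, _P),
                ("a", "b", "c", "e", 0, _P, _P),
                ("a", "b", "d", "e", 0, _P, _P),
            ],
            X5,
        )
    if name in ("A5a", "A5b"):
        aug = [("a", "f", "c")]  # the vertex carrying f
        if name == "A5a":
            aug.append(("c", "d", "e"))  # the multi-cherry vertex
        return _marked_tree_system(
            _A5_TREE, aug, lambda q: 1 if q == _AB_CD else 0
        )
    if name in ("A6a", "A6b"):
        # AUG everywhere in the interior except the two end cherries
        # (A6b additionally un-marks s, the vertex carrying c)
        aug = [("a", "f", "c"), ("c", "g", "a"), ("g", "d", "a")]
        if name == "A6b":
            aug = [("a", "f", "c"), ("g", "d", "a")]
        return _marked_tree_system(
            _A6_TREE, aug, lambda q: 1 if q in _A6_PRIME else 0
        )
    raise TreeError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# Forbidden-configuration fixture (k = 3) and its two-leaf repair
# ---------------------------------------------------------------------------


def forbidden_fixture() -> Tuple[AugmentedTree, FrozenSet[str], FrozenSet[str]]:
    """A central PLAIN vertex fenced in by three leafed reticulations.

    Around a central PLAIN vertex p sit three AUG vertices w1..w3, each
    carrying one X-leaf l_i and, beyond a PLAIN vertex u_i, a cherry of a
    root handle R_i and an X-leaf y_i.  Every edge into w_i is forced
    towards w_i, so p would need outdegree three: no orientation exists.
    """
    edges = []
    leaf_map = {}
    p = 0
    nid = 1
    for i in range(3):
        w = nid
        l = nid + 1
        u = nid + 2
        rh = nid + 3
        y = nid + 4
        nid += 5
        edges += [(p, w), (w, l), (w, u), (u, rh), (u, y)]
        leaf_map[l] = f"l{i + 1}"
        leaf_map[rh] = f"R_{i + 1}"
        leaf_map[y] = f"y{i + 1}"
    tree = UnrootedTree(edges, leaf_map)
    aug = {1, 6, 11}  # the w_i
    t = AugmentedTree(tree, aug)
    R = frozenset(f"R_{i + 1}" for i in range(3))
    X = t.taxa - R
    return t, X, R


def forbidden_fixture_repaired() -> Tuple[AugmentedTree, FrozenSet[str], FrozenSet[str]]:
    """The same configuration with leaf l1 replaced by the cherry {l1, R_0}.

    The extra root handle gives w1 an incoming arc from outside the centre,
    freeing p; the instance becomes orientable.
    """
    t, X, R = forbidden_fixture()
    tree = t.tree
    l1 = tree.leaf_of("l1")
    (w1,) = tree.graph[l1]
    edges = [e for e in tree.graph.edges() if frozenset(e) != frozenset((w1, l1))]
    c = max(tree.graph) + 1
    rh = c + 1
    edges += [(w1, c), (c, l1), (c, rh)]
    leaf_map = dict(tree.leaf_map)
    leaf_map[rh] = "R_0"
    new_tree = UnrootedTree(edges, leaf_map)
    new_t = AugmentedTree(new_tree, t.aug)
    R2 = R | {"R_0"}
    return new_t, new_t.taxa - R2, R2
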