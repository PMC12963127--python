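"""Arboreal networks: multi-rooted DAGs whose planted shape is a tree.

An arboreal network on X is a directed acyclic graph with leaf set X that
can be thought of as a forest of rooted phylogenetic trees joined by extra
arcs, each modelling a horizontal gene transfer between trees.  Formally:
every vertex of indegree ≥ 2 (a *reticulation*, the transfer recipient) has
outdegree one, and planting the network — hanging a new handle vertex r̂
above every root r — and forgetting arc directions yields a phylogenetic
tree on X ∪ R(N).

Dropping directions and marking reticulations AUG turns a network into an
augmented tree (:func:`underlying_augmented`); recovering the directions
from that tree is the job of :mod:`arbornet.orient`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import networkx as nx
from networkx.algorithms import isomorphism

from .augtree import AugmentedTree
from .treecore import TreeError, UnrootedTree, check_taxon

__all__ = [
    "ArborealNetwork",
    "PlantedNetwork",
    "validate_arboreal",
    "plant",
    "unplant",
    "underlying_augmented",
    "networks_equal",
    "read_arcs",
    "write_arcs",
    "to_dot",
]

ARCS_HEADER = "#ARBOREAL v1"


class ArborealNetwork:
    """A validated arboreal network held as a directed graph.

    Leaves (outdegree-0 vertices) carry the taxa of X; other vertex names
    are opaque.
    """

    def __init__(self, arcs: Iterable[Tuple[str, str]]):
        g = nx.DiGraph()
        g.add_edges_from(arcs)
        self.graph = g
        self.roots: FrozenSet[str] = frozenset()
        self.reticulations: FrozenSet[str] = frozenset()
        validate_arboreal(self)

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(v for v in self.graph if self.graph.out_degree(v) == 0)

    def __repr__(self) -> str:
        return (
            f"<ArborealNetwork on {len(self.taxa)} taxa, "
            f"{len(self.roots)} root(s), {len(self.reticulations)} reticulation(s)>"
        )


@dataclass(frozen=True)
class PlantedNetwork:
    """A network plus its root handles r̂ (one per root, arc r̂ → r)."""

    network: ArborealNetwork
    handles: Dict[str, str]  # root -> handle name


def validate_arboreal(cand: ArborealNetwork) -> ArborealNetwork:
    """Enforce every invariant of the type; records roots and reticulations."""
    g = cand.graph
    if len(g) == 0:
        raise TreeError("empty network")
    if not nx.is_directed_acyclic_graph(g):
        raise TreeError("network contains a directed cycle")
    und = g.to_undirected(as_view=False)
    if not nx.is_tree(und):
        raise TreeError("underlying undirected graph is not a tree")
    roots, retics = set(), set()
    for v in g:
        ind, outd = g.in_degree(v), g.out_degree(v)
        if ind >= 2:
            if outd != 1:
                raise TreeError(
                    f"reticulation {v!r} has outdegree {outd}, must be 1"
                )
            retics.add(v)
        if ind == 0:
            if outd < 2:
                raise TreeError(f"root {v!r} has outdegree {outd}, must be >= 2")
            roots.add(v)
        elif ind + outd == 2:
            # the planted underlying graph must be phylogenetic
            raise TreeError(f"non-root vertex {v!r} has total degree 2")
        if outd == 0:
            check_taxon(v)
    cand.roots = frozenset(roots)
    cand.reticulations = frozenset(retics)
    return cand


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def plant(n: ArborealNetwork, handle_namer=None) -> PlantedNetwork:
    """N^p: add a handle vertex r̂ with arc (r̂, r) above every root.

    ``handle_namer`` maps (index, root) to the handle's name; the default
    produces ``R_1, R_2, ...`` in sorted-root order.
    """
    if handle_namer is None:
        handle_namer = lambda i, r: f"R_{i + 1}"
    handles: Dict[str, str] = {}
    used = set(n.graph)
    for i, r in enumerate(sorted(n.roots)):
        name = handle_namer(i, r)
        if name in used or name in handles.values():
            raise TreeError(f"handle name {name!r} collides")
        handles[r] = name
    return PlantedNetwork(network=n, handles=handles)


def unplant(p: PlantedNetwork) -> ArborealNetwork:
    return p.network


def planted_arcs(p: PlantedNetwork) -> List[Tuple[str, str]]:
    arcs = list(p.network.graph.edges())
    arcs.extend((h, r) for r, h in p.handles.items())
    return arcs


# ---------------------------------------------------------------------------
# The underlying augmented tree 𝒰(N)
# ---------------------------------------------------------------------------


def underlying_augmented(
    n: ArborealNetwork, handle_namer=None
) -> Tuple[AugmentedTree, FrozenSet[str]]:
    """𝒰(N): the planted network, undirected, with reticulations marked AUG.

    Returns the augmented tree on X ∪ R(N) and the set R(N) of handle taxa.
    """
    p = plant(n, handle_namer)
    arcs = planted_arcs(p)
    names = sorted({v for arc in arcs for v in arc})
    vid = {name: i for i, name in enumerate(names)}
    edges = [(vid[u], vid[v]) for u, v in arcs]
    g = nx.Graph(edges)
    leaf_map = {v: name for name, v in vid.items() if g.degree(v) == 1}
    tree = UnrootedTree(edges, leaf_map)
    aug = {vid[v] for v in n.reticulations}
    t = AugmentedTree(tree, aug)
    # a reticulation has two interior parents, so at most its child can be a leaf
    for v in t.aug:
        leaf_neighbours = [u for u in tree.graph[v] if tree.is_leaf(u)]
        assert len(leaf_neighbours) <= 1, "reticulation adjacent to two leaves"
    return t, frozenset(p.handles.values())


def networks_equal(n1: ArborealNetwork, n2: ArborealNetwork) -> bool:
    """Taxon-preserving isomorphism of the directed graphs."""
    if n1.taxa != n2.taxa:
        return False

    def tag(g: nx.DiGraph) -> nx.DiGraph:
        h = g.copy()
        for v in h:
            h.nodes[v]["taxon"] = v if h.out_degree(v) == 0 else None
        return h

    gm = isomorphism.DiGraphMatcher(
        tag(n1.graph),
        tag(n2.graph),
        node_match=lambda x, y: x["taxon"] == y["taxon"],
    )
    return gm.is_isomorphic()


# ---------------------------------------------------------------------------
# Arc-list I/O
# ---------------------------------------------------------------------------


def write_arcs(n: ArborealNetwork) -> str:
    lines = [ARCS_HEADER]
    lines.extend(f"{u}\t{v}" for u, v in sorted(n.graph.edges()))
    return "\n".join(lines) + "\n"


def read_arcs(text: str) -> ArborealNetwork:
    lines = text.splitlines()
    if not lines or lines[0].strip() != ARCS_HEADER:
        raise TreeError(f"arc list must start with {ARCS_HEADER!r}")
    arcs = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TreeError(f"line {lineno}: expected 'tail<TAB>head'")
        arcs.append((parts[0], parts[1]))
    return ArborealNetwork(arcs)


def to_dot(n: ArborealNetwork) -> str:
    lines = ["digraph arboreal {"]
    for v in sorted(n.graph):
        shape = "box" if v in n.reticulations else "ellipse"
        lines.append(f'  "{v}" [shape={shape}];')
    for u, v in sorted(n.graph.edges()):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
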