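"""Orienting a binary augmented tree into an arboreal network (Check).

Given a binary augmented tree on X ∪ R — think: the underlying tree of a
multi-rooted HGT network whose arc directions were forgotten, with the
reticulations still marked — and the designated root-handle taxa R, decide
whether the tree's edges can be directed so that

* every handle edge points out of its handle leaf, every X-leaf edge points
  into its leaf,
* every AUG interior vertex becomes a reticulation (indegree 2, outdegree 1),
* every PLAIN interior vertex becomes a tree vertex (indegree 1, outdegree 2),

and, if so, return the resulting arboreal network.  On a tree these local
profiles make every edge direction *forced*: starting from the leaf edges,
any vertex with two of its three edges decided determines the third, and the
frontier of undecided edges always contains such a vertex.  The orientation
is therefore unique whenever it exists, and independent of the choice of
reference root ρ.  A brute-force enumerator over all boundary-respecting
orientations is provided as an independent oracle, together with the
contraction of the tree to its core (the subtree spanned by R and the
reticulation-adjacent leaves) and a diagnostic for the forbidden
configuration of all-PLAIN regions fenced in by leaf-carrying reticulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .arboreal import ArborealNetwork, underlying_augmented
from .augtree import AugmentedTree, Mark, augmentation_equivalent
from .treecore import TreeError, TreeMode, UnrootedTree

__all__ = [
    "Direction",
    "FailureCode",
    "OrientResult",
    "CoreContraction",
    "forced_direction",
    "contract_to_core",
    "check_orient",
    "brute_force_orient",
    "detect_forbidden_configuration",
]

Edge = FrozenSet[int]


def _edge(u: int, v: int) -> Edge:
    return frozenset((u, v))


class Direction(Enum):
    IN = "in"
    OUT = "out"
    INFEASIBLE = "infeasible"
    SATISFIED = "satisfied"


class FailureCode(Enum):
    PRUNE_STRANDED_AUG = "PRUNE_STRANDED_AUG"
    VERTEX_INFEASIBLE = "VERTEX_INFEASIBLE"
    ENDGAME_CONFLICT = "ENDGAME_CONFLICT"
    POST_VALIDATION = "POST_VALIDATION"


@dataclass(frozen=True)
class OrientResult:
    network: Optional[ArborealNetwork] = None
    code: Optional[FailureCode] = None
    witness: Optional[int] = None

    @property
    def success(self) -> bool:
        return self.network is not None


def _target(mark: Mark) -> Tuple[int, int]:
    # reticulations collect two incoming transfers; tree vertices branch
    return (2, 1) if mark is Mark.AUG else (1, 2)


def forced_direction(mark: Mark, n_in: int, n_out: int) -> Direction:
    """Resolve a binary interior vertex with 2 or 3 of its edges decided.

    With two edges known the third direction is forced (relative to the
    vertex) or the profile is infeasible; with all three known the profile
    either matches the target — (2,1) for AUG, (1,2) for PLAIN — or not.
    """
    if n_in < 0 or n_out < 0 or n_in + n_out > 3:
        raise TreeError("vertex degree bookkeeping out of range")
    ti, to = _target(mark)
    if n_in > ti or n_out > to:
        return Direction.INFEASIBLE
    known = n_in + n_out
    if known == 3:
        return Direction.SATISFIED
    if known == 2:
        return Direction.IN if ti - n_in == 1 else Direction.OUT
    raise TreeError("forced_direction needs at least 2 decided edges")


# ---------------------------------------------------------------------------
# Instance plumbing
# ---------------------------------------------------------------------------


def _check_instance(
    t: AugmentedTree, X: Iterable[str], R: Iterable[str]
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    X, R = frozenset(X), frozenset(R)
    tree = t.tree
    if tree.mode is not TreeMode.PHYLOGENETIC or not tree.is_binary():
        raise TreeError("orientation requires a binary phylogenetic tree")
    if not R:
        raise TreeError("root set R must be non-empty")
    if not X:
        raise TreeError("leaf set X must be non-empty")
    if X & R or (X | R) != tree.taxa:
        raise TreeError("X and R must partition the leaf taxa")
    if len(tree.taxa) < 3:
        raise TreeError("need at least 3 leaves")
    return X, R


class _Orienter:
    """Shared bookkeeping: edge directions plus per-vertex in/out counts."""

    def __init__(self, t: AugmentedTree, X: FrozenSet[str], R: FrozenSet[str]):
        self.t = t
        self.X = X
        self.R = R
        self.g = t.tree.graph
        self.direction: Dict[Edge, Tuple[int, int]] = {}
        self.n_in = {v: 0 for v in self.g}
        self.n_out = {v: 0 for v in self.g}

    def set_dir(self, tail: int, head: int) -> None:
        e = _edge(tail, head)
        assert e not in self.direction
        self.direction[e] = (tail, head)
        self.n_out[tail] += 1
        self.n_in[head] += 1

    def undecided(self, v: int) -> List[int]:
        return [u for u in self.g[v] if _edge(u, v) not in self.direction]

    def orient_leaf_edges(self) -> None:
        tree = self.t.tree
        for leaf, taxon in tree.leaf_map.items():
            nb = next(iter(self.g[leaf]))
            if taxon in self.R:
                self.set_dir(leaf, nb)
            else:
                self.set_dir(nb, leaf)

    def finalize(self) -> OrientResult:
        """Strip the handles, validate, and verify the 𝒰-round-trip."""
        tree = self.t.tree
        taxa = tree.taxa
        handle_leaves = {tree.leaf_of(r) for r in self.R}

        def name(v: int) -> str:
            if v in tree.leaf_map:
                return tree.leaf_map[v]
            n = f"n{v}"
            while n in taxa:
                n = "_" + n
            return n

        arcs = []
        handle_of_root: Dict[str, str] = {}
        for tail, head in self.direction.values():
            if tail in handle_leaves:
                handle_of_root[name(head)] = tree.leaf_map[tail]
                continue
            if head in handle_leaves:
                # an arc into a handle can never be part of a network
                return OrientResult(
                    code=FailureCode.POST_VALIDATION, witness=head
                )
            arcs.append((name(tail), name(head)))
        try:
            net = ArborealNetwork(arcs)
        except TreeError:
            return OrientResult(code=FailureCode.POST_VALIDATION)
        if frozenset(handle_of_root) != net.roots:
            return OrientResult(code=FailureCode.POST_VALIDATION)
        u_tree, handles = underlying_augmented(
            net, handle_namer=lambda i, r: handle_of_root[r]
        )
        if handles != self.R or not augmentation_equivalent(u_tree, self.t):
            return OrientResult(code=FailureCode.POST_VALIDATION)
        return OrientResult(network=net)


# ---------------------------------------------------------------------------
# Check
# ---------------------------------------------------------------------------


def check_orient(
    t: AugmentedTree,
    X: Iterable[str],
    R: Iterable[str],
    rho: Optional[str] = None,
) -> OrientResult:
    """Orient t into an arboreal network with root handles R, or certify failure.

    Edge directions are propagated eagerly from the leaf boundary: whenever a
    vertex has one undecided edge left, :func:`forced_direction` decides it.
    Because every decision is forced, the outcome (and on success the
    network) does not depend on ρ, which is accepted for interface
    compatibility and defaults to the smallest handle taxon.

    Infeasibility surfaces either at a vertex whose in/out profile cannot be
    met (``VERTEX_INFEASIBLE`` with the vertex as witness) or at the final
    validation of the assembled network (``POST_VALIDATION``).
    """
    X, R = _check_instance(t, X, R)
    if rho is None:
        rho = min(R)
    elif rho not in R:
        raise TreeError(f"rho {rho!r} is not a root handle")

    orienter = _Orienter(t, X, R)
    orienter.orient_leaf_edges()
    g = orienter.g
    queue = deque(v for v in g if g.degree(v) > 1)
    while queue:
        v = queue.popleft()
        if g.degree(v) == 1:
            continue
        und = orienter.undecided(v)
        if len(und) > 1:
            continue
        res = forced_direction(t.mark(v), orienter.n_in[v], orienter.n_out[v])
        if res is Direction.INFEASIBLE:
            return OrientResult(code=FailureCode.VERTEX_INFEASIBLE, witness=v)
        if not und:
            continue  # SATISFIED
        (u,) = und
        if res is Direction.IN:
            orienter.set_dir(u, v)
        else:
            orienter.set_dir(v, u)
        queue.append(u)
        queue.append(v)
    assert len(orienter.direction) == g.number_of_edges()
    # final profile audit (catches a conflict pushed onto the last edge)
    for v in g:
        if g.degree(v) == 1:
            continue
        if forced_direction(t.mark(v), orienter.n_in[v], orienter.n_out[v]) is not Direction.SATISFIED:
            return OrientResult(code=FailureCode.VERTEX_INFEASIBLE, witness=v)
    return orienter.finalize()


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_orient(
    t: AugmentedTree, X: Iterable[str], R: Iterable[str]
) -> List[ArborealNetwork]:
    """All admissible orientations, by exhaustive search over interior edges.

    Leaf edges are fixed by the boundary conditions; every assignment of the
    remaining edges satisfying the interior degree profiles is completed and
    passed through the same final validation as :func:`check_orient`.  For a
    binary tree the result has at most one element.
    """
    X, R = _check_instance(t, X, R)
    if len(t.tree.taxa) > 16:
        raise TreeError("brute force capped at 16 leaves")
    base = _Orienter(t, X, R)
    base.orient_leaf_edges()
    interior_edges = [
        (u, v)
        for u, v in t.tree.graph.edges()
        if _edge(u, v) not in base.direction
    ]
    results: List[ArborealNetwork] = []

    def feasible(v: int, n_in: int, n_out: int) -> bool:
        ti, to = _target(t.mark(v))
        return n_in <= ti and n_out <= to

    def rec(idx: int) -> None:
        if idx == len(interior_edges):
            for v in base.g:
                if base.g.degree(v) > 1:
                    ti, to = _target(t.mark(v))
                    if (base.n_in[v], base.n_out[v]) != (ti, to):
                        return
            res = base.finalize()
            if res.success:
                results.append(res.network)
            return
        u, v = interior_edges[idx]
        for tail, head in ((u, v), (v, u)):
            base.set_dir(tail, head)
            if feasible(tail, base.n_in[tail], base.n_out[tail]) and feasible(
                head, base.n_in[head], base.n_out[head]
            ):
                rec(idx + 1)
            e = _edge(u, v)
            del base.direction[e]
            base.n_out[tail] -= 1
            base.n_in[head] -= 1

    rec(0)
    return results


# ---------------------------------------------------------------------------
# Core contraction
# ---------------------------------------------------------------------------


@dataclass
class CoreContraction:
    """T^ρ: the tree contracted onto R and the reticulation-adjacent leaves.

    ``tau`` maps each core edge to the vertex path it replaces in T (both
    endpoints included); ``partial`` holds the directions of the pruned
    edges, all pointing towards the removed leaves.  ``failure`` is set when
    pruning strands an AUG vertex whose profile can no longer be met.
    """

    core: Optional[AugmentedTree]
    tau: Dict[Edge, List[int]]
    partial: Dict[Edge, Tuple[int, int]]
    rho: str
    failure: Optional[Tuple[FailureCode, Optional[int]]] = None


def contract_to_core(
    t: AugmentedTree, X: Iterable[str], R: Iterable[str], rho: str
) -> CoreContraction:
    """Prune AUG-free, root-free subtrees and suppress the resulting paths.

    Subtrees containing neither an AUG vertex nor a root handle hang off the
    core; their edges are directed towards the removed leaves (each pruned
    PLAIN attachment then only needs the one incoming arc its retained edge
    will provide).  Leaves adjacent to an AUG vertex stay: they are the
    forced outgoing arc of their reticulation.  Suppressed PLAIN degree-2
    vertices are recorded in ``tau`` so that core decisions can be mirrored
    onto whole paths of T.
    """
    X, R = _check_instance(t, X, R)
    if rho not in R:
        raise TreeError(f"rho {rho!r} is not a root handle")
    tree = t.tree
    aug = t.aug_vertices()
    r_leaves = {tree.leaf_of(r) for r in R}
    work = tree.graph.copy()
    partial: Dict[Edge, Tuple[int, int]] = {}

    def removable(l: int) -> bool:
        if l in r_leaves or l in aug:
            return False
        if l in tree.leaf_map:
            nb = next(iter(work[l]))
            return nb not in aug
        return True

    changed = True
    while changed and len(work) > 2:
        changed = False
        for l in [v for v in work if work.degree(v) == 1]:
            if len(work) <= 2:
                break
            if removable(l):
                nb = next(iter(work[l]))
                partial[_edge(nb, l)] = (nb, l)
                work.remove_node(l)
                changed = True

    stranded = [v for v in aug if v in work and work.degree(v) <= 1]
    if stranded:
        return CoreContraction(
            core=None,
            tau={},
            partial=partial,
            rho=rho,
            failure=(FailureCode.PRUNE_STRANDED_AUG, stranded[0]),
        )

    tau: Dict[Edge, List[int]] = {_edge(u, v): [u, v] for u, v in work.edges()}
    core_g = work.copy()
    for v in [v for v in work if work.degree(v) == 2 and v not in aug]:
        n1, n2 = core_g[v]
        p1 = tau.pop(_edge(n1, v))
        p2 = tau.pop(_edge(v, n2))
        if p1[0] != n1:
            p1 = p1[::-1]
        if p2[-1] != n2:
            p2 = p2[::-1]
        assert p1[-1] == v == p2[0]
        core_g.remove_node(v)
        core_g.add_edge(n1, n2)
        tau[_edge(n1, n2)] = p1 + p2[1:]

    # in the degenerate all-pruned case a single unlabelled attachment stub
    # survives as the core's second vertex; give it a synthetic taxon
    leaf_map = {
        v: tree.leaf_map.get(v, f"core_{v}")
        for v in core_g
        if core_g.degree(v) == 1
    }
    try:
        core_tree = UnrootedTree(
            core_g.edges(), leaf_map, mode=TreeMode.PARTIALLY_SUBDIVIDED
        )
        core = AugmentedTree(core_tree, aug & set(core_g))
    except TreeError:
        # e.g. a reticulation reduced to a leaf-adjacent subdivision point:
        # its outgoing arcs are already spent, no orientation can exist
        return CoreContraction(
            core=None,
            tau=tau,
            partial=partial,
            rho=rho,
            failure=(FailureCode.PRUNE_STRANDED_AUG, None),
        )
    return CoreContraction(core=core, tau=tau, partial=partial, rho=rho)


# ---------------------------------------------------------------------------
# Forbidden configuration
# ---------------------------------------------------------------------------


def detect_forbidden_configuration(
    t: AugmentedTree, X: Iterable[str], R: Iterable[str]
) -> List[FrozenSet[int]]:
    """Connected all-PLAIN leafless regions fenced in by leafed reticulations.

    Returns every connected set C of interior PLAIN vertices without leaf
    neighbours whose entire boundary consists of AUG vertices adjacent to
    exactly one X-leaf.  Each boundary edge is then forced *into* its AUG
    vertex (whose single outgoing arc feeds its leaf), so some vertex of C
    would need outdegree 3; a witness implies check_orient failure.  The
    converse does not hold — this is a diagnostic, not a decision procedure.
    """
    X, R = _check_instance(t, X, R)
    tree = t.tree
    g = tree.graph
    aug = t.aug_vertices()

    def leaf_neighbours(v: int) -> List[int]:
        return [u for u in g[v] if tree.is_leaf(u)]

    candidates = {
        v
        for v in g
        if g.degree(v) > 1 and v not in aug and not leaf_neighbours(v)
    }
    witnesses: List[FrozenSet[int]] = []
    sub = g.subgraph(candidates)
    for comp in nx.connected_components(sub):
        boundary = {u for v in comp for u in g[v] if u not in comp}
        ok = True
        for b in boundary:
            if b not in aug:
                ok = False
                break
            lnb = leaf_neighbours(b)
            if len(lnb) != 1 or tree.leaf_map[lnb[0]] not in X:
                ok = False
                break
        if ok and boundary:
            witnesses.append(frozenset(comp))
    return witnesses
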