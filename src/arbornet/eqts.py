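"""Enhanced quartet tree systems (γ, ν).

A subdivision map γ assigns each quartet tree on a ground set X either −1
(absent) or the number k ≥ 0 of subdivision points on its interior edge;
ν marks the quartet vertices PLAIN/AUG.  Such a pair encodes an augmented
phylogenetic tree exactly when six combinatorial properties (here called
A1–A6) hold:

A1  at most one topology per 4-subset has γ ≥ 0;
A2  support closure: a supported quartet extends by any fifth taxon on one
    of its sides;
A3  quartets sharing a leaf triple agree on the mark of its median;
A4  every subdivision point of a supported quartet is *supported*: witnessed
    by two overlapping quartets whose shared median is AUG;
A5  a "shrinking" linear relation between γ-values of overlapping quartets;
A6  an additive relation between γ-values of quartets in caterpillar position.

The module stores systems as per-quartet records (γ plus the two median
marks — cross-quartet vertex identity is exactly what A3 certifies), checks
the six properties, and reconstructs the unique augmented tree from a valid
system via split reconstruction plus verification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .augtree import Mark
from .treecore import (
    QuartetTree,
    TreeError,
    check_taxon,
    splits_from_quartets,
    tree_from_splits,
    Split,
    SplitSystem,
    displayed_quartets,
    median,
)

__all__ = [
    "QuartetRecord",
    "EnhancedQuartetSystem",
    "PropertyReport",
    "NotRealizable",
    "PROPERTY_NAMES",
    "read_eqts_tsv",
    "write_eqts_tsv",
    "median_status",
    "is_supported",
    "check_properties",
    "reconstruct_augmented_tree",
]

PROPERTY_NAMES = ("A1", "A2", "A3", "A4", "A5", "A6")


@dataclass(frozen=True)
class QuartetRecord:
    """γ(q) ≥ 0 plus the marks of the two medians of the canonical quartet.

    ``nu_near`` is the mark of the pair_1-side median, ``nu_far`` of the
    pair_2-side median.  Absence of a record encodes γ = −1.  The γ(q)
    subdivision points of the partially subdivided quartet are implicitly
    AUG and need no storage.
    """

    gamma: int
    nu_near: Mark = Mark.PLAIN
    nu_far: Mark = Mark.PLAIN

    def __post_init__(self):
        if self.gamma < 0:
            raise TreeError("gamma must be >= 0 (absence encodes -1)")


@dataclass(frozen=True)
class EnhancedQuartetSystem:
    ground: FrozenSet[str]
    table: Dict[QuartetTree, QuartetRecord]

    def __post_init__(self):
        if len(self.ground) < 4:
            raise TreeError("ground set must have at least 4 taxa")
        if not self.table:
            raise TreeError("support must be non-empty")
        for q in self.table:
            if not q.taxa <= self.ground:
                raise TreeError(f"quartet {q} not on ground set")

    @property
    def support(self) -> Set[QuartetTree]:
        return set(self.table)

    def gamma(self, q: QuartetTree) -> int:
        rec = self.table.get(q)
        return -1 if rec is None else rec.gamma

    def gamma4(self, a: str, b: str, c: str, d: str) -> int:
        """γ(ab|cd) with −1 for absent quartets."""
        return self.gamma(QuartetTree(a, b, c, d))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnhancedQuartetSystem):
            return NotImplemented
        return self.ground == other.ground and self.table == other.table


@dataclass
class PropertyReport:
    """Violation witnesses for each of the six properties."""

    violations: Dict[str, List[str]] = field(
        default_factory=lambda: {name: [] for name in PROPERTY_NAMES}
    )

    @property
    def all_pass(self) -> bool:
        return all(not v for v in self.violations.values())

    def failing(self) -> List[str]:
        return [name for name in PROPERTY_NAMES if self.violations[name]]

    def __str__(self) -> str:
        lines = []
        for name in PROPERTY_NAMES:
            wit = self.violations[name]
            status = "ok" if not wit else f"FAIL ({len(wit)} witness(es))"
            lines.append(f"{name}: {status}")
            for w in wit[:5]:
                lines.append(f"    {w}")
            if len(wit) > 5:
                lines.append(f"    ... and {len(wit) - 5} more")
        return "\n".join(lines)


class NotRealizable(TreeError):
    """The system is not induced by any augmented tree."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("a", "b", "c", "d", "gamma", "nu_ab", "nu_cd")


def write_eqts_tsv(sys: EnhancedQuartetSystem) -> str:
    """Serialize: columns a b c d gamma nu_ab nu_cd; 1 = AUG, 0 = PLAIN."""
    lines = ["#X=" + ",".join(sorted(sys.ground))]
    lines.append("#" + "\t".join(_TSV_COLUMNS))
    for q in sorted(sys.table, key=str):
        rec = sys.table[q]
        lines.append(
            "\t".join(
                (
                    *q.pair_1,
                    *q.pair_2,
                    str(rec.gamma),
                    "1" if rec.nu_near is Mark.AUG else "0",
                    "1" if rec.nu_far is Mark.AUG else "0",
                )
            )
        )
    return "\n".join(lines) + "\n"


def read_eqts_tsv(text: str) -> EnhancedQuartetSystem:
    ground: Set[str] = set()
    table: Dict[QuartetTree, QuartetRecord] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#X="):
                ground.update(check_taxon(t) for t in line[3:].split(",") if t)
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise TreeError(f"line {lineno}: expected 7 tab-separated fields")
        a, b, c, d, g, nab, ncd = fields
        for t in (a, b, c, d):
            check_taxon(t)
        gamma = int(g)
        if gamma < 0:
            raise TreeError(f"line {lineno}: negative gamma (omit absent quartets)")
        q = QuartetTree(a, b, c, d)
        if q.pair_1 != (a, b) or q.pair_2 != (c, d):
            raise TreeError(
                f"line {lineno}: row not canonical (expected {q.pair_1 + q.pair_2})"
            )
        if q in table:
            raise TreeError(f"line {lineno}: duplicate quartet {q}")
        if nab not in "01" or ncd not in "01":
            raise TreeError(f"line {lineno}: marks must be 0 or 1")
        table[q] = QuartetRecord(
            gamma=gamma,
            nu_near=Mark.AUG if nab == "1" else Mark.PLAIN,
            nu_far=Mark.AUG if ncd == "1" else Mark.PLAIN,
        )
        ground.update((a, b, c, d))
    return EnhancedQuartetSystem(ground=frozenset(ground), table=table)


# ---------------------------------------------------------------------------
# Median marks
# ---------------------------------------------------------------------------


def median_status(
    sys: EnhancedQuartetSystem, q: QuartetTree, triple: Iterable[str]
) -> Mark:
    """ν(med_q(x,y,z)) for a triple of three of q's four taxa.

    The median of a triple containing both taxa of pair_1 is the near
    vertex; a triple containing both of pair_2 gives the far vertex.
    """
    rec = sys.table.get(q)
    if rec is None:
        raise TreeError(f"quartet {q} not in support")
    tr = frozenset(triple)
    if len(tr) != 3 or not tr <= q.taxa:
        raise TreeError(f"triple {sorted(tr)} is not 3 of {q}'s taxa")
    if frozenset(q.pair_1) <= tr:
        return rec.nu_near
    return rec.nu_far


# ---------------------------------------------------------------------------
# Support of augmentation points (property A4)
# ---------------------------------------------------------------------------


def _labellings(q: QuartetTree, gamma: int, i: int):
    """All leaf labellings (a,b,c,d, position) compatible with q's symmetries.

    Swapping within a pair is free; swapping the pairs reflects the position
    index i -> gamma + 1 - i (points are counted from the near median).
    """
    (a, b), (c, d) = q.pair_1, q.pair_2
    j = gamma + 1 - i
    return [
        (a, b, c, d, i),
        (b, a, c, d, i),
        (a, b, d, c, i),
        (b, a, d, c, i),
        (c, d, a, b, j),
        (d, c, a, b, j),
        (c, d, b, a, j),
        (d, c, b, a, j),
    ]


def is_supported(
    sys: EnhancedQuartetSystem, q: QuartetTree, i: int
) -> Tuple[bool, Optional[str]]:
    """Is the i-th augmentation point of (q, γ(q)) supported by supp(γ)?

    Positions are counted 1..γ(q) from the near median.  The point is
    supported if some taxon z outside q and some labelling ab|cd of q yield
    quartets q'' = ab|dz with γ = i−1 and q' = bz|cd with γ = γ(q)−i, both
    in the support, whose median of {b, d, z} is marked AUG in both — the
    configuration obtained by hanging z off the point itself in the unique
    tree displaying both witnesses.

    Returns (supported, witness-taxon-or-None).
    """
    g = sys.gamma(q)
    if g < 1:
        raise TreeError(f"{q} has no augmentation point (gamma={g})")
    if not 1 <= i <= g:
        raise TreeError(f"position {i} out of range 1..{g}")
    outside = sorted(sys.ground - q.taxa)
    for a, b, c, d, pos in _labellings(q, g, i):
        for z in outside:
            q2 = QuartetTree(a, b, d, z)  # ab|dz, below the point
            if sys.gamma(q2) != pos - 1:
                continue
            q1 = QuartetTree(b, z, c, d)  # bz|cd, above the point
            if sys.gamma(q1) != g - pos:
                continue
            if (
                median_status(sys, q2, (b, d, z)) is Mark.AUG
                and median_status(sys, q1, (b, d, z)) is Mark.AUG
            ):
                return True, z
    return False, None


# ---------------------------------------------------------------------------
# The six properties
# ---------------------------------------------------------------------------


def _check_a1(sys: EnhancedQuartetSystem, out: List[str]) -> None:
    by_quad: Dict[FrozenSet[str], List[QuartetTree]] = {}
    for q in sys.table:
        by_quad.setdefault(q.taxa, []).append(q)
    for quad, qs in sorted(by_quad.items(), key=lambda kv: sorted(kv[0])):
        if len(qs) > 1:
            out.append(
                f"4-set {{{','.join(sorted(quad))}}} has topologies "
                + ", ".join(sorted(map(str, qs)))
            )


def _check_a2(sys: EnhancedQuartetSystem, out: List[str]) -> None:
    for q in sorted(sys.table, key=str):
        (a, b), (c, d) = q.pair_1, q.pair_2
        for x in sorted(sys.ground - q.taxa):
            same_ab = sys.gamma4(a, b, c, x) >= 0 and sys.gamma4(a, b, d, x) >= 0
            same_cd = sys.gamma4(a, x, c, d) >= 0 and sys.gamma4(b, x, c, d) >= 0
            if not (same_ab or same_cd):
                out.append(f"{q} does not extend by {x} on either side")


def _check_a3(sys: EnhancedQuartetSystem, out: List[str]) -> None:
    qs = sorted(sys.table, key=str)
    for q1, q2 in itertools.combinations(qs, 2):
        shared = q1.taxa & q2.taxa
        if len(shared) < 3:
            continue
        for triple in itertools.combinations(sorted(shared), 3):
            m1 = median_status(sys, q1, triple)
            m2 = median_status(sys, q2, triple)
            if m1 is not m2:
                out.append(
                    f"{q1} and {q2} disagree on the median of "
                    f"{{{','.join(triple)}}}: {m1.value} vs {m2.value}"
                )


def _check_a4(sys: EnhancedQuartetSystem, out: List[str]) -> None:
    for q in sorted(sys.table, key=str):
        g = sys.table[q].gamma
        for i in range(1, g + 1):
            ok, _ = is_supported(sys, q, i)
            if not ok:
                out.append(f"augmentation point {i} of ({q}, {g}) is unsupported")


def _check_a5(sys: EnhancedQuartetSystem, out: List[str]) -> None:
    for a, b, c, d, e in itertools.permutations(sorted(sys.ground), 5):
        g_abcd = sys.gamma4(a, b, c, d)
        g_abce = sys.gamma4(a, b, c, e)
        if not g_abcd > g_abce >= 0:
            continue
        bullet = median_status(sys, QuartetTree(a, b, c, e), (a, c, e)) is Mark.AUG
        expected = g_abcd - g_abce - (1 if bullet else 0)
        actual = sys.gamma4(a, e, c, d)
        if actual != expected:
            out.append(
                f"gamma({a}{e}|{c}{d}) = {actual}, expected {expected} from "
                f"gamma({a}{b}|{c}{d}) = {g_abcd}, gamma({a}{b}|{c}{e}) = {g_abce}"
                f" (median {'AUG' if bullet else 'PLAIN'})"
            )


def _check_a6(sys: EnhancedQuartetSystem, out: List[str]) -> None:
    for a, b, c, d, e in itertools.permutations(sorted(sys.ground), 5):
        g_abcd = sys.gamma4(a, b, c, d)
        g_bcde = sys.gamma4(b, c, d, e)
        if g_abcd < 0 or g_bcde < 0:
            continue
        bullet = median_status(sys, QuartetTree(a, b, c, d), (b, c, d)) is Mark.AUG
        expected = g_abcd + g_bcde + (1 if bullet else 0)
        actual = sys.gamma4(a, b, d, e)
        if actual != expected:
            out.append(
                f"gamma({a}{b}|{d}{e}) = {actual}, expected {expected} from "
                f"gamma({a}{b}|{c}{d}) = {g_abcd}, gamma({b}{c}|{d}{e}) = {g_bcde}"
                f" (median {'AUG' if bullet else 'PLAIN'})"
            )


def check_properties(sys: EnhancedQuartetSystem) -> PropertyReport:
    """Check A1–A6 by direct enumeration; O(|X|^5), fine for |X| ≤ 12."""
    report = PropertyReport()
    _check_a1(sys, report.violations["A1"])
    _check_a2(sys, report.violations["A2"])
    _check_a3(sys, report.violations["A3"])
    _check_a4(sys, report.violations["A4"])
    if len(sys.ground) >= 5:
        _check_a5(sys, report.violations["A5"])
        _check_a6(sys, report.violations["A6"])
    return report


# ---------------------------------------------------------------------------
# Reconstruction (encoding theorem)
# ---------------------------------------------------------------------------


def reconstruct_augmented_tree(sys: EnhancedQuartetSystem):
    """Reconstruct the unique augmented tree (T, ν) with γ_T = γ and ν_T = ν.

    Strategy: amalgamate the support's quartets into splits, build the tree,
    read each interior vertex's mark off any supported quartet in which it
    survives as a median, and verify the induced system reproduces the input
    exactly.  Raises :class:`NotRealizable` otherwise — by the encoding
    theorem this happens precisely when some property A1–A6 fails.
    """
    from .augtree import AugmentedTree, induced_eqts

    X = sys.ground
    splits = splits_from_quartets(sys.support, X)
    nontrivial = {s for s in splits if not s.is_trivial}
    trivial = {Split(X, {t}, X - {t}) for t in X}
    full = SplitSystem(X, nontrivial | trivial)
    if not _system_is_compatible(full):
        raise NotRealizable("splits", "amalgamated splits are incompatible")
    tree = tree_from_splits(full)
    if tree.is_star():
        raise NotRealizable("splits", "support induces no non-trivial split")
    if displayed_quartets(tree) != sys.support:
        raise NotRealizable(
            "support", "support is not the displayed-quartet set of any tree"
        )
    # read interior marks off surviving medians
    marks: Dict[int, Mark] = {}
    for q in sys.support:
        for triple in itertools.combinations(sorted(q.taxa), 3):
            v = median(tree, *triple)
            m = median_status(sys, q, triple)
            prev = marks.get(v)
            if prev is None:
                marks[v] = m
            elif prev is not m:
                raise NotRealizable(
                    "marks", f"conflicting marks for the median of {triple}"
                )
    aug = {v for v, m in marks.items() if m is Mark.AUG}
    try:
        cand = AugmentedTree(tree, aug)
    except TreeError as exc:
        raise NotRealizable("marks", str(exc)) from exc
    if induced_eqts(cand) != sys:
        raise NotRealizable("verify", "candidate tree does not induce the system")
    return cand


def _system_is_compatible(system: SplitSystem) -> bool:
    from .treecore import is_compatible

    return is_compatible(system)
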