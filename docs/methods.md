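# Methods

## Objects

**Unrooted trees.** Trees are simple undirected graphs with taxa on the
degree-1 vertices (`treecore.UnrootedTree`).  Two modes exist: phylogenetic
(no degree-2 vertices) and partially subdivided (finitely many degree-2
*subdivision points*, none adjacent to a leaf).  Vertex ids are opaque
integers; interior vertices are addressed from the outside through median
triples, so nothing outside a tree object ever depends on its internal
numbering.

**Splits and quartets.** An edge of a phylogenetic tree induces a full
split A|B of the taxa; a split system corresponds to a tree exactly when it
is pairwise compatible and contains the trivial splits (tree construction
goes through the laminar family of clusters away from the smallest taxon).
A quartet tree ab|cd is the binary 4-leaf tree separating {a,b} from
{c,d}; a tree *displays* ab|cd when its restriction to those four leaves
is that tree.  `splits_from_quartets` recovers the non-trivial splits of a
tree from its displayed quartets by greedy maximal extension of each
quartet's two sides; this is exact on displayed-quartet sets (the maximal
extension of a displayed quartet is always a full split), and the test
suite cross-checks it against exhaustive enumeration of all bipartitions
up to n = 8.

**Augmented trees.** An augmented tree (T, ν) adds a {◦, •} marking:
leaves are ◦, subdivision points are •, other interior vertices free.  In
the network reading, • records a reticulation — a horizontal-transfer
recipient — after arc directions are forgotten.

**Enhanced quartet tree systems.** (γ, ν) with γ assigning each quartet
topology −1 (absent) or the number of subdivision points on its interior
edge, and ν marking the quartet medians.  We store ν per quartet as the two
median marks only.  Cross-quartet vertex identity is deliberately not
modelled: property A3 is precisely the assertion that quartets sharing a
leaf triple agree on the triple's median, so a global vertex map would
either duplicate A3 or presuppose it.  The γ(q) subdivision points of a
record are implicitly •, so they need no storage either.

## The induced system and its inverse

For a displayed quartet q = xy|tz of an augmented phylogenetic tree, γ_T(q)
counts the augmentation vertices strictly between m₁ = med(x,y,t) and
m₂ = med(t,z,x) — both endpoints excluded — and the record's marks are
ν(m₁), ν(m₂).  The six properties A1–A6 checked by `eqts.check_properties`
characterise the systems of this form; the checker works by direct
enumeration (O(|X|⁵) for A5/A6, with A4's witness search over one outside
taxon and the quartet's eight symmetry labellings), which at the package's
target scale |X| ≤ 12 runs in well under a second.

Reconstruction (`eqts.reconstruct_augmented_tree`) does not re-play the
inductive uniqueness argument; it amalgamates the support into splits,
builds the tree, rejects if the tree's displayed quartets differ from the
support, reads each interior vertex's mark off any supported quartet in
which the vertex survives as a median (every interior vertex of a
non-star tree does, via one leaf from each of three of its components),
and finally verifies that the candidate induces the input system record
for record.  The final verification makes the procedure conservative: any
reconstruction it returns is correct by construction, and failure at any
stage coincides, on everything we have tested (200 random trees and 200
single-record mutations per run), with a property violation.

**A4's positional reading.** A subdivision point is indexed by its position
i ∈ 1..γ(q) from the pair_1-side median; its witnesses must satisfy
γ(q″) = i−1 and γ(q′) = γ(q)−i, with the position reflected
(i ↦ γ(q)+1−i) when the quartet is read from the other pair.  This is the
reading under which induced systems are exactly supported (hanging the
witness taxon at the point itself), and the round-trip harness confirms
it on every generated tree.

## Independence of the six properties

`genfix.independence_fixtures` ships nine small systems, one or two per
property.  The A1–A4 fixtures are explicit four- and five-taxon tables;
those for A5 and A6 are read off six- and seven-leaf marked trees with a
prescribed, deliberately non-induced γ.  The suite establishes that each
of A1, A2, A3, A4 and A6 can fail while all other properties hold.

For A5 (the shrinking relation γ(ae|cd) = γ(ab|cd) − γ(ab|ce) − [•]) the
situation is different, and worth recording.  Whenever ae|cd is in the
support, the A6 instance on (b, a, e, c, d) *is* the A5 equation, so an
A5 violation of that kind always drags A6 down with it; and violations of
the absence kind (ae|cd missing although the relation demands a
non-negative value) require an unwitnessed γ position, which A4 forbids.
Consistent with this, exhaustive searches over all mark/γ assignments on
the relevant five- and six-taxon supports, and randomized mutation
searches over induced systems, produced systems failing exactly A6 but
none failing exactly A5: the two A5 fixtures here fail A6 as well.  We
conjecture that A5 is implied by A1–A4 together with A6; the package keeps
A5 as a separate check regardless, both for symmetry and because its
witnesses are far more local (hence more readable) than A6's.

## Arboreal networks and orientation

A valid network is a DAG whose planted undirected form is a phylogenetic
tree, with reticulations of outdegree 1, roots of outdegree ≥ 2 and no
non-root degree-2 vertices.  These local conditions force
#reticulations = #roots − 1 and, per interior vertex of the underlying
tree, the degree profile (in 2, out 1) at • vertices and (in 1, out 2)
at ◦ vertices.

`orient.check_orient` therefore treats orientation as pure constraint
propagation: leaf edges are fixed by the boundary (handle edges leave
their leaves, X-leaf edges enter theirs), and any interior vertex with two
decided edges forces its third via `forced_direction`.  On a tree the
frontier of undecided edges always contains such a vertex, so propagation
never stalls, every decision is forced, and the admissible orientation is
unique when it exists — which also makes the outcome independent of the
reference handle ρ (accepted for interface compatibility only).  A
conflict surfaces either at a vertex whose profile cannot be met
(`VERTEX_INFEASIBLE`, with the vertex as witness) or at the final
validation, which rebuilds the network, revalidates it and checks that
its underlying augmented tree is augmentation-equivalent to the input
(`POST_VALIDATION`).  The staged alternative — contract to the core
spanned by the handles and the reticulation-adjacent leaves, then
repeatedly collapse cherries — is mathematically the same forced
propagation scheduled differently; `contract_to_core` is still provided
(with the edge-to-path lookup τ and the pruned-edge orientations) because
the core is a useful diagnostic object in its own right.  One subtlety: a
reticulation above a pruned all-◦ subtree legitimately survives in the
core as a degree-2 subdivision point (its single out-arc went to the
pruned side); only a reticulation reduced to degree ≤ 1, or left adjacent
to a leaf at degree 2, is a certified failure (`PRUNE_STRANDED_AUG`).

`brute_force_orient` is the independent oracle: it enumerates every
orientation of the interior edges (leaf edges fixed), filters by the
degree profiles, and validates survivors exactly as `check_orient` does.
Uniqueness (0 or 1 admissible orientations) is asserted over 500 seeded
networks per run.  `detect_forbidden_configuration` flags connected all-◦
leafless regions whose entire boundary consists of • vertices carrying
exactly one X-leaf: each boundary edge is then forced inward, so some
region vertex would need outdegree 3.  The witness is sufficient for
failure, not necessary.

## Generators

* `random_binary_tree(n, seed)` — stepwise leaf addition with a uniform
  random edge choice per step; n ≥ 3.
* `random_augmented_tree(n, p_aug, seed)` — independent • marks on
  interior vertices.  Default p_aug = 0.3; the encoding round-trip harness
  uses p_aug ∈ {0.2, 0.5} and n ≤ 9, sizes at which the O(|X|⁵) property
  checker and the exhaustive test oracles stay fast while every structural
  case (nested marks, marks at cherries, mark-free trees) is exercised.
* `random_arboreal_network(n_leaves, n_trees, seed)` — partitions the taxa
  into components of ≥ 2 leaves (so every component has an arc for a
  transfer to subdivide), builds a rooted binary tree per component, and
  adds one transfer arc per edge of a random tree-of-trees, the tail
  subdividing a random donor arc and the head a random recipient arc.
  Acyclicity is structural (one connector per component-tree edge), and
  every output validates; the orientation harness runs |X| ≤ 12 with 1–4
  roots, plus one 200-leaf instance as a scaling smoke test.

All generators draw from a single `numpy` generator seeded per call; same
seed, same output.

What the simulations do **not** emulate: biologically calibrated transfer
rates, branch lengths, clocks or sequence evolution — the generators
produce uniform-ish topologies whose purpose is to cover combinatorial
structure, not to mimic empirical HGT frequency.  Passing round trips
therefore certify the combinatorial claims (encoding, uniqueness,
orientation) over the topology space, and say nothing about inference
from data.

## Numerical and formatting choices

* Quartets are canonicalized (pairs sorted, smallest-taxon pair first);
  splits store the part containing the smallest ground taxon first; the
  Newick writer orders children by smallest descendant taxon.  All output
  is therefore bit-stable, and equivalence checks reduce to string
  equality of canonical serializations.
* Newick is parsed by `dendropy`; a rooted-style degree-2 top vertex is
  suppressed on read (standard unrooted convention).  Branch lengths are
  rejected rather than ignored.  The augmented dialect marks • with the
  internal node label `AUG`, which is reserved.
* Absent quartets enter the A5/A6 equation checks with value −1, so a
  required quartet that is missing is a violation rather than a skip.
* Degenerate inputs: star trees induce no system and are rejected;
  orientation requires ≥ 3 leaves and non-empty X and R; the degenerate
  all-◦ core keeps the handle plus one synthetic-taxon attachment stub.

## Limitations

* Property checking is brute-force O(|X|⁵); comfortable to |X| ≈ 15, not
  intended for hundreds of taxa.  Orientation, by contrast, is near-linear
  and tested at 200 leaves.
* `splits_from_quartets` is exact on displayed-quartet sets; on arbitrary
  quartet inputs the greedy extension may miss splits that exhaustive
  enumeration would find (the reconstruction pipeline is unaffected, since
  its final verification rejects any such input anyway).
* Orientation is restricted to binary augmented trees with a known root
  set; searching over unknown root sets, and non-binary orientation, are
  out of scope.
* Estimating augmentation marks or quartet systems from sequence data is
  out of scope; the package starts from combinatorial objects.
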