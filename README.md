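# arbornet

Combinatorial tools for **multi-rooted phylogenetic networks** that model
horizontal gene transfer (HGT) between bacteria living in different
ecological niches.  When no single species tree can be assumed, the
evolution of a set *X* of organisms can instead be described by an
*arboreal network*: a forest of rooted phylogenetic trees (one per niche)
joined by transfer arcs, i.e. a multi-rooted DAG in which every
*reticulation* (indegree ≥ 2 vertex, the recipient of a transfer) has
outdegree one, and whose planted, undirected form is an unrooted
phylogenetic tree.

`arbornet` implements the two combinatorial primitives such networks rest
on:

1. **Quartet encodings of augmented trees.**  Forgetting the arc directions
   of a planted network *N* leaves an *augmented tree* 𝒰(N) = (T, ν): an
   unrooted tree on X ∪ R(N) whose reticulations are still marked
   ν(v) = • ("AUG").  An augmented tree is in turn encoded by its
   *enhanced quartet tree system* (γ_T, ν_T): for every displayed quartet
   xy|tz, γ_T counts the marked vertices strictly between the median of
   {x,y,t} and the median of {t,z,x}, and ν_T records the marks of those
   two medians.  A pair (γ, ν) arises from a (unique) augmented tree
   exactly when six local properties A1–A6 hold — e.g. A1: one topology
   per 4-set; A3: quartets sharing a leaf triple agree on its median's
   mark; A6: γ(ab|de) = γ(ab|cd) + γ(bc|de) + [ν(med_{ab|cd}(b,c,d)) = •].
   The package checks the properties, exhibits their (in)dependence with a
   fixture suite, and reconstructs the tree from a valid system
   (split amalgamation + verification).

2. **Orientation (the Check procedure).**  Given a binary augmented tree on
   X ∪ R and the designated root handles R, direct the edges so that every
   • vertex becomes a reticulation (in 2, out 1) and every ◦ vertex a tree
   vertex (in 1, out 2), with handle edges leaving their leaves and X-leaf
   edges entering theirs.  On a tree every direction is forced from the
   leaf boundary, so the admissible orientation is unique when it exists;
   `check_orient` finds it — or certifies failure — in near-linear time,
   with an exhaustive oracle (`brute_force_orient`) and a diagnostic for
   the forbidden all-◦ configuration fenced in by leaf-carrying
   reticulations.

## Worked example

The 5-leaf caterpillar with cherries {1,2} and {4,5}, middle vertex marked:

```python
>>> import arbornet as an
>>> t = an.read_augmented_newick("((1,2),3,(4,5))AUG;")
>>> s = an.induced_eqts(t)
>>> [(str(q), r.gamma) for q, r in sorted(s.table.items(), key=lambda kv: str(kv[0]))]
[('12|34', 0), ('12|35', 0), ('12|45', 1), ('13|45', 0), ('23|45', 0)]
>>> s.gamma4("1", "3", "2", "4")       # topology not displayed by the tree
-1
>>> an.check_properties(s).all_pass
True
>>> an.write_augmented_newick(an.reconstruct_augmented_tree(s))
'(1,2,(3,(4,5))AUG);'
```

The quartet 12|45 spans the marked vertex, so it carries one subdivision
point (γ = 1); the other displayed quartets carry none; undisplayed
topologies get γ = −1.  Reconstruction returns the marked caterpillar, up
to augmentation-equivalence.

Networks round-trip through their underlying trees:

```python
>>> from arbornet import genfix
>>> net = genfix.random_arboreal_network(5, 2, seed=0)   # 2 roots, 1 reticulation
>>> u, R = an.underlying_augmented(net)
>>> res = an.check_orient(u, u.taxa - R, R)
>>> res.success and an.networks_equal(res.network, net)
True
```

The same operations are available from the shell:

```sh
arbornet sim network --n 9 --k-trees 3 --seed 4 --out net.arcs
arbornet underlying --net net.arcs --out t.nwk --roots-out roots.txt
arbornet orient --tree t.nwk --roots roots.txt --out net2.arcs   # prints SUCCESS
arbornet induce --tree t.nwk --out sys.tsv
arbornet check --eqts sys.tsv                                    # A1..A6: ok
```

## Layout

| module | contents |
| --- | --- |
| `arbornet.treecore` | unrooted trees, Newick I/O, splits, quartets, medians, restriction, split amalgamation |
| `arbornet.augtree` | augmented trees, marked-Newick dialect, induced systems |
| `arbornet.eqts` | enhanced quartet tree systems, TSV I/O, properties A1–A6, reconstruction |
| `arbornet.arboreal` | arboreal networks, planting, underlying augmented tree, arc-list I/O |
| `arbornet.orient` | forced-direction propagation, core contraction, brute-force oracle, forbidden configuration |
| `arbornet.genfix` | seeded simulators and the independence fixture suite |

See `docs/methods.md` for the model, the algorithms and their assumptions,
and known limitations.
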