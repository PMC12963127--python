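import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arbornet as an
from arbornet import genfix
from arbornet.treecore import (
    QuartetTree,
    Split,
    SplitSystem,
    TreeError,
    quartet_topology,
    quartets_of_split,
    splits_compatible,
)


def exhaustive_splits_from_quartets(quartets, ground):
    """Independent oracle: enumerate every non-trivial bipartition of the
    ground set and keep those whose cross-quartets are all present."""
    X = sorted(ground)
    Q = set(quartets)
    out = set()
    for r in range(2, len(X) - 1):
        for part_a in itertools.combinations(X, r):
            a = frozenset(part_a)
            b = frozenset(X) - a
            if all(
                QuartetTree(a1, a2, b1, b2) in Q
                for a1, a2 in itertools.combinations(sorted(a), 2)
                for b1, b2 in itertools.combinations(sorted(b), 2)
            ):
                out.add(Split(X, a, b))
    return out


class TestNewick:
    def test_cat5_splits(self, cat5):
        nontrivial = {str(s) for s in an.splits_of_tree(cat5) if not s.is_trivial}
        assert nontrivial == {"1,2|3,4,5", "1,2,3|4,5"}

    def test_unlabelled_top_leaf_errors(self):
        with pytest.raises(TreeError):
            an.read_newick("((1,2));")

    @pytest.mark.parametrize("bad", ["(a,b,c)", "(a,b,(c,d);", "((a,a),b,c);"])
    def test_malformed(self, bad):
        with pytest.raises(TreeError):
            an.read_newick(bad)

    def test_branch_lengths_rejected(self):
        with pytest.raises(TreeError):
            an.read_newick("((a:1,b:2),c,d);")

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_random_trees(self, seed):
        t = genfix.random_binary_tree(4 + seed % 7, seed)
        text = an.write_newick(t)
        assert an.write_newick(an.read_newick(text)) == text

    def test_degree_two_vertex_rejected_in_phylogenetic_mode(self):
        with pytest.raises(TreeError):
            an.read_newick("((a,(b,c)),(d),e);")


class TestSplits:
    def test_split_canonical_form(self):
        s = Split("abcde", {"d", "e"}, {"a", "b", "c"})
        assert s.part_a == frozenset("abc")
        assert str(s) == "a,b,c|d,e"

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_binary_tree_split_count(self, n):
        t = genfix.random_binary_tree(n, seed=n)
        assert len(an.splits_of_tree(t)) == 2 * n - 3

    def test_star_tree_has_only_trivial_splits(self):
        t = an.read_newick("(a,b,c,d,e);")
        assert all(s.is_trivial for s in an.splits_of_tree(t))

    def test_compatibility(self, cat5):
        sigma = an.splits_of_tree(cat5)
        assert an.is_compatible(sigma)
        X = cat5.taxa
        clash = SplitSystem(
            X,
            [Split(X, "12", "345"), Split(X, "13", "245")],
        )
        assert not an.is_compatible(clash)
        assert an.is_compatible(SplitSystem(X, [Split(X, "12", "345")]))

    def test_tree_from_splits_examples(self, cat5):
        X = cat5.taxa
        trivial = [Split(X, {t}, X - {t}) for t in X]
        sys = SplitSystem(X, trivial + [Split(X, "12", "345"), Split(X, "123", "45")])
        rebuilt = an.tree_from_splits(sys)
        assert an.write_newick(rebuilt) == an.write_newick(cat5)
        star = an.tree_from_splits(SplitSystem(X, trivial))
        assert star.is_star()
        with pytest.raises(TreeError):
            an.tree_from_splits(
                SplitSystem(X, trivial + [Split(X, "12", "345"), Split(X, "13", "245")])
            )

    def test_missing_trivial_split_errors(self, cat5):
        X = cat5.taxa
        with pytest.raises(TreeError):
            an.tree_from_splits(SplitSystem(X, [Split(X, "12", "345")]))

    @pytest.mark.parametrize("seed", range(15))
    def test_split_equivalence_round_trip(self, seed):
        t = genfix.random_binary_tree(4 + seed % 7, seed)
        rebuilt = an.tree_from_splits(an.splits_of_tree(t))
        assert an.write_newick(rebuilt) == an.write_newick(t)


class TestQuartets:
    @given(
        taxa=st.lists(
            st.text("abcdefghij0123456789", min_size=1, max_size=3),
            min_size=4,
            max_size=4,
            unique=True,
        ),
        within1=st.booleans(),
        within2=st.booleans(),
        pair_swap=st.booleans(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_canonicalization_is_symmetry_invariant(
        self, taxa, within1, within2, pair_swap
    ):
        a, b, c, d = taxa
        p1 = (b, a) if within1 else (a, b)
        p2 = (d, c) if within2 else (c, d)
        args = (*p2, *p1) if pair_swap else (*p1, *p2)
        assert QuartetTree(*args) == QuartetTree(a, b, c, d)
        assert QuartetTree(a, b, c, d).same_side(a, b)
        assert not QuartetTree(a, b, c, d).same_side(a, c)

    def test_canonical_form(self):
        q = QuartetTree("d", "c", "b", "a")
        assert q.pair_1 == ("a", "b") and q.pair_2 == ("c", "d")
        assert str(QuartetTree("z", "b", "d", "c")) == "bz|cd"

    def test_cat5_displayed(self, cat5):
        assert {str(q) for q in an.displayed_quartets(cat5)} == {
            "12|34",
            "12|35",
            "12|45",
            "13|45",
            "23|45",
        }

    def test_star_displays_nothing(self):
        t = an.read_newick("(a,b,c,d,e);")
        assert an.displayed_quartets(t) == set()

    def test_two_quartet_closure_tree_displays_five(self):
        # the unique binary tree on {a,b,c,d,z} displaying ab|dz and bz|dc
        t = an.read_newick("((a,b),z,(c,d));")
        Q = an.displayed_quartets(t)
        assert QuartetTree("a", "b", "d", "z") in Q
        assert QuartetTree("b", "z", "d", "c") in Q
        assert len(Q) == 5

    def test_at_most_one_topology_per_4_set(self):
        t = genfix.random_binary_tree(8, seed=3)
        Q = an.displayed_quartets(t)
        seen = {}
        for q in Q:
            assert q.taxa not in seen
            seen[q.taxa] = q

    def test_union_over_splits(self, cat5):
        per_split = set()
        for s in an.splits_of_tree(cat5):
            if not s.is_trivial:
                per_split |= quartets_of_split(s)
        assert per_split == an.displayed_quartets(cat5)


class TestRestrictMedian:
    def test_restrict_examples(self, cat5):
        sub, _ = an.restrict_tree(cat5, {"1", "3", "4", "5"})
        assert quartet_topology(sub, "1", "3", "4", "5") == QuartetTree("1", "3", "4", "5")
        sub2, _ = an.restrict_tree(cat5, {"1", "2", "3", "4"})
        assert quartet_topology(sub2, "1", "2", "3", "4") == QuartetTree("1", "2", "3", "4")

    def test_restrict_to_full_leaf_set_is_identity(self, cat5):
        sub, vmap = an.restrict_tree(cat5, cat5.taxa)
        assert an.write_newick(sub) == an.write_newick(cat5)
        assert set(vmap) == set(cat5.graph)

    def test_restrict_rejects_non_leaves(self, cat5):
        with pytest.raises(TreeError):
            an.restrict_tree(cat5, {"1", "zz"})

    def test_median_examples(self, cat5):
        v = an.median(cat5, "1", "2", "4")
        assert set(cat5.graph[v]) >= {cat5.leaf_of("1"), cat5.leaf_of("2")}

    @pytest.mark.parametrize("seed", range(5))
    def test_median_symmetry(self, seed):
        t = genfix.random_binary_tree(7, seed)
        for x, y, z in itertools.combinations(sorted(t.taxa), 3):
            m = an.median(t, x, y, z)
            assert m == an.median(t, z, x, y) == an.median(t, y, z, x)

    @pytest.mark.parametrize("seed", range(5))
    def test_median_consistency_under_restriction(self, seed):
        t = genfix.random_binary_tree(7, seed)
        for quad in itertools.combinations(sorted(t.taxa), 4):
            sub, vmap = an.restrict_tree(t, quad)
            for triple in itertools.combinations(quad, 3):
                assert vmap[an.median(t, *triple)] == an.median(sub, *triple)


class TestSplitsFromQuartets:
    def test_cat5(self, cat5):
        Q = an.displayed_quartets(cat5)
        got = {str(s) for s in an.splits_from_quartets(Q, cat5.taxa)}
        assert got == {"1,2|3,4,5", "1,2,3|4,5"}

    def test_single_quartet(self):
        q = QuartetTree("a", "b", "c", "d")
        got = an.splits_from_quartets({q}, "abcd")
        assert {str(s) for s in got} == {"a,b|c,d"}

    def test_dropped_quartet_loses_a_split(self, cat5):
        Q = an.displayed_quartets(cat5) - {QuartetTree("1", "3", "4", "5")}
        got = {str(s) for s in an.splits_from_quartets(Q, cat5.taxa)}
        assert got == {"1,2|3,4,5"}

    @pytest.mark.parametrize("seed", range(12))
    def test_against_exhaustive_oracle(self, seed):
        t = genfix.random_binary_tree(5 + seed % 4, seed)
        Q = an.displayed_quartets(t)
        expected = exhaustive_splits_from_quartets(Q, t.taxa)
        assert set(an.splits_from_quartets(Q, t.taxa).splits) == expected
        nontrivial = {s for s in an.splits_of_tree(t) if not s.is_trivial}
        assert expected == nontrivial
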