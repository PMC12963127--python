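import pytest

import arbornet as an
from arbornet import genfix
from arbornet.augtree import AugmentedTree, Mark
from arbornet.orient import (
    Direction,
    FailureCode,
    brute_force_orient,
    check_orient,
    contract_to_core,
    detect_forbidden_configuration,
    forced_direction,
)
from arbornet.treecore import TreeError


def instance_from_network(net):
    t, R = an.underlying_augmented(net)
    return t, t.taxa - R, R


class TestForcedDirection:
    @pytest.mark.parametrize(
        "mark,n_in,n_out,expected",
        [
            (Mark.AUG, 1, 1, Direction.IN),
            (Mark.AUG, 2, 0, Direction.OUT),
            (Mark.AUG, 0, 2, Direction.INFEASIBLE),
            (Mark.PLAIN, 1, 1, Direction.OUT),
            (Mark.PLAIN, 0, 2, Direction.IN),
            (Mark.PLAIN, 2, 0, Direction.INFEASIBLE),
            (Mark.AUG, 2, 1, Direction.SATISFIED),
            (Mark.PLAIN, 1, 2, Direction.SATISFIED),
            (Mark.PLAIN, 3, 0, Direction.INFEASIBLE),
        ],
    )
    def test_profiles(self, mark, n_in, n_out, expected):
        assert forced_direction(mark, n_in, n_out) is expected

    def test_underdetermined_rejected(self):
        with pytest.raises(TreeError):
            forced_direction(Mark.PLAIN, 1, 0)


class TestCheckOrient:
    def test_single_root_all_plain(self):
        t = an.read_augmented_newick("((R_1,a),(b,c));")
        res = check_orient(t, {"a", "b", "c"}, {"R_1"})
        assert res.success
        net = res.network
        assert len(net.roots) == 1
        assert not net.reticulations
        oracle = brute_force_orient(t, {"a", "b", "c"}, {"R_1"})
        assert len(oracle) == 1 and an.networks_equal(net, oracle[0])

    def test_net9_round_trip(self, net9):
        t, X, R = instance_from_network(net9)
        res = check_orient(t, X, R)
        assert res.success
        assert an.networks_equal(res.network, net9)

    @pytest.mark.parametrize("seed", range(40))
    def test_random_round_trips(self, seed):
        net = genfix.random_arboreal_network(8 + seed % 5, 1 + seed % 4, seed)
        t, X, R = instance_from_network(net)
        res = check_orient(t, X, R)
        assert res.success
        assert an.networks_equal(res.network, net)
        assert len(res.network.reticulations) == len(R) - 1

    @pytest.mark.parametrize("seed", range(10))
    def test_rho_independence(self, seed):
        net = genfix.random_arboreal_network(9, 3, seed)
        t, X, R = instance_from_network(net)
        nets = [check_orient(t, X, R, rho=r).network for r in sorted(R)]
        for other in nets[1:]:
            assert an.networks_equal(nets[0], other)

    def test_swapped_root_set_agrees_with_oracle(self, net9):
        # swap a root handle with an ordinary leaf: outcome must match the
        # exhaustive enumeration under the altered boundary conditions
        t, X, R = instance_from_network(net9)
        x = sorted(X)[0]
        r = sorted(R)[0]
        X2, R2 = (X - {x}) | {r}, (R - {r}) | {x}
        res = check_orient(t, X2, R2)
        assert res.success == (len(brute_force_orient(t, X2, R2)) == 1)

    def test_forbidden_configuration_fails_at_centre(self):
        t, X, R = genfix.forbidden_fixture()
        res = check_orient(t, X, R)
        assert not res.success
        assert res.code is FailureCode.VERTEX_INFEASIBLE
        assert res.witness in {v for v in t.tree.graph if t.mark(v) is Mark.PLAIN}

    def test_repaired_configuration_succeeds(self):
        t, X, R = genfix.forbidden_fixture_repaired()
        res = check_orient(t, X, R)
        assert res.success


class TestBruteForce:
    def test_net9_unique_orientation(self, net9):
        t, X, R = instance_from_network(net9)
        nets = brute_force_orient(t, X, R)
        assert len(nets) == 1
        assert an.networks_equal(nets[0], net9)

    def test_forbidden_fixture_has_none(self):
        t, X, R = genfix.forbidden_fixture()
        assert brute_force_orient(t, X, R) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_agreement_with_check(self, seed):
        import random

        rng = random.Random(seed)
        net = genfix.random_arboreal_network(8, 1 + seed % 3, seed)
        t, X, R = instance_from_network(net)
        if rng.random() < 0.5:
            # scramble the instance by reassigning one leaf's side
            x = rng.choice(sorted(X))
            r = rng.choice(sorted(R))
            X, R = (X - {x}) | {r}, (R - {r}) | {x}
        res = check_orient(t, X, R)
        nets = brute_force_orient(t, X, R)
        assert len(nets) <= 1
        assert res.success == (len(nets) == 1)
        if res.success:
            assert an.networks_equal(res.network, nets[0])


class TestContraction:
    def test_prune_directions_point_outward(self, net9):
        t, X, R = instance_from_network(net9)
        cc = contract_to_core(t, X, R, min(R))
        assert cc.failure is None
        for (tail, head) in cc.partial.values():
            # heads of pruned arcs lie farther from the core than tails
            assert head not in cc.core.tree.graph

    def test_core_leaves_are_roots_or_aug_adjacent(self, net9):
        t, X, R = instance_from_network(net9)
        cc = contract_to_core(t, X, R, min(R))
        tree = cc.core.tree
        for v in tree.graph:
            if tree.is_leaf(v):
                taxon = tree.leaf_map[v]
                adj_aug = any(u in cc.core.aug for u in tree.graph[v])
                assert taxon in R or adj_aug

    def test_tau_paths_tile_unpruned_edges(self, net9):
        t, X, R = instance_from_network(net9)
        cc = contract_to_core(t, X, R, min(R))
        covered = set()
        for path in cc.tau.values():
            covered.update(frozenset(e) for e in zip(path, path[1:]))
        pruned = set(cc.partial)
        alledges = {frozenset(e) for e in t.tree.graph.edges()}
        assert covered | pruned == alledges
        assert not covered & pruned

    def test_degenerate_all_plain_core(self):
        t = an.read_augmented_newick("((R_1,a),(b,c));")
        cc = contract_to_core(t, {"a", "b", "c"}, {"R_1"}, "R_1")
        assert cc.failure is None
        assert len(cc.core.tree.graph) == 2  # the handle and its attachment

    def test_stranded_reticulation_detected(self):
        # AUG vertex between two all-PLAIN subtrees: both sides prune away
        t = an.read_augmented_newick("(((a,b),(c,d))AUG,R_1,e);")
        cc = contract_to_core(t, {"a", "b", "c", "d", "e"}, {"R_1"}, "R_1")
        assert cc.failure is not None
        assert cc.failure[0] is FailureCode.PRUNE_STRANDED_AUG
        res = check_orient(t, {"a", "b", "c", "d", "e"}, {"R_1"})
        assert not res.success


class TestForbiddenConfiguration:
    def test_f3_witness(self):
        t, X, R = genfix.forbidden_fixture()
        wits = detect_forbidden_configuration(t, X, R)
        assert len(wits) == 1 and len(wits[0]) == 1

    def test_repair_removes_witness(self):
        t, X, R = genfix.forbidden_fixture_repaired()
        assert detect_forbidden_configuration(t, X, R) == []

    def test_all_plain_tree_clean(self):
        net = genfix.random_arboreal_network(10, 1, 5)
        t, X, R = instance_from_network(net)
        assert detect_forbidden_configuration(t, X, R) == []


class TestScaling:
    def test_large_instance_under_wall_clock(self):
        import time

        net = genfix.random_arboreal_network(196, 4, 7)
        t, X, R = instance_from_network(net)
        start = time.monotonic()
        res = check_orient(t, X, R)
        elapsed = time.monotonic() - start
        assert res.success
        assert len(t.tree.taxa) == 200
        assert elapsed < 5.0
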