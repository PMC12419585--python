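"""Synchronous dynamics: successors, attractors, basins, clamping."""

import numpy as np
import pytest

from boolgrn import (
    enumerate_attractors,
    generate_network,
    perturb,
    report_cycles,
    successor,
)
from conftest import constant_network, identity_network
from oracles import naive_attractors, naive_successor_table

# hand-evaluated transition table of the toy3 fixture (A bit0, B bit1, C bit2)
TOY3_TRANSITIONS = {0: 4, 4: 6, 2: 5, 6: 6, 1: 2, 5: 2, 3: 3, 7: 2}


class TestSuccessor:
    def test_identity_rules_fix_every_state(self):
        net = identity_network(4)
        for s in range(16):
            assert successor(net, s) == s

    def test_all_constant_rules_map_to_constant_state(self):
        net = constant_network(4, bits=[1, 0, 1, 0])
        target = 0b0101
        for s in range(16):
            assert successor(net, s) == target

    def test_toy_network_matches_hand_evaluation(self, toy3):
        for s, nxt in TOY3_TRANSITIONS.items():
            assert successor(toy3, s) == nxt

    def test_out_of_range_state_rejected(self, toy3):
        with pytest.raises(ValueError):
            successor(toy3, 8)


class TestEnumerateAttractors:
    def test_identity_network_all_fixed_points(self):
        res = enumerate_attractors(identity_network(4))
        assert len(res) == 16
        assert all(a.length == 1 and a.basin_size == 1 for a in res.attractors)

    def test_constant_network_single_global_attractor(self):
        res = enumerate_attractors(constant_network(5, bits=[1, 1, 0, 0, 1]))
        assert len(res) == 1
        (a,) = res.attractors
        assert a.states == (0b10011,)
        assert a.basin_size == 32

    def test_toy_network_attractors_and_basins(self, toy3):
        res = enumerate_attractors(toy3)
        got = {a.states: a.basin_size for a in res.attractors}
        # from the hand table: fixed points 3 and 6, plus the 2-cycle (2, 5)
        assert got == {(3,): 1, (6,): 3, (2, 5): 4}

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_naive_walker_on_random_networks(self, seed):
        net = generate_network(10, 1.5, 3, seed=seed)
        res = enumerate_attractors(net)
        want = naive_attractors(net)
        got = {a.states: a.basin_size for a in res.attractors}
        assert got == want
        assert sum(got.values()) == 1024

    def test_capacity_error_recommends_sampling(self):
        net = generate_network(22, 1.0, 2, seed=0)
        with pytest.raises(ValueError, match="sampled"):
            enumerate_attractors(net, max_exhaustive_genes=20)

    def test_sampled_mode_is_subset_of_exhaustive(self):
        net = generate_network(10, 1.5, 3, seed=6)
        full = enumerate_attractors(net)
        sub = enumerate_attractors(net, mode="sampled", n_samples=200, seed=1)
        assert not sub.exact
        assert sub.cycle_keys() <= full.cycle_keys()
        assert sub.total_states == 200
        assert sum(a.basin_size for a in sub.attractors) == 200


class TestPerturb:
    def test_clamp_every_gene_forces_single_state(self, toy3):
        res = perturb(toy3, up_genes={"A", "B"}, down_genes={"C"})
        assert len(res) == 1
        (a,) = res.attractors
        assert a.states == (0b011,)
        assert a.basin_size == 1

    def test_clamp_nothing_is_identity(self, toy3):
        base = enumerate_attractors(toy3)
        res = perturb(toy3)
        assert res.cycle_keys() == base.cycle_keys()

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_clamped_enumeration_matches_oracle_on_reduced_system(self, seed):
        net = generate_network(8, 1.5, 3, seed=seed)
        g = net.genes[2]
        res = perturb(net, down_genes={g})
        want = naive_attractors(net.with_clamped({g: 0}))
        got = {a.states: a.basin_size for a in res.attractors}
        assert got == want
        assert res.total_states == 128

    def test_attractor_states_carry_clamped_values(self):
        net = generate_network(9, 1.5, 3, seed=14)
        up, down = {net.genes[0]}, {net.genes[4]}
        res = perturb(net, up_genes=up, down_genes=down)
        i_up, i_down = 0, 4
        for a in res.attractors:
            for s in a.states:
                assert (s >> i_up) & 1 == 1
                assert (s >> i_down) & 1 == 0

    def test_initial_state_mode_lets_genes_evolve(self, toy3):
        # start from states with A=1: {1, 3, 5, 7}; hand table sends
        # 1->2->5->2 (cycle 2,5), 3->3, 5->2..., 7->2...
        res = perturb(toy3, up_genes={"A"}, mode="initial_state")
        got = {a.states: a.basin_size for a in res.attractors}
        assert got == {(3,): 1, (2, 5): 3}
        assert res.total_states == 4

    def test_overlapping_sets_rejected(self, toy3):
        with pytest.raises(ValueError, match="both"):
            perturb(toy3, up_genes={"A"}, down_genes={"A"})

    def test_unknown_gene_rejected(self, toy3):
        with pytest.raises(ValueError, match="unknown"):
            perturb(toy3, up_genes={"Z"})


class TestReportCycles:
    def test_fixed_point_has_empty_oscillating_set(self):
        res = enumerate_attractors(constant_network(3))
        (info,) = report_cycles(res)
        assert info == {"cycle_length": 1, "oscillating_genes": []}

    def test_two_cycle_oscillating_genes_are_the_xor(self, toy3):
        res = enumerate_attractors(toy3)
        by_len = {a.length: i for i, a in enumerate(res.attractors)}
        info = report_cycles(res)[by_len[2]]
        # cycle (2, 5) = (0,1,0) vs (1,0,1): XOR flips A, B and C
        assert info["cycle_length"] == 2
        assert info["oscillating_genes"] == ["A", "B", "C"]

    def test_planted_two_cycle_matches_bitwise_xor_oracle(self):
        rng = np.random.default_rng(15)
        for seed in range(5):
            net = generate_network(8, 1.5, 3, seed=30 + seed)
            res = enumerate_attractors(net)
            infos = report_cycles(res)
            for a, info in zip(res.attractors, infos):
                if a.length == 2:
                    xor = a.states[0] ^ a.states[1]
                    want = [g for i, g in enumerate(net.genes) if (xor >> i) & 1]
                    assert info["oscillating_genes"] == want

    def test_json_export_is_consistent(self, toy3):
        res = enumerate_attractors(toy3)
        d = res.to_dict()
        assert d["total_states"] == 8
        assert sum(a["basin_size"] for a in d["attractors"]) == 8
        for a in d["attractors"]:
            assert all(set(s) <= {"0", "1"} for s in a["states"])
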