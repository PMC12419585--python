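"""Planted-network and count-emission generator."""

import numpy as np
import pandas as pd
import pytest

from boolgrn import (
    GroundTruth,
    binarize,
    generate_network,
    simulate_expression,
    successor,
)
from boolgrn.data import CONTROL, TREATED
from oracles import naive_successor_table


class TestGenerateNetwork:
    def test_zero_mean_in_degree_gives_constants(self):
        net = generate_network(5, 0.0, 2, seed=1)
        assert all(net.parents[g] == [] for g in net.genes)
        assert all(len(net.truth_tables[g]) == 1 for g in net.genes)

    def test_seed_determinism(self):
        a = generate_network(10, 1.5, 3, seed=7)
        b = generate_network(10, 1.5, 3, seed=7)
        assert a.genes == b.genes
        assert a.parents == b.parents
        assert a.truth_tables == b.truth_tables

    def test_mean_in_degree_near_target(self):
        net = generate_network(10, 1.5, 3, seed=7)
        total_parents = sum(len(net.parents[g]) for g in net.genes)
        assert 1.0 <= total_parents / 10 <= 2.0

    def test_no_self_loops_by_default(self):
        net = generate_network(30, 2.0, 4, seed=3)
        assert all(g not in net.parents[g] for g in net.genes)

    def test_rules_non_constant_when_parents_exist(self):
        net = generate_network(30, 2.0, 4, seed=5)
        for g in net.genes:
            if net.parents[g]:
                tt = net.truth_tables[g]
                assert any(tt) and not all(tt)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 1, "mean_in_degree": 1, "max_in_degree": 2},
            {"n_genes": 5, "mean_in_degree": 3, "max_in_degree": 2},
            {"n_genes": 5, "mean_in_degree": 1, "max_in_degree": 5},
        ],
    )
    def test_invalid_sizes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_network(seed=0, **kwargs)


class TestSimulateExpression:
    def test_shape_and_labels(self):
        net = generate_network(23, 1.5, 3, seed=2)
        truth = GroundTruth(network=net, n_control=4, n_treated=4, seed=2)
        cm, latent = simulate_expression(truth)
        assert cm.counts.shape == (23, 8)
        assert cm.condition.tolist() == [CONTROL] * 4 + [TREATED] * 4
        assert latent.shape == (23, 8)

    def test_seed_determinism_bit_identical(self):
        net = generate_network(10, 1.5, 3, seed=9)
        truth = GroundTruth(network=net, seed=5)
        cm1, lat1 = simulate_expression(truth)
        cm2, lat2 = simulate_expression(truth)
        assert cm1.counts.equals(cm2.counts)
        assert lat1.equals(lat2)

    def test_counts_non_negative_integers(self):
        net = generate_network(10, 1.5, 3, seed=9)
        cm, _ = simulate_expression(GroundTruth(network=net, seed=1))
        vals = cm.counts.to_numpy()
        assert (vals >= 0).all()
        assert np.issubdtype(vals.dtype, np.integer)

    def test_clamped_gene_fixed_in_treated_latents(self):
        net = generate_network(10, 1.5, 3, seed=9)
        g = net.genes[3]
        truth = GroundTruth(network=net, clamp_spec={g: 0}, seed=4)
        cm, latent = simulate_expression(truth)
        treated = cm.samples_of(TREATED)
        assert (latent.loc[g, treated] == 0).all()

    def test_noiseless_emission_recovers_latent_states(self):
        net = generate_network(12, 1.5, 3, seed=11)
        truth = GroundTruth(
            network=net,
            mean_low=1.0,
            mean_high=100.0,
            deterministic=True,
            library_sigma=0.0,
            n_control=6,
            n_treated=6,
            seed=11,
        )
        cm, latent = simulate_expression(truth)
        # unit factors: with no library-size noise the counts are already
        # comparable, and estimated factors would leak other genes' states
        # into latent-constant genes
        ones = pd.Series(1.0, index=cm.samples)
        states, degenerate = binarize(cm, factors=ones)
        varying = latent.nunique(axis=1) > 1
        assert states.loc[varying].equals(latent.loc[varying])
        # latent-constant genes are flagged degenerate and set all-OFF
        assert degenerate[~varying].all()
        assert (states.loc[~varying] == 0).all().all()

    def test_latent_states_lie_on_attractors(self):
        net = generate_network(8, 1.5, 3, seed=13)
        truth = GroundTruth(network=net, n_control=5, n_treated=0, seed=13)
        _, latent = simulate_expression(truth)
        succ = naive_successor_table(net)
        for col in latent.columns:
            s = sum(
                int(latent.at[g, col]) << i for i, g in enumerate(net.genes)
            )
            seen = set()
            cur = s
            while cur not in seen:  # walk must return to s: s is on a cycle
                seen.add(cur)
                cur = succ[cur]
            assert cur == s

    def test_invalid_ground_truth_rejected(self):
        net = generate_network(5, 1.0, 2, seed=0)
        with pytest.raises(ValueError):
            GroundTruth(network=net, mean_low=10, mean_high=5)
        with pytest.raises(ValueError):
            GroundTruth(network=net, dispersion=0)
        with pytest.raises(ValueError):
            GroundTruth(network=net, clamp_spec={"nope": 1})


def test_scalar_successor_matches_naive_oracle():
    net = generate_network(7, 1.5, 3, seed=17)
    table = naive_successor_table(net)
    for s in range(2 ** 7):
        assert successor(net, s) == table[s]


class TestPerturbationPanel:
    def test_deterministic_and_labelled(self):
        from boolgrn import simulate_perturbation_panel

        net = generate_network(10, 1.5, 3, seed=7)
        truth = GroundTruth(network=net, seed=7)
        a = simulate_perturbation_panel(truth, 12, 2)
        b = simulate_perturbation_panel(truth, 12, 2)
        assert a[0].counts.equals(b[0].counts)
        assert a[1].equals(b[1])
        assert a[2] == b[2]
        assert a[0].counts.shape == (10, 12)

    def test_clamps_respected_in_latent_states(self):
        from boolgrn import simulate_perturbation_panel

        net = generate_network(10, 1.5, 3, seed=8)
        truth = GroundTruth(network=net, seed=8)
        _, latent, clamps = simulate_perturbation_panel(truth, 15, 3)
        for j, clamp in enumerate(clamps):
            assert len(clamp) == 3
            for g, v in clamp.items():
                assert latent.iloc[:, j][g] == v

    def test_bad_panel_sizes_rejected(self):
        from boolgrn import simulate_perturbation_panel

        net = generate_network(5, 1.0, 2, seed=0)
        truth = GroundTruth(network=net, seed=0)
        with pytest.raises(ValueError):
            simulate_perturbation_panel(truth, 0, 1)
        with pytest.raises(ValueError):
            simulate_perturbation_panel(truth, 5, 9)
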