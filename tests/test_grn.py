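"""Tree-ensemble network inference, edge thresholding, AUPR scoring."""

import networkx as nx
import numpy as np
import pytest

from boolgrn import edge_aupr, edge_prevalence, threshold_edges
from boolgrn.grn import GENIE3, read_edge_list, write_edge_list
from oracles import manual_average_precision


def _weighted_graph(edges):
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestGENIE3:
    def test_copied_regulator_dominates(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 10))
        X[:, 5] = X[:, 0]  # target 5 is an exact copy of regulator 0
        est = GENIE3(n_trees=100, seed=3).fit(X)
        imp_to_5 = est.importances_[:, 5]
        assert np.argmax(imp_to_5) == 0
        assert imp_to_5[0] > 0.5

    def test_per_target_importances_sum_to_one(self):
        rng = np.random.default_rng(4)
        est = GENIE3(n_trees=50, seed=1).fit(rng.normal(size=(30, 6)))
        np.testing.assert_allclose(est.importances_.sum(axis=0), 1.0)
        assert np.all(np.diag(est.importances_) == 0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 5))
        a = GENIE3(n_trees=50, seed=7).fit(X).importances_
        perm = rng.permutation(25)
        b = GENIE3(n_trees=50, seed=7).fit(X[perm]).importances_
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_target_flagged_not_fatal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        X[:, 2] = 3.0
        est = GENIE3(n_trees=20, seed=0).fit(X, feature_names=list("abcde"))
        assert est.degenerate_targets_ == ["c"]
        assert est.importances_[:, 2].sum() == 0

    def test_too_few_genes_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="regulators"):
            GENIE3(n_trees=10).fit(rng.normal(size=(10, 2)))

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 5))
        a = GENIE3(n_trees=30, seed=2).fit(X).importances_
        b = GENIE3(n_trees=30, seed=2).fit(X).importances_
        np.testing.assert_array_equal(a, b)


class TestThresholdEdges:
    def test_zero_weight_min_keeps_everything(self):
        g = _weighted_graph([("a", "b", 0.9), ("b", "c", 0.5), ("c", "a", 0.1)])
        out = threshold_edges(g, mode="weight_min", value=0)
        assert set(out.edges) == set(g.edges)

    def test_weight_min_cut(self):
        g = _weighted_graph([("a", "b", 0.9), ("b", "c", 0.5), ("c", "a", 0.1)])
        out = threshold_edges(g, mode="weight_min", value=0.4)
        assert set(out.edges) == {("a", "b"), ("b", "c")}

    def test_top_k_edges_density(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(23)]
        g = nx.DiGraph()
        for u in nodes:
            for v in nodes:
                if u != v:
                    g.add_edge(u, v, weight=float(rng.random()))
        out = threshold_edges(g, mode="top_k_edges", value=13)
        assert out.number_of_edges() == 13
        # a 23-node graph with 13 directed edges has density 13/506
        n = 23
        assert 13 / (n * (n - 1)) == pytest.approx(0.0257, abs=5e-4)

    def test_top_k_per_target(self):
        g = _weighted_graph(
            [("a", "t", 0.9), ("b", "t", 0.5), ("c", "t", 0.7), ("t", "a", 0.2)]
        )
        out = threshold_edges(g, mode="top_k_per_target", value=2)
        assert set(out.in_edges("t")) == {("a", "t"), ("c", "t")}

    def test_isolated_nodes_dropped_by_default(self):
        g = _weighted_graph([("a", "b", 0.9), ("c", "d", 0.05)])
        out = threshold_edges(g, mode="weight_min", value=0.5)
        assert set(out.nodes) == {"a", "b"}
        kept = threshold_edges(g, mode="weight_min", value=0.5, keep_isolated=True)
        assert set(kept.nodes) == {"a", "b", "c", "d"}

    def test_negative_threshold_rejected(self):
        g = _weighted_graph([("a", "b", 0.9)])
        with pytest.raises(ValueError):
            threshold_edges(g, mode="weight_min", value=-1)

    def test_edge_list_round_trip(self, tmp_path):
        g = _weighted_graph([("a", "b", 0.25), ("b", "c", 0.5)])
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        back = read_edge_list(path)
        assert set(back.edges) == set(g.edges)
        assert back["a"]["b"]["weight"] == 0.25


class TestEdgeAupr:
    def test_perfect_ranking_gives_one(self):
        g = _weighted_graph(
            [("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.1), ("c", "a", 0.0)]
        )
        assert edge_aupr(g, {("a", "b"), ("b", "c")}) == pytest.approx(1.0)

    def test_matches_manual_average_precision(self):
        rng = np.random.default_rng(7)
        nodes = [f"g{i}" for i in range(8)]
        g = nx.DiGraph()
        labels, scores = [], []
        true = set()
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                w = float(rng.random())
                g.add_edge(u, v, weight=w)
                is_true = rng.random() < 0.15
                if is_true:
                    true.add((u, v))
        if not true:
            true = {("g0", "g1")}
        got = edge_aupr(g, true)
        for u in sorted(nodes):
            for v in sorted(nodes):
                if u == v:
                    continue
                scores.append(g[u][v]["weight"])
                labels.append(1 if (u, v) in true else 0)
        want = manual_average_precision(labels, scores)
        assert got == pytest.approx(want, abs=1e-9)

    def test_prevalence_helper(self):
        assert edge_prevalence(23, 13) == pytest.approx(13 / 506)


class TestPlantedRecovery:
    """Edge recovery from steady states under random clamps (the
    interventional panel directed inference requires)."""

    @staticmethod
    def _panel_aupr(seed, n_trees=100, **truth_kwargs):
        from boolgrn import (
            GroundTruth,
            generate_network,
            genie3_importances,
            simulate_perturbation_panel,
        )
        from boolgrn.grn import network_edges

        net = generate_network(15, 1.5, 3, seed=seed)
        truth = GroundTruth(network=net, seed=seed, **truth_kwargs)
        cm, _, _ = simulate_perturbation_panel(truth, 60, 2)
        g = genie3_importances(cm, n_trees=n_trees, seed=seed)
        true_edges = network_edges(net)
        return edge_aupr(g, true_edges), len(true_edges) / (15 * 14)

    def test_recovery_beats_prevalence(self):
        aupr, prev = self._panel_aupr(seed=1)
        assert aupr > 2 * prev

    def test_mean_aupr_degrades_with_noise(self):
        default = high = 0.0
        seeds = (1, 2, 3)
        for seed in seeds:
            a, prev = self._panel_aupr(seed, dispersion=10.0, library_sigma=0.3)
            b, _ = self._panel_aupr(seed, dispersion=2.0, library_sigma=0.5)
            default += a / len(seeds)
            high += b / len(seeds)
        assert default >= high
        # pure noise carries no edge signal at all: AUPR ~ prevalence
        rng = np.random.default_rng(0)
        from boolgrn.grn import GENIE3

        X = rng.normal(size=(60, 15))
        est = GENIE3(n_trees=100, seed=0).fit(
            X, feature_names=[f"g{i + 1:02d}" for i in range(15)]
        )
        from boolgrn import generate_network
        from boolgrn.grn import network_edges

        net = generate_network(15, 1.5, 3, seed=1)
        noise_aupr = edge_aupr(est.to_graph(), network_edges(net))
        assert noise_aupr < high
        assert noise_aupr < 2.5 * network_edges(net).__len__() / (15 * 14)
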