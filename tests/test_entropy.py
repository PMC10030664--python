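import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agenet import (RunConfig, bin_weights, cohort_entropy,
                    differential_entropy, fit_ensemble, global_entropy,
                    local_entropy, make_cohort, make_scaffold,
                    wilcoxon_rank_sum)
from agenet.entropy import EntropyTable
from conftest import sample_network_from_graph
from oracles import exact_ranksum_p, oracle_entropy


class TestFitEnsemble:
    def test_complete_graph_single_bin_is_deterministic(self):
        net = sample_network_from_graph(nx.complete_graph(4),
                                        {i: 5.0 for i in range(4)})
        model = fit_ensemble(net)
        for i in range(4):
            for j in range(i + 1, 4):
                assert model.link_probability(i, j) == pytest.approx(1.0)
        s_raw, s_norm = global_entropy(model)
        assert s_raw == 0.0
        assert s_norm == 0.0

    def test_two_nodes_one_edge_forced(self):
        net = sample_network_from_graph(nx.Graph([(0, 1)]), {0: 1.0, 1: 2.0})
        model = fit_ensemble(net)
        assert model.link_probability(0, 1) == pytest.approx(1.0)
        assert global_entropy(model)[0] == 0.0

    def test_edgeless_network_rejected(self):
        scaffold_graph = nx.Graph([("a", "b"), ("c", "d")])
        net = sample_network_from_graph(scaffold_graph,
                                        {"a": 1, "b": 2, "c": 3, "d": 4})
        net.edges = np.empty((0, 2), dtype=np.int64)
        net.weights = np.empty(0)
        with pytest.raises(ValueError, match="edgeless"):
            fit_ensemble(net)

    def test_constraints_reproduced_within_tolerance(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.35, seed=5)
        net = sample_network_from_graph(g, {v: rng.uniform(1, 9) for v in g.nodes})
        binning = bin_weights(net)
        model = fit_ensemble(net, binning)
        assert np.allclose(model.expected_degrees(), net.degrees(), atol=1e-7)
        assert np.allclose(model.expected_bin_counts(), binning.counts, atol=1e-7)

    def test_matches_direct_constrained_maximization(self):
        """Canonical-ensemble entropy equals brute-force constrained
        maximization of Shannon entropy on 6-node graphs."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 4:
            g = nx.gnp_random_graph(6, 0.55, seed=int(rng.integers(2**31)))
            if g.number_of_edges() < 1:
                continue
            net = sample_network_from_graph(
                g, {v: rng.uniform(1, 10) for v in g.nodes})
            binning = bin_weights(net)
            model = fit_ensemble(net, binning)
            s, _ = global_entropy(model)
            s_oracle = oracle_entropy(net.n_nodes, net.edges.tolist(),
                                      binning.bin_of_edge.tolist(),
                                      binning.n_bins)
            assert s == pytest.approx(s_oracle, abs=1e-6)
            checked += 1

    def test_entropy_nonnegative_and_normalized(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(15, 0.3, seed=11)
        net = sample_network_from_graph(g, {v: rng.uniform(1, 9) for v in g.nodes})
        s_raw, s_norm = global_entropy(fit_ensemble(net))
        assert s_raw >= 0
        assert s_norm == pytest.approx(s_raw / net.n_nodes)


class TestLocalEntropy:
    def test_equal_weights_reach_log_degree(self):
        g = nx.star_graph(4)
        vals = {0: 1.0, 1: 3.0, 2: 3.0, 3: 3.0, 4: 3.0}
        ent = local_entropy(sample_network_from_graph(g, vals))
        assert ent["0"] == pytest.approx(math.log(4))

    def test_single_edge_node_is_zero(self):
        ent = local_entropy(sample_network_from_graph(nx.Graph([(0, 1)]),
                                                      {0: 1.0, 1: 5.0}))
        assert ent["0"] == 0.0
        assert ent["1"] == 0.0

    def test_hand_value_for_1_1_2_weights(self):
        # star with incident weights (1,1,2): p=(0.25,0.25,0.5), S=1.0397
        g = nx.star_graph(3)
        vals = {0: 4.0, 1: 5.0, 2: 3.0, 3: 6.0}
        ent = local_entropy(sample_network_from_graph(g, vals))
        assert ent["0"] == pytest.approx(1.0397, abs=1e-4)

    def test_bounded_by_log_degree(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(20, 0.3, seed=9)
        net = sample_network_from_graph(g, {v: rng.uniform(1, 9) for v in g.nodes})
        ent = local_entropy(net)
        deg = dict(nx.degree(nx.relabel_nodes(g, str)))
        for node, s in ent.items():
            assert -1e-12 <= s <= math.log(max(deg[node], 1)) + 1e-12

    def test_all_zero_weights_give_zero(self):
        net = sample_network_from_graph(nx.path_graph(4),
                                        {i: 2.0 for i in range(4)})
        assert set(local_entropy(net).values()) == {0.0}


class TestWilcoxon:
    def test_fully_separated_4v4_exact(self):
        p = wilcoxon_rank_sum(np.array([1, 2, 3, 4.0]), np.array([5, 6, 7, 8.0]))[1]
        assert p == pytest.approx(2 / 70)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(loc=rng.uniform(0, 2), size=5)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-10)

    def test_tied_data_uses_midranks_without_error(self):
        x = np.array([1.0, 1.0, 2.0, 3.0] * 3)
        y = np.array([1.0, 2.0, 2.0, 4.0] * 3)
        _, p = wilcoxon_rank_sum(x, y)
        assert 0 < p <= 1


def _table_from_local(local: pd.DataFrame, groups: dict) -> EntropyTable:
    samples = pd.DataFrame({"sample": list(local.columns),
                            "group": [groups[s] for s in local.columns]})
    return EntropyTable(samples, local, groups)


class TestDifferentialEntropy:
    def _groups(self):
        samples = [f"y{i}" for i in range(4)] + [f"o{i}" for i in range(4)]
        return samples, {s: (3 if s.startswith("y") else 27) for s in samples}

    def test_identical_sides_not_significant(self):
        samples, groups = self._groups()
        local = pd.DataFrame(
            {s: {"g1": 0.5, "g2": 0.8} for s in samples})
        res = differential_entropy(_table_from_local(local, groups), [3], [27])
        assert (res["pvalue"] == 1.0).all()
        assert not res["significant"].any()

    def test_small_shift_fails_median_filter(self):
        samples, groups = self._groups()
        local = pd.DataFrame(
            {s: {"g1": (0.50 if s.startswith("y") else 0.52) + 0.001 * i,
                 "g2": 0.9}
             for i, s in enumerate(samples)})
        res = differential_entropy(_table_from_local(local, groups), [3], [27])
        row = res.loc["g1"]
        assert row["pvalue"] < 0.05
        assert abs(row["shift"]) < 0.03
        assert not row["significant"]

    def test_clear_shift_detected(self):
        samples, groups = self._groups()
        local = pd.DataFrame(
            {s: {"g1": (0.5 if s.startswith("y") else 0.9) + 0.001 * i,
                 "g2": 0.4 + 0.0005 * i}
             for i, s in enumerate(samples)})
        res = differential_entropy(_table_from_local(local, groups), [3], [27])
        assert bool(res.loc["g1", "significant"])
        assert not bool(res.loc["g2", "significant"])

    def test_too_few_samples_per_side_errors(self):
        local = pd.DataFrame({"y0": {"g": 0.1}, "o0": {"g": 0.2}, "o1": {"g": 0.3}})
        groups = {"y0": 3, "o0": 27, "o1": 27}
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_entropy(_table_from_local(local, groups), [3], [27])

    def test_node_absent_on_one_side_dropped(self):
        samples, groups = self._groups()
        local = pd.DataFrame(
            {s: {"g1": 0.5 + 0.01 * i,
                 "g2": (np.nan if s.startswith("o") else 0.4)}
             for i, s in enumerate(samples)})
        res = differential_entropy(_table_from_local(local, groups), [3], [27])
        assert "g2" not in res.index

    def test_mean_statistic_option(self):
        samples, groups = self._groups()
        local = pd.DataFrame(
            {s: {"g1": (0.5 if s.startswith("y") else 0.9) + 0.001 * i}
             for i, s in enumerate(samples)})
        cfg = RunConfig(diff_statistic="mean")
        res = differential_entropy(_table_from_local(local, groups), [3], [27], cfg)
        assert res.loc["g1", "shift"] == pytest.approx(0.4, abs=0.01)


class TestCohortPipeline:
    def test_cohort_table_shapes_and_groups(self):
        scaffold, _ = make_scaffold(60, 2, seed=0)
        expr, _ = make_cohort(scaffold, groups=(3, 27), n_per_group=2,
                              noise_scale=(0.1, 0.2), seed=1)
        table = cohort_entropy(expr, scaffold)
        assert len(table.samples) == 4
        assert table.local.shape[1] == 4
        assert set(table.samples["group"]) == {3, 27}
        assert (table.samples["global_entropy_raw"] >= 0).all()
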