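import networkx as nx
import numpy as np
import pytest

from agenet import (RunConfig, closest_distance, degree_matched_sample,
                    gene_set_from_iterable, make_scaffold,
                    pairwise_proximity_matrix, proximity_genes, proximity_z)
from agenet.io import Scaffold
from agenet.proximity import _degree_bins
from conftest import random_connected_graphs
from oracles import brute_closest_distance, brute_proximity_genes


def _path_scaffold(n=5):
    return Scaffold(nx.path_graph([str(i) for i in range(1, n + 1)]))


class TestClosestDistance:
    def test_self_distance_is_zero(self):
        sc = _path_scaffold()
        assert closest_distance(sc, {"1", "3"}, {"1", "3"}) == 0.0

    def test_path_endpoints(self):
        sc = _path_scaffold()
        assert closest_distance(sc, {"1"}, {"5"}) == pytest.approx(4.0)

    def test_path_two_by_two(self):
        sc = _path_scaffold()
        assert closest_distance(sc, {"1", "2"}, {"4", "5"}) == pytest.approx(2.5)

    def test_unreachable_genes_excluded(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        sc = Scaffold(g)
        # 'x' is disconnected from B: contributes nothing to either side
        assert closest_distance(sc, {"a", "x"}, {"b"}) == pytest.approx(1.0)

    def test_all_unreachable_errors(self):
        sc = Scaffold(nx.Graph([("a", "b"), ("x", "y")]))
        with pytest.raises(ValueError, match="no finite"):
            closest_distance(sc, {"a"}, {"x"})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_on_small_graphs(self, seed):
        for g in random_connected_graphs(10, 8, seed=seed * 7 + 1):
            g = nx.relabel_nodes(g, str)
            sc = Scaffold(g)
            rng = np.random.default_rng(seed)
            nodes = sorted(sc.nodes)
            a = set(rng.choice(nodes, size=min(3, len(nodes)), replace=False))
            b = set(rng.choice(nodes, size=min(3, len(nodes)), replace=False))
            try:
                expected = brute_closest_distance(g, a, b)
            except ValueError:
                continue
            assert closest_distance(sc, a, b) == pytest.approx(expected)
            assert closest_distance(sc, b, a) == pytest.approx(expected)

    def test_adding_shared_gene_never_increases_distance(self):
        scaffold, _ = make_scaffold(100, 2, seed=1)
        nodes = sorted(scaffold.nodes)
        a = set(nodes[:5])
        b = set(nodes[40:45])
        base = closest_distance(scaffold, a, b)
        enriched = closest_distance(scaffold, a, b | {nodes[0]})
        assert enriched <= base


class TestDegreeMatchedSample:
    @pytest.fixture(scope="class")
    def scaffold(self):
        return make_scaffold(400, 3, seed=5)[0]

    def test_sample_size_and_uniqueness(self, scaffold):
        nodes = sorted(scaffold.nodes)
        template = set(nodes[:17])
        s = degree_matched_sample(scaffold, template, np.random.default_rng(0))
        assert len(s) == 17

    def test_degree_bin_histogram_preserved(self, scaffold):
        bins = _degree_bins(scaffold)
        nodes = sorted(scaffold.nodes)
        template = set(nodes[10:40])
        s = degree_matched_sample(scaffold, template, np.random.default_rng(1))
        hist = lambda genes: np.bincount([bins[g] for g in genes],
                                         minlength=max(bins.values()) + 1)
        assert np.array_equal(hist(template), hist(s))

    def test_hub_template_stays_in_hub_bin(self, scaffold):
        degs = dict(scaffold.graph.degree())
        hubs = sorted(degs, key=degs.get, reverse=True)[:5]
        bins = _degree_bins(scaffold)
        s = degree_matched_sample(scaffold, set(hubs), np.random.default_rng(2))
        assert {bins[g] for g in s} <= {bins[g] for g in hubs}

    def test_fixed_seed_reproducible(self, scaffold):
        template = set(sorted(scaffold.nodes)[:10])
        s1 = degree_matched_sample(scaffold, template, np.random.default_rng(9))
        s2 = degree_matched_sample(scaffold, template, np.random.default_rng(9))
        assert s1 == s2

    def test_overfull_draw_errors(self):
        # more draws than the (fully merged) bin holds
        sc = Scaffold(nx.path_graph([str(i) for i in range(4)]))
        with pytest.raises(ValueError, match="draws requested"):
            degree_matched_sample(sc, ["0", "0", "1", "1", "2"],
                                  np.random.default_rng(0))


class TestProximityZ:
    @pytest.fixture(scope="class")
    def scaffold(self):
        return make_scaffold(300, 3, seed=11)[0]

    def test_fixed_seed_bit_identical(self, scaffold):
        nodes = sorted(scaffold.nodes)
        a = gene_set_from_iterable(nodes[:10], scaffold, "A")
        b = gene_set_from_iterable(nodes[50:60], scaffold, "B")
        cfg = RunConfig(n_permutations=50, rng_seed=4)
        r1 = proximity_z(scaffold, a, b, cfg)
        r2 = proximity_z(scaffold, a, b, cfg)
        assert r1 == r2

    def test_random_sets_are_uncalibrated_near_zero(self, scaffold):
        rng = np.random.default_rng(0)
        nodes = sorted(scaffold.nodes)
        cfg = RunConfig(n_permutations=200, rng_seed=1)
        zs = []
        for seed in range(10):
            pick = np.random.default_rng(seed).choice(nodes, size=24, replace=False)
            a = gene_set_from_iterable(pick[:12], scaffold, "A")
            b = gene_set_from_iterable(pick[12:], scaffold, "B")
            zs.append(proximity_z(scaffold, a, b, cfg,
                                  rng=np.random.default_rng(seed + 100)).z)
        assert np.sum(np.abs(zs) < 2) >= 9

    def test_planted_neighbour_set_is_proximal(self, scaffold):
        rng = np.random.default_rng(3)
        nodes = sorted(scaffold.nodes)
        a_nodes = rng.choice(nodes, size=12, replace=False).tolist()
        neigh = sorted({n for g in a_nodes for n in scaffold.graph.neighbors(g)}
                       - set(a_nodes))
        b_nodes = rng.choice(neigh, size=min(12, len(neigh)), replace=False)
        a = gene_set_from_iterable(a_nodes, scaffold, "A")
        b = gene_set_from_iterable(b_nodes, scaffold, "B")
        res = proximity_z(scaffold, a, b, RunConfig(n_permutations=500, rng_seed=2))
        assert res.z < -1.5
        assert res.p_empirical < 0.05


class TestProximityGenes:
    def test_path_intermediate(self):
        sc = Scaffold(nx.path_graph(["1", "2", "3"]))
        pg = proximity_genes(sc, gene_set_from_iterable({"1"}, sc, "A"),
                             gene_set_from_iterable({"3"}, sc, "B"))
        assert pg.roles == {"1": "endpoint-A", "2": "intermediate",
                            "3": "endpoint-B"}

    def test_shared_gene_labelled_common(self):
        sc = Scaffold(nx.path_graph(["1", "2", "3"]))
        pg = proximity_genes(sc, gene_set_from_iterable({"1", "2"}, sc, "A"),
                             gene_set_from_iterable({"2", "3"}, sc, "B"))
        assert pg.roles["2"] == "common"

    def test_diamond_collects_both_shortest_paths(self):
        sc = Scaffold(nx.Graph([("a", "b"), ("b", "d"), ("a", "c"), ("c", "d")]))
        pg = proximity_genes(sc, gene_set_from_iterable({"a"}, sc, "A"),
                             gene_set_from_iterable({"d"}, sc, "B"))
        assert pg.nodes == {"a", "b", "c", "d"}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration(self, seed):
        for g in random_connected_graphs(8, 8, seed=seed + 30):
            g = nx.relabel_nodes(g, str)
            sc = Scaffold(g)
            rng = np.random.default_rng(seed)
            nodes = sorted(sc.nodes)
            a = set(rng.choice(nodes, size=min(3, len(nodes)), replace=False))
            b = set(rng.choice(nodes, size=min(3, len(nodes)), replace=False))
            pg = proximity_genes(sc, gene_set_from_iterable(a, sc, "A"),
                                 gene_set_from_iterable(b, sc, "B"))
            assert pg.nodes == brute_proximity_genes(g, a, b)


class TestPairwiseMatrix:
    def test_reference_against_itself_is_zero(self):
        scaffold, _ = make_scaffold(200, 3, seed=21)
        nodes = sorted(scaffold.nodes)
        ref = gene_set_from_iterable(nodes[:10], scaffold, "ref")
        cfg = RunConfig(n_permutations=50, rng_seed=3)
        table = pairwise_proximity_matrix(scaffold, [ref], ref, cfg)
        assert table.loc[0, "d_ab"] == 0.0

    def test_empty_condition_list(self):
        scaffold, _ = make_scaffold(50, 2, seed=2)
        ref = gene_set_from_iterable(sorted(scaffold.nodes)[:5], scaffold, "ref")
        assert pairwise_proximity_matrix(scaffold, [], ref).empty

    def test_planted_proximal_flagged_distal_not(self):
        from agenet import make_condition_sets
        hits = 0
        for seed in range(5):
            scaffold, _ = make_scaffold(400, 3, seed=seed)
            rng = np.random.default_rng(seed)
            nodes = sorted(scaffold.nodes)
            ref = gene_set_from_iterable(
                rng.choice(nodes, size=15, replace=False), scaffold, "ref")
            prox, distal, _ = make_condition_sets(scaffold, ref, 15, 15,
                                                  seed=seed)
            cfg = RunConfig(n_permutations=300, rng_seed=seed)
            table = pairwise_proximity_matrix(scaffold, [prox, distal], ref, cfg)
            flags = dict(zip(table["condition"], table["significant"]))
            hits += flags["proximal"] and not flags["distal"]
        assert hits >= 4
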