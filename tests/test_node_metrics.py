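import numpy as np
import pytest

from cdrnet.node_metrics import (
    CliqueGuardError,
    centralities,
    cohort_cv,
    kcore_decomposition,
    largest_clique,
    metric_frequency_correlation,
    neighborhood_sizes,
)
from cdrnet.repertoire import CloneRecord, Repertoire

from .conftest import make_layer, random_gnp_layer
from . import _oracles as oracle


class TestCentralitiesSmall:
    def test_four_cycle_pagerank_uniform(self):
        layer = make_layer([(0, 1), (1, 2), (2, 3), (0, 3)], 4)
        for alpha in (0.5, 0.85, 0.99):
            nm = centralities(layer, alpha=alpha)
            assert np.allclose(nm.pagerank, 0.25, atol=1e-9)

    def test_path3_center_betweenness(self, path3):
        nm = centralities(path3)
        assert nm.betweenness[1] == pytest.approx(1.0)
        assert nm.betweenness[0] == nm.betweenness[2] == 0.0

    def test_complete3_closeness_one(self, triangle):
        nm = centralities(triangle)
        assert np.allclose(nm.closeness, 1.0)

    def test_isolated_node_conventions(self):
        layer = make_layer([(0, 1)], 3)
        nm = centralities(layer)
        assert nm.degree[2] == 0
        assert nm.closeness[2] == 0.0
        assert nm.betweenness[2] == 0.0
        assert nm.transitivity[2] == 0.0

    def test_pagerank_sums_to_one(self):
        rng = np.random.default_rng(0)
        nm = centralities(random_gnp_layer(20, 0.2, rng))
        assert nm.pagerank.sum() == pytest.approx(1.0)

    def test_eigenvector_authority_equal_undirected(self):
        rng = np.random.default_rng(3)
        nm = centralities(random_gnp_layer(25, 0.2, rng))
        assert np.allclose(nm.eigenvector, nm.authority, atol=1e-8)

    def test_scores_scaled_to_max_one(self):
        rng = np.random.default_rng(4)
        nm = centralities(random_gnp_layer(15, 0.3, rng))
        assert nm.eigenvector.max() == pytest.approx(1.0)
        assert nm.authority.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_oracle_spot_check(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 25))
        layer = random_gnp_layer(n, 0.25, rng)
        a = oracle.adjacency_matrix(layer.edges, n)
        nm = centralities(layer)
        assert np.allclose(nm.eigenvector, oracle.eigenvector_centrality(a), atol=1e-8)
        assert np.allclose(nm.betweenness, oracle.betweenness(a), atol=1e-8)
        assert np.allclose(nm.closeness, oracle.closeness(a), atol=1e-8)
        assert np.allclose(nm.pagerank, oracle.pagerank(a), atol=1e-8)
        assert np.array_equal(nm.coreness, oracle.coreness(a))


class TestKCore:
    def test_complete4_all_coreness3(self):
        layer = make_layer([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
        kc = kcore_decomposition(layer)
        assert list(kc.coreness) == [3, 3, 3, 3]
        assert kc.k_max == 3
        assert kc.maximal_core_fraction == 100.0

    def test_star_all_coreness1(self, star4):
        kc = kcore_decomposition(star4)
        assert list(kc.coreness) == [1, 1, 1, 1]

    def test_k4_plus_pendant(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)] + [(3, 4)]
        kc = kcore_decomposition(make_layer(edges, 5))
        assert list(kc.coreness) == [3, 3, 3, 3, 1]
        assert sorted(kc.maximal_core_nodes.tolist()) == [0, 1, 2, 3]
        assert kc.maximal_core_fraction == pytest.approx(80.0)
        assert kc.core_sizes == {1: 5, 2: 4, 3: 4}

    def test_coreness_at_most_degree(self):
        rng = np.random.default_rng(8)
        layer = random_gnp_layer(30, 0.15, rng)
        kc = kcore_decomposition(layer)
        assert (kc.coreness <= layer.degrees()).all()


class TestNeighborhoods:
    def test_path5_center(self):
        layer = make_layer([(0, 1), (1, 2), (2, 3), (3, 4)], 5)
        import networkx as nx

        g = layer.to_networkx()
        d1 = len(nx.single_source_shortest_path_length(g, 2, cutoff=1)) - 1
        assert d1 / 5 == pytest.approx(2 / 5)
        sizes = neighborhood_sizes(layer, orders=[1, 2, 3, 4])
        # mean over all five nodes; plateau at (component size - 1)/N
        assert sizes[4] == pytest.approx(4 / 5)
        assert sizes[1] <= sizes[2] <= sizes[3] <= sizes[4]

    def test_isolated_node_zero(self):
        layer = make_layer(np.empty((0, 2)), 3)
        sizes = neighborhood_sizes(layer, orders=[1, 5])
        assert sizes[1] == 0.0 and sizes[5] == 0.0

    def test_plateau_at_diameter(self):
        rng = np.random.default_rng(2)
        layer = random_gnp_layer(15, 0.3, rng)
        sizes = neighborhood_sizes(layer, orders=[14])
        from cdrnet.graph_metrics import connected_components

        comps = connected_components(layer)
        expected = np.mean(
            [(comps.sizes[comps.labels[v]] - 1) / 15 for v in range(15)]
        )
        assert sizes[14] == pytest.approx(expected)


class TestLargestClique:
    def test_triangle_with_pendant(self):
        size, members = largest_clique(make_layer([(0, 1), (0, 2), (1, 2), (2, 3)], 4))
        assert size == 3 and members == [0, 1, 2]

    def test_edgeless_graph_clique_one(self):
        size, _ = largest_clique(make_layer(np.empty((0, 2)), 3))
        assert size == 1

    def test_complete5(self):
        size, _ = largest_clique(
            make_layer([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)
        )
        assert size == 5

    def test_guard(self):
        with pytest.raises(CliqueGuardError):
            largest_clique(make_layer([(0, 1)], 10), max_nodes=5)


class TestCohortCV:
    def test_constant_zero(self):
        assert cohort_cv([5, 5, 5]).cv == 0.0

    def test_two_point(self):
        assert cohort_cv([1, 3]).cv == pytest.approx(70.7106781, abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(6) + 0.5
        assert cohort_cv(x).cv == pytest.approx(cohort_cv(7.3 * x).cv)

    def test_zero_mean_undefined(self):
        assert cohort_cv([-1.0, 1.0]).cv is None


class TestMetricFrequencyCorrelation:
    def _rep_and_metrics(self):
        rep = Repertoire(
            "s",
            [CloneRecord(s, c) for s, c in
             [("CARDY", 10), ("CARDW", 5), ("CARVV", 3), ("CAWWW", 2)]],
        )
        layer = make_layer([(0, 1), (0, 2), (0, 3)], 4)
        return rep, centralities(layer)

    def test_metric_equal_frequency_r1(self):
        rep, nm = self._rep_and_metrics()
        nm.degree = rep.frequencies.copy()
        assert metric_frequency_correlation(nm, rep, "degree") == pytest.approx(1.0)

    def test_metric_negative_frequency_rm1(self):
        rep, nm = self._rep_and_metrics()
        nm.degree = -rep.frequencies
        assert metric_frequency_correlation(nm, rep, "degree") == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        rep, nm = self._rep_and_metrics()
        r = metric_frequency_correlation(nm, rep, "degree")
        x = nm.degree.astype(float)
        y = rep.frequencies
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected)

    def test_constant_metric_undefined(self):
        rep, nm = self._rep_and_metrics()
        nm.degree = np.ones(4)
        assert metric_frequency_correlation(nm, rep, "degree") is None
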