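"""Node and global graph statistics against closed forms and oracles."""

import numpy as np
import pytest

from pcornet.metrics import (
    avg_clustering,
    betweenness,
    closeness,
    density,
    distance_matrix,
    eigenvector_centrality,
    global_metrics,
    harmonic_closeness,
    hits,
    hits_matrix,
    local_clustering,
    node_metrics,
    path_stats,
)
from pcornet.network import HealthNetwork, potential_edge_count

from conftest import (
    betweenness_enumeration_oracle,
    complete_network,
    distance_oracle,
    random_network,
    star_network,
    table1_style_network,
)


class TestDistancesAndPaths:
    def test_path_graph_closed_form(self):
        net = HealthNetwork.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
        diameter, avg, connected = path_stats(net)
        assert (diameter, connected) == (2, True)
        assert avg == pytest.approx(4 / 3)

    def test_complete_graph_closed_form(self):
        diameter, avg, connected = path_stats(complete_network(6))
        assert (diameter, avg, connected) == (1, 1.0, True)

    def test_matches_matrix_power_oracle_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            net = random_network(rng, int(rng.integers(3, 13)),
                                 p_edge=float(rng.uniform(0.15, 0.8)))
            assert (distance_matrix(net) == distance_oracle(net.adjacency)).all()

    def test_disconnected_graph_reports_flag(self):
        net = HealthNetwork.from_edges(["a", "b", "c", "d"],
                                       [("a", "b"), ("c", "d")])
        diameter, avg, connected = path_stats(net)
        assert not connected
        assert diameter == 1 and avg == 1.0


class TestCloseness:
    def test_published_stress_row_configuration(self):
        """9 direct neighbours and 7 nodes at distance 2 in a 17-node graph
        give closeness 16/23 = 0.6957 and harmonic 12.5/16 = 0.7813."""
        net = table1_style_network()
        assert round(closeness(net, 0), 4) == 0.6957
        # 0.78125 prints as 0.7813 under the published table's half-up rounding
        assert abs(harmonic_closeness(net, 0) - 0.7813) <= 5e-5
        assert harmonic_closeness(net, 0) == pytest.approx((9 + 3.5) / 16)

    def test_star_center_and_leaf(self):
        net = star_network(17)
        assert closeness(net, 0) == 1.0
        assert harmonic_closeness(net, 0) == 1.0
        assert closeness(net, 1) == pytest.approx(16 / 31)

    def test_isolated_node_is_zero(self):
        net = HealthNetwork.from_edges(["a", "b", "c"], [("a", "b")])
        assert closeness(net, 2) == 0.0
        assert harmonic_closeness(net, 2) == 0.0

    def test_unreachable_nodes_contribute_zero_to_harmonic(self):
        net = HealthNetwork.from_edges(["a", "b", "c", "d"],
                                       [("a", "b"), ("c", "d")])
        assert harmonic_closeness(net, 0) == pytest.approx(1 / 3)


class TestBetweenness:
    def test_star_closed_form(self):
        net = star_network(17)
        scores = betweenness(net)
        assert scores[0] == pytest.approx(16 * 15 / 2)  # C(16, 2)
        assert np.allclose(scores[1:], 0.0)

    def test_complete_graph_has_no_intermediaries(self):
        assert np.allclose(betweenness(complete_network(7)), 0.0)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(12):
            net = random_network(rng, int(rng.integers(4, 11)),
                                 p_edge=float(rng.uniform(0.2, 0.7)))
            assert np.allclose(betweenness(net),
                               betweenness_enumeration_oracle(net), atol=1e-9)

    def test_total_flow_conservation(self):
        """Summed betweenness equals the total intermediary credit over
        connected pairs: sum over pairs of (path length - 1)... weighted by
        tie shares, cross-checked via the enumeration oracle totals."""
        rng = np.random.default_rng(22)
        for _ in range(5):
            net = random_network(rng, 9, p_edge=0.4)
            assert betweenness(net).sum() == pytest.approx(
                betweenness_enumeration_oracle(net).sum(), abs=1e-9)


class TestEigenvectorAndHits:
    def test_max_score_is_one(self):
        rng = np.random.default_rng(30)
        net = random_network(rng, 10, p_edge=0.5)
        assert eigenvector_centrality(net).max() == pytest.approx(1.0)

    def test_regular_graph_scores_all_one(self):
        labels = [f"v{i}" for i in range(6)]
        edges = [(labels[i], labels[(i + 1) % 6]) for i in range(6)]  # cycle
        net = HealthNetwork.from_edges(labels, edges)
        assert np.allclose(eigenvector_centrality(net), 1.0, atol=1e-8)

    def test_star_leaf_to_center_ratio(self):
        """Leading eigenvector of a 17-star: leaves at 1/sqrt(16) = 0.25 of
        the center."""
        scores = eigenvector_centrality(star_network(17))
        assert scores[0] == pytest.approx(1.0)
        assert np.allclose(scores[1:], 0.25, atol=1e-8)

    def test_hub_equals_authority_on_undirected_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            net = random_network(rng, int(rng.integers(3, 12)), p_edge=0.5)
            if net.n_edges == 0:
                continue
            hub, auth = hits(net)
            assert np.allclose(hub, auth, atol=1e-10)

    def test_hits_is_l2_normalized_eigenvector(self):
        rng = np.random.default_rng(32)
        net = random_network(rng, 8, p_edge=0.6)
        eig = eigenvector_centrality(net)
        _hub, auth = hits(net)
        assert np.allclose(auth, eig / np.linalg.norm(eig), atol=1e-8)

    def test_directed_toy_authority(self):
        """a->b, c->b: b is the sole authority; checked against explicit
        eigen-decomposition of A^T A."""
        a = np.zeros((3, 3))
        a[0, 1] = 1.0
        a[2, 1] = 1.0
        hub, auth = hits_matrix(a)
        evals, evecs = np.linalg.eigh(a.T @ a)
        lead = np.abs(evecs[:, np.argmax(evals)])
        assert np.allclose(auth, lead / np.linalg.norm(lead), atol=1e-10)
        assert auth[1] == pytest.approx(1.0)
        assert np.allclose(hub, [np.sqrt(0.5), 0.0, np.sqrt(0.5)], atol=1e-10)

    def test_edgeless_graph_rejected(self):
        net = HealthNetwork.from_edges(["a", "b"], [])
        with pytest.raises(ValueError):
            eigenvector_centrality(net)


class TestClustering:
    @pytest.mark.parametrize("degree, tri, expected", [
        (4, 5, 0.8333),    # 10/12
        (9, 12, 0.3333),   # 24/72
        (8, 11, 0.3929),   # 22/56
    ])
    def test_published_coefficient_configurations(self, degree, tri, expected):
        """Clustering coefficient 2T/(k(k-1)) for the degree/triangle
        combinations appearing in the published node table."""
        labels = ["hub"] + [f"n{i}" for i in range(degree)]
        edges = [("hub", f"n{i}") for i in range(degree)]
        pairs = [(a, b) for a in range(degree) for b in range(a + 1, degree)]
        edges += [(f"n{a}", f"n{b}") for a, b in pairs[:tri]]
        net = HealthNetwork.from_edges(labels, edges)
        coef, count = local_clustering(net, 0)
        assert round(coef, 4) == expected
        assert count == tri

    def test_triangle_graph(self):
        net = complete_network(3)
        for v in range(3):
            assert local_clustering(net, v) == (1.0, 1)

    def test_low_degree_convention(self):
        net = HealthNetwork.from_edges(["a", "b", "c"], [("a", "b")])
        assert local_clustering(net, 0) == (0.0, 0)
        assert local_clustering(net, 2) == (0.0, 0)

    def test_average_clustering_bounded(self):
        rng = np.random.default_rng(40)
        for _ in range(10):
            net = random_network(rng, 10, p_edge=0.5)
            assert 0.0 <= avg_clustering(net) <= 1.0


class TestDensityAndGlobal:
    def test_density_bounds(self):
        assert density(complete_network(8)) == 1.0
        assert density(HealthNetwork.from_edges(["a", "b", "c"], [])) == 0.0

    def test_density_times_potential_count_is_edge_count(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            net = random_network(rng, int(rng.integers(3, 15)), p_edge=0.4)
            n = net.n_nodes
            assert density(net) * potential_edge_count(n) == pytest.approx(
                net.n_edges, abs=1e-12)

    def test_global_metrics_assembly(self):
        net = table1_style_network()
        g = global_metrics(net, modularity_q=0.4)
        assert g.edge_count == net.n_edges
        assert g.diameter >= g.avg_path_length >= 1.0
        assert 0.0 <= g.avg_clustering <= 1.0


class TestNodeMetricsTable:
    def test_empty_graph_gives_zero_metrics(self):
        net = HealthNetwork.from_edges(["a", "b", "c"], [])
        table = node_metrics(net)
        numeric = table.drop(columns=["ID"])
        assert (numeric.to_numpy() == 0).all()

    def test_published_row_coherence(self):
        """The same node carries closeness 0.6957, harmonic 0.7813 and
        clustering 0.3333 (degree 9, 12 neighbour edges) in one row."""
        net = table1_style_network()
        table = node_metrics(net).set_index("ID")
        row = table.loc["v0"]
        assert round(row["ClosenessCentrality"], 4) == 0.6957
        assert abs(row["HarmonicClosenessCentrality"] - 0.7813) <= 5e-5
        assert round(row["Clustering.Coefficient"], 4) == 0.3333
        assert row["NumberTriangles"] == 12

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(50)
        net = random_network(rng, 12, p_edge=0.4)
        part = {lab: i % 3 for i, lab in enumerate(net.labels)}
        a = node_metrics(net, part)
        b = node_metrics(net, part)
        assert a.equals(b)

    def test_partition_must_cover_all_nodes(self):
        net = star_network(4)
        with pytest.raises(ValueError, match="v3"):
            node_metrics(net, {"v0": 0, "v1": 0, "v2": 0})
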