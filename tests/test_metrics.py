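"""Graph metrics against the brute-force oracle, closed forms and nulls."""

import numpy as np
import pytest

from restgraph import (
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    global_efficiency,
    local_efficiency,
    metric_table,
    rewire_preserving_degree,
    small_world_parameters,
)
from restgraph.errors import DisconnectedGraphError
from tests.conftest import (
    complete_graph,
    graph_from_edges,
    oracle_clustering,
    oracle_global_efficiency,
    oracle_local_efficiency,
    oracle_path_length,
    path_graph,
    random_connected_graph,
    star_graph,
)


class TestClosedForms:
    def test_complete_graph_everything_one(self):
        g = complete_graph(6)
        assert clustering_coefficient(g)[1] == pytest.approx(1.0)
        assert characteristic_path_length(g)[1] == pytest.approx(1.0)
        assert global_efficiency(g)[1] == pytest.approx(1.0)
        assert local_efficiency(g)[1] == pytest.approx(1.0)

    def test_star_graph(self):
        g = star_graph(6)
        assert clustering_coefficient(g)[1] == 0.0
        assert local_efficiency(g)[1] == 0.0
        # hub at distance 1 from all; leaves at distance 2 from each other
        n_pairs = 15
        assert characteristic_path_length(g)[1] == pytest.approx((5 * 1 + 10 * 2) / n_pairs)
        assert global_efficiency(g)[1] == pytest.approx((5 * 1 + 10 * 0.5) / n_pairs)

    def test_path_of_three(self):
        g = path_graph(3)
        assert characteristic_path_length(g)[1] == pytest.approx(4.0 / 3.0)
        assert global_efficiency(g)[1] == pytest.approx((1 + 1 + 0.5) / 3.0)

    def test_ring_clustering_per_node(self):
        # 2-neighbour ring lattice: every node has C_i = 0.5
        n = 12
        edges = []
        for i in range(n):
            edges.append((i, (i + 1) % n))
            edges.append((i, (i + 2) % n))
        g = graph_from_edges(n, {(min(i, j), max(i, j)) for i, j in edges})
        per_node, mean = clustering_coefficient(g)
        np.testing.assert_allclose(per_node, 0.5)
        assert mean == pytest.approx(0.5)

    def test_disconnected_path_length_raises(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(DisconnectedGraphError):
            characteristic_path_length(g)
        # efficiency treats unreachable pairs as zero contribution
        assert global_efficiency(g)[1] == pytest.approx(2.0 / 6.0)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(25))
    def test_random_graphs_match_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 13))
        g = random_connected_graph(n, float(rng.uniform(0.3, 0.8)), rng)
        adj = g.adjacency.tolist()

        c_node, c_mean = clustering_coefficient(g)
        oc_node, oc_mean = oracle_clustering(adj)
        np.testing.assert_allclose(c_node, oc_node, atol=1e-12)
        assert c_mean == pytest.approx(oc_mean, abs=1e-12)

        l_node, l_mean = characteristic_path_length(g)
        ol_node, ol_mean = oracle_path_length(adj)
        np.testing.assert_allclose(l_node, ol_node, atol=1e-12)
        assert l_mean == pytest.approx(ol_mean, abs=1e-12)

        e_node, e_mean = global_efficiency(g)
        oe_node, oe_mean = oracle_global_efficiency(adj)
        np.testing.assert_allclose(e_node, oe_node, atol=1e-12)
        assert e_mean == pytest.approx(oe_mean, abs=1e-12)

        le_node, le_mean = local_efficiency(g)
        ole_node, ole_mean = oracle_local_efficiency(adj)
        np.testing.assert_allclose(le_node, ole_node, atol=1e-12)
        assert le_mean == pytest.approx(ole_mean, abs=1e-12)


class TestNullModel:
    def test_degrees_preserved_exactly(self):
        rng = np.random.default_rng(1)
        g = random_connected_graph(30, 0.2, rng)
        for null in rewire_preserving_degree(g, n_nulls=5, seed=3):
            np.testing.assert_array_equal(null.degrees(), g.degrees())
            assert not np.any(np.diagonal(null.adjacency))
            assert np.array_equal(null.adjacency, null.adjacency.T)
            characteristic_path_length(null)  # still connected

    def test_nulls_actually_randomize(self):
        rng = np.random.default_rng(2)
        g = random_connected_graph(30, 0.2, rng)
        nulls = rewire_preserving_degree(g, n_nulls=3, seed=4)
        for null in nulls:
            assert np.any(null.adjacency != g.adjacency)
        assert np.any(nulls[0].adjacency != nulls[1].adjacency)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        g = random_connected_graph(20, 0.3, rng)
        a = rewire_preserving_degree(g, n_nulls=2, seed=9)
        b = rewire_preserving_degree(g, n_nulls=2, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)

    def test_swap_free_graph_returns_input(self):
        g = complete_graph(3)
        nulls = rewire_preserving_degree(g, n_nulls=2, seed=0)
        for null in nulls:
            np.testing.assert_array_equal(null.adjacency, g.adjacency)

    def test_small_world_ratios_of_lattice(self):
        from restgraph import generate_planted_graph

        g = generate_planted_graph(60, 3, 0.1, seed=0)
        nulls = rewire_preserving_degree(g, n_nulls=20, seed=1)
        gamma, lam, sigma, null_cp, null_lp = small_world_parameters(g, nulls)
        assert gamma > 1.0
        assert 0.8 < lam < 1.6
        assert sigma == pytest.approx(gamma / lam)
        assert null_cp > 0
        assert null_lp >= 1.0


class TestMetricTable:
    def test_table_shape_and_contents(self):
        rng = np.random.default_rng(5)
        graphs = [random_connected_graph(10, 0.5, rng) for _ in range(2)]
        graphs[0].cost, graphs[1].cost = 0.2, 0.3
        table = metric_table("subj", graphs, include_nodal=True)
        assert set(table["cost"]) == {0.2, 0.3}
        glob = table[table["scope"] == "global"]
        assert len(glob) == 2 * 4
        node = table[table["scope"] == "node"]
        assert len(node) == 2 * 4 * 10
        # table values agree with direct computation
        g0 = graphs[0]
        row = glob[(glob["cost"] == 0.2) & (glob["metric"] == "clustering")]
        assert row["value"].iloc[0] == pytest.approx(clustering_coefficient(g0)[1])

    def test_smallworld_only_at_requested_costs(self):
        rng = np.random.default_rng(6)
        graphs = [random_connected_graph(12, 0.5, rng) for _ in range(2)]
        graphs[0].cost, graphs[1].cost = 0.2, 0.3
        table = metric_table("s", graphs, n_nulls=5, smallworld_costs=[0.3], include_nodal=False)
        sw = table[table["metric"].isin(["gamma", "lambda", "sigma"])]
        assert set(sw["cost"]) == {0.3}
        assert len(sw) == 3

    def test_compute_metrics_with_nulls_populates_ratios(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(20, 0.3, rng)
        ms = compute_metrics(g, n_nulls=5, seed=2)
        assert ms.n_nulls == 5
        assert ms.gamma is not None and ms.sigma == pytest.approx(ms.gamma / ms.lambda_ratio)
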