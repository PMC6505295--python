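import numpy as np
import pytest

from scnpf import (
    ExpressionMatrix,
    GeneNetwork,
    NetworkPropagation,
    PropagationConfig,
    SimulationConfig,
    normalize_adjacency,
    propagate_matrix,
    rwr_propagate,
    scnpf_propagation,
    simulate_expression,
    simulate_network,
)


def _net(adj, prefix="g"):
    adj = np.asarray(adj, dtype=float)
    return GeneNetwork([f"{prefix}{i}" for i in range(adj.shape[0])], adj)


def random_connected_network(rng, n):
    adj = (rng.random((n, n)) < 0.1) * rng.random((n, n))
    adj = np.triu(adj, 1)
    for i in range(1, n):  # spanning path guarantees connectivity
        adj[i - 1, i] = max(adj[i - 1, i], rng.random() + 0.1)
    return _net(adj + adj.T)


class TestNormalizeAdjacency:
    def test_regular_graph_unchanged(self):
        tm = normalize_adjacency(_net([[0, 1], [1, 0]]))
        np.testing.assert_array_equal(tm.W, [[0, 1], [1, 0]])

    def test_path_graph_splits_middle_column(self):
        tm = normalize_adjacency(_net([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        np.testing.assert_allclose(tm.W[:, 1], [0.5, 0, 0.5])
        np.testing.assert_allclose(tm.W.sum(axis=0), 1.0)

    def test_isolated_node_column_stays_zero(self):
        tm = normalize_adjacency(_net([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        assert np.all(tm.W[:, 2] == 0)
        assert list(tm.isolated()) == [False, False, True]


class TestRWR:
    def test_r_equal_one_is_identity(self, rng):
        net = random_connected_network(rng, 30)
        tm = normalize_adjacency(net)
        p0 = rng.random(30)
        out = rwr_propagate(tm, p0, PropagationConfig(r=1.0))
        np.testing.assert_array_equal(out, p0)

    def test_two_node_toy_steady_state(self):
        # direct solve of (I - 0.5 W) p = 0.5 p0 gives [2/3, 1/3]
        tm = normalize_adjacency(_net([[0, 1], [1, 0]]))
        for method in ("iterative", "closed_form"):
            out = rwr_propagate(
                tm, np.array([1.0, 0.0]), PropagationConfig(r=0.5, method=method)
            )
            np.testing.assert_allclose(out, [2 / 3, 1 / 3], atol=1e-6)

    def test_iterative_matches_closed_form(self, rng):
        net = random_connected_network(rng, 100)
        tm = normalize_adjacency(net)
        p0 = rng.random(100) * 10
        it = rwr_propagate(tm, p0, PropagationConfig(r=0.5, method="iterative", tol=1e-10))
        cf = rwr_propagate(tm, p0, PropagationConfig(r=0.5, method="closed_form"))
        np.testing.assert_allclose(it, cf, atol=1e-6)

    def test_mass_conserved_on_connected_graph(self, rng):
        net = random_connected_network(rng, 60)
        tm = normalize_adjacency(net)
        p0 = rng.random(60)
        out = rwr_propagate(tm, p0, PropagationConfig(r=0.5))
        assert out.sum() == pytest.approx(p0.sum(), abs=1e-8)

    def test_r_zero_rejected(self):
        with pytest.raises(ValueError, match="restart probability"):
            PropagationConfig(r=0.0)

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        net = random_connected_network(rng, 50)
        tm = normalize_adjacency(net)
        with pytest.raises(RuntimeError, match="did not converge"):
            rwr_propagate(
                tm,
                rng.random(50),
                PropagationConfig(r=0.01, method="iterative", max_iter=2, tol=1e-14),
            )


class TestPropagateMatrix:
    def test_disjoint_gene_sets_error(self, small_expr):
        net = _net(np.array([[0.0, 1], [1, 0]]), prefix="other")
        with pytest.raises(ValueError, match="no overlap"):
            propagate_matrix(small_expr, net)

    def test_gene_outside_network_passes_through(self, small_expr):
        # network covers only the first 10 genes
        sub = np.ones((10, 10)) - np.eye(10)
        net = GeneNetwork(small_expr.gene_ids[:10], sub)
        out = propagate_matrix(small_expr, net)
        np.testing.assert_array_equal(out.values[10:], small_expr.values[10:])
        assert out.gene_ids == small_expr.gene_ids
        assert out.cell_ids == small_expr.cell_ids

    def test_two_module_toy_confines_mass(self):
        # two 10-gene cliques joined by one weak bridge; signal seeded in
        # module 1 should barely leak into module 2 at r=0.5
        n = 20
        adj = np.zeros((n, n))
        adj[:10, :10] = 1.0
        adj[10:, 10:] = 1.0
        np.fill_diagonal(adj, 0.0)
        adj[9, 10] = adj[10, 9] = 1e-4
        net = _net(adj)
        p0 = np.zeros(n)
        p0[:5] = 10.0
        tm = normalize_adjacency(net)
        # independent direct solve of the steady-state linear system
        expected = 0.5 * np.linalg.solve(np.eye(n) - 0.5 * tm.W, p0)
        got = rwr_propagate(tm, p0, PropagationConfig(r=0.5, method="iterative", tol=1e-12))
        np.testing.assert_allclose(got, expected, atol=1e-8)
        assert np.all(got[:10][p0[:10] == 0] > 0)  # within-module zeros filled
        assert got[10:].sum() < 1e-3 * got.sum()  # across-bridge leak tiny

    def test_matrix_totals_conserved_per_cell(self, rng):
        net = random_connected_network(rng, 40)
        expr = ExpressionMatrix(
            rng.poisson(2.0, size=(40, 15)).astype(float),
            net.node_ids,
            [f"c{i}" for i in range(15)],
        )
        out = propagate_matrix(expr, net, PropagationConfig(r=0.5))
        np.testing.assert_allclose(
            out.values.sum(axis=0), expr.values.sum(axis=0), atol=1e-8
        )

    def test_rescale_restores_totals(self, rng):
        # only half the network genes are measured, so mass leaks to the
        # unmeasured block; rescale restores per-cell totals
        net = random_connected_network(rng, 40)
        expr = ExpressionMatrix(
            rng.poisson(2.0, size=(20, 5)).astype(float) + 1,
            net.node_ids[:20],
            [f"c{i}" for i in range(5)],
        )
        out = propagate_matrix(expr, net, PropagationConfig(r=0.5, rescale=True))
        np.testing.assert_allclose(
            out.values.sum(axis=0), expr.values.sum(axis=0), atol=1e-8
        )


class TestScnpfPropagation:
    def test_context_mode_densifies(self):
        expr, labels, modules = simulate_expression(SimulationConfig(seed=3))
        out = scnpf_propagation(expr, mode="context")
        assert (out.values == 0).sum() < (expr.values == 0).sum()

    def test_priori_mode_matches_per_cell_propagation(self, rng):
        net = random_connected_network(rng, 30)
        expr = ExpressionMatrix(
            rng.poisson(3.0, size=(30, 4)).astype(float),
            net.node_ids,
            [f"c{i}" for i in range(4)],
        )
        from scnpf import PrioriNetworkConfig, prepare_priori_network

        pcfg = PrioriNetworkConfig(edge_quantile=0.0)
        out = scnpf_propagation(expr, mode="priori", net=net, priori_cfg=pcfg)
        prepared = prepare_priori_network(net, pcfg)
        tm = normalize_adjacency(prepared)
        for j in range(4):
            expected = rwr_propagate(tm, expr.values[:, j])
            np.testing.assert_allclose(out.values[:, j], expected, atol=1e-10)

    def test_moderately_expressed_gene_count_increases(self):
        # at 30% dropout, imputation should raise the number of genes
        # detected in more than half the cells
        expr, labels, modules = simulate_expression(
            SimulationConfig(seed=7, dropout_rate_target=0.3)
        )
        from scnpf import ContextNetworkConfig

        # permissive gene filter so the network also covers the moderately
        # expressed genes whose detection imputation should rescue
        ctx = ContextNetworkConfig(gene_expr_percentile=0.0)
        out = scnpf_propagation(expr, mode="context", ctx_cfg=ctx)
        threshold = expr.n_cells / 2
        before = ((expr.values > 0).sum(axis=1) > threshold).sum()
        after = ((out.values > 0).sum(axis=1) > threshold).sum()
        assert after > before

    def test_same_cluster_profiles_move_closer(self):
        expr, labels, modules = simulate_expression(SimulationConfig(seed=5))
        net = simulate_network(modules, seed=5, gene_ids=expr.gene_ids)
        out = scnpf_propagation(expr, mode="priori", net=net)

        def mean_within_cluster_l1(values):
            dists = []
            for c in np.unique(labels):
                cols = values[:, labels == c]
                cols = cols / cols.sum(axis=0, keepdims=True)
                for a in range(0, cols.shape[1] - 1, 2):
                    dists.append(np.abs(cols[:, a] - cols[:, a + 1]).sum())
            return np.mean(dists)

        assert mean_within_cluster_l1(out.values) < mean_within_cluster_l1(expr.values)


class TestEstimatorInterface:
    def test_fit_transform_and_params(self):
        expr, labels, modules = simulate_expression(SimulationConfig(seed=2))
        est = NetworkPropagation(mode="context", r=0.5)
        assert est.get_params()["r"] == 0.5
        out = est.fit(expr).transform(expr)
        assert hasattr(est, "network_") and hasattr(est, "transition_")
        assert out.shape == expr.shape

    def test_unfitted_transform_errors(self, small_expr):
        with pytest.raises(RuntimeError, match="not fitted"):
            NetworkPropagation().transform(small_expr)

    def test_priori_without_network_errors(self, small_expr):
        with pytest.raises(ValueError, match="requires a network"):
            NetworkPropagation(mode="priori").fit(small_expr)
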