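"""Network estimation, centrality, and stability diagnostics."""

import numpy as np
import pandas as pd
import pytest

from traitnet.impute import pmm_impute
from traitnet.network import (
    CovarianceNetwork,
    centrality,
    correlation_matrix,
    cs_coefficient,
    edge_bootstrap,
    estimate_network,
)
from traitnet.network import _partial_from_precision


def normal_table(n, corr, seed=0, names=None):
    rng = np.random.default_rng(seed)
    p = corr.shape[0]
    X = rng.multivariate_normal(np.zeros(p), corr, size=n)
    return pd.DataFrame(X, columns=names or [f"v{i}" for i in range(p)])


class TestCorrelationMatrix:
    def test_duplicated_and_negated_columns(self):
        df = normal_table(50, np.eye(3), seed=1)
        df["dup"] = df["v0"]
        df["neg"] = -df["v1"]
        cm = correlation_matrix(df)
        assert cm.rho.at["v0", "dup"] == pytest.approx(1.0)
        assert cm.rho.at["v1", "neg"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        cm = correlation_matrix(normal_table(500, np.eye(8), seed=2))
        off = np.abs(cm.rho.to_numpy()[np.triu_indices(8, 1)])
        assert off.mean() < 0.1

    def test_constant_column_warns_and_sets_missing(self):
        df = normal_table(30, np.eye(3), seed=3)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="undefined"):
            cm = correlation_matrix(df)
        assert np.isnan(cm.rho.at["v0", "flat"])

    def test_pairwise_complete_counts(self):
        df = normal_table(30, np.eye(3), seed=4)
        df.iloc[:10, 0] = np.nan
        cm = correlation_matrix(df)
        assert cm.n_pairs.at["v0", "v1"] == 20
        assert cm.n_pairs.at["v1", "v2"] == 30

    def test_imputation_set_pooling(self):
        df = normal_table(30, np.eye(3), seed=5)
        df.iloc[:5, 1] = np.nan
        imp = pmm_impute(df, m=3, maxit=3, seed=6)
        pooled = correlation_matrix(imp)
        first = correlation_matrix(imp, pooling="first")
        assert pooled.rho.shape == (3, 3)
        assert np.allclose(np.diag(pooled.rho), 1.0)
        assert not pooled.rho.equals(first.rho) or imp.m == 1


class TestEstimator:
    def test_identity_input_gives_empty_network(self):
        cm = correlation_matrix(normal_table(200, np.eye(5), seed=7))
        net = estimate_network(cm)
        assert np.allclose(net.weights_, 0.0)

    def test_direct_dependence_recovered_and_bystander_isolated(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=500)
        x2 = rng.normal(size=500)
        x3 = x1 + 0.3 * rng.normal(size=500)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        net = estimate_network(df)
        W = net.weights_frame()
        assert W.at["x1", "x3"] > 0.5
        assert abs(W.at["x1", "x2"]) < 0.1
        assert abs(W.at["x2", "x3"]) < 0.1

    def test_chain_conditional_independence(self):
        # x1 -> x2 -> x3: the partial edge (1,3) vanishes although the
        # marginal correlation is strong
        rng = np.random.default_rng(9)
        x1 = rng.normal(size=1000)
        x2 = 0.8 * x1 + 0.6 * rng.normal(size=1000)
        x3 = 0.8 * x2 + 0.6 * rng.normal(size=1000)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        net = estimate_network(df)
        W = net.weights_frame()
        assert df["x1"].corr(df["x3"], method="spearman") > 0.3
        assert abs(W.at["x1", "x3"]) < 0.1
        assert W.at["x1", "x2"] > 0.3 and W.at["x2", "x3"] > 0.3

    def test_zero_penalty_limit_matches_pseudoinverse(self):
        corr = np.array([
            [1.0, 0.5, 0.2],
            [0.5, 1.0, 0.4],
            [0.2, 0.4, 1.0],
        ])
        df = normal_table(4000, corr, seed=10)
        S = df.corr(method="spearman").to_numpy()
        expected = _partial_from_precision(np.linalg.inv(S))
        net = CovarianceNetwork(lambda_fixed=1e-10).fit(df)
        assert np.allclose(net.weights_, expected, atol=1e-6)

    def test_correlation_estimator_returns_rho(self):
        df = normal_table(100, np.eye(4), seed=11)
        net = estimate_network(df, estimator="correlation")
        rho = df.corr(method="spearman").to_numpy()
        np.fill_diagonal(rho, 0.0)
        assert np.allclose(net.weights_, rho)

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError, match="estimator"):
            estimate_network(normal_table(20, np.eye(3)), estimator="magic")


def brute_force_centrality(W):
    """Independent recomputation of the three metrics from their definitions."""
    p = W.shape[0]
    strength = np.array([sum(abs(W[i, j]) for j in range(p)) for i in range(p)])
    ei = np.array([sum(W[i, j] for j in range(p)) for i in range(p)])
    A = np.abs(W)
    v = np.ones(p)
    for _ in range(2000):  # power iteration
        nxt = A @ v
        if nxt.max() == 0:
            break
        nxt = nxt / np.linalg.norm(nxt)
        if np.allclose(nxt, v, atol=1e-12):
            v = nxt
            break
        v = nxt
    eig = np.abs(v) / np.abs(v).max() if np.abs(v).max() > 0 else np.abs(v)
    return strength, eig, ei


class TestCentrality:
    def test_hand_example(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.3
        c = centrality(W)
        assert c.loc[0, "strength"] == pytest.approx(0.8)
        assert c.loc[0, "expected_influence"] == pytest.approx(0.2)

    def test_two_node_symmetry(self):
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        c = centrality(W)
        assert np.allclose(c["eigenvector"], 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(-1, 1, (5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        c = centrality(W)
        s, e, ei = brute_force_centrality(W)
        assert np.allclose(c["strength"], s)
        assert np.allclose(c["expected_influence"], ei)
        assert np.allclose(c["eigenvector"], e, atol=1e-6)
        # rankings agree with the oracle
        assert list(np.argsort(c["eigenvector"])) == list(np.argsort(e))

    def test_sum_identities(self):
        rng = np.random.default_rng(12)
        W = rng.uniform(-1, 1, (6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        c = centrality(W)
        assert c["strength"].sum() == pytest.approx(np.abs(W).sum())
        assert c["expected_influence"].sum() == pytest.approx(W.sum())
        assert (c["strength"] >= c["expected_influence"].abs() - 1e-12).all()

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            c = centrality(np.zeros((4, 4)))
        assert (c == 0).all().all()


class TestEdgeBootstrap:
    def test_strong_edge_flagged_significant(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.9
        df = normal_table(100, corr, seed=13)
        res = edge_bootstrap(df, n_boot=150, seed=1,
                             estimator=CovarianceNetwork(n_lambda=20))
        assert res.mask.iloc[0, 1]

    def test_null_false_positive_rate_near_nominal(self):
        # independent columns: ~5% of edges spuriously significant
        rates = []
        for seed in range(6):
            df = normal_table(100, np.eye(8), seed=20 + seed)
            res = edge_bootstrap(
                df, n_boot=150, seed=seed,
                estimator=CovarianceNetwork(estimator="correlation"),
            )
            rates.append(res.edges["significant"].mean())
        assert 0.005 < np.mean(rates) < 0.15

    def test_deterministic_under_seed(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.5
        df = normal_table(60, corr, seed=14)
        est = CovarianceNetwork(n_lambda=15)
        a = edge_bootstrap(df, estimator=est, n_boot=50, seed=3)
        b = edge_bootstrap(df, estimator=est, n_boot=50, seed=3)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            edge_bootstrap(normal_table(5, np.eye(3)), n_boot=10, seed=0)


class TestCSCoefficient:
    def test_replicated_strong_signal_is_maximally_stable(self):
        # hub + isolated node: a heterogeneous strength profile that any
        # subset of the 20x-replicated cohort reproduces
        theta = np.eye(6)
        for a, b, w in [(0, 1, 0.7), (1, 2, 0.6), (3, 4, -0.6)]:
            theta[a, b] = theta[b, a] = -w
        S = np.linalg.inv(theta)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        base = normal_table(24, S, seed=15)
        big = pd.concat([base] * 20, ignore_index=True)
        res = cs_coefficient(
            big, metric="strength",
            estimator=CovarianceNetwork(n_lambda=15),
            drop_grid=[0.25, 0.5, 0.75],
            n_boot=40, seed=4,
        )
        assert res.cs_coefficient == 0.75
        assert res.reliable

    def test_pure_noise_is_unstable(self):
        df = normal_table(24, np.eye(6), seed=16)
        res = cs_coefficient(
            df, metric="expected_influence",
            estimator=CovarianceNetwork(n_lambda=15),
            n_boot=40, seed=5,
        )
        assert res.cs_coefficient < 0.25
        assert not res.reliable

    def test_monotone_nonincreasing_in_r_threshold(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.7
        df = normal_table(120, corr, seed=17)
        est = CovarianceNetwork(estimator="correlation")
        cs_values = [
            cs_coefficient(df, metric="strength", estimator=est,
                           n_boot=60, r_threshold=r, seed=6).cs_coefficient
            for r in (0.5, 0.7, 0.9)
        ]
        assert cs_values[0] >= cs_values[1] >= cs_values[2]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            cs_coefficient(normal_table(20, np.eye(3)), metric="pagerank")


def test_plot_network_draws_edges():
    import matplotlib

    matplotlib.use("Agg")
    from traitnet.network import plot_network

    corr = np.eye(3)
    corr[0, 1] = corr[1, 0] = 0.8
    net = estimate_network(normal_table(200, corr, seed=30))
    ax = plot_network(net)
    assert len(ax.lines) >= 1
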