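"""Graphical lasso, EBIC selection, partial correlations, density bands."""

import warnings

import numpy as np
import pandas as pd
import pytest

from bridgenet import (
    EstimationConfig,
    density_band,
    ebic_score,
    estimate_network,
    graphical_lasso,
    lambda_path,
    make_multilayer_precision,
    precision_to_pcor,
    sample_cohort,
)


class TestLambdaPath:
    def test_endpoints(self):
        S = np.array([[1.0, 0.8], [0.8, 1.0]])
        path = lambda_path(S, EstimationConfig(n_lambdas=2, lambda_min_ratio=0.01))
        np.testing.assert_allclose(path, [0.8, 0.008])

    def test_strictly_decreasing(self):
        S = np.array([[1.0, 0.5, 0.2], [0.5, 1, 0.1], [0.2, 0.1, 1]])
        path = lambda_path(S, EstimationConfig(n_lambdas=50))
        assert (np.diff(path) < 0).all()

    def test_identity_degenerates_to_single_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            path = lambda_path(np.eye(4))
        np.testing.assert_array_equal(path, [0.0])


class TestGraphicalLasso:
    def test_unpenalized_limit_is_matrix_inverse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        S = np.corrcoef(X, rowvar=False)
        K = graphical_lasso(S, 0.0)
        np.testing.assert_allclose(K, np.linalg.inv(S), atol=1e-6)

    @pytest.mark.parametrize("r,lam,vanishes", [(0.5, 0.6, True), (0.5, 0.5, True), (0.5, 0.3, False)])
    def test_p2_closed_form_edge_vanishing(self, r, lam, vanishes):
        # for p=2 the glasso covariance soft-thresholds the off-diagonal:
        # the edge survives iff lam < |r|
        S = np.array([[1.0, r], [r, 1.0]])
        K = graphical_lasso(S, lam)
        if vanishes:
            assert abs(K[0, 1]) < 1e-8
        else:
            expected = (abs(r) - lam)  # surviving covariance entry magnitude
            W = np.linalg.inv(K)
            assert abs(abs(W[0, 1]) - expected) < 1e-4

    def test_diagonal_input_stays_diagonal(self):
        S = np.diag([1.0, 1.0, 1.0])
        for lam in (0.0, 0.2, 0.8):
            K = graphical_lasso(S, lam)
            assert np.allclose(K - np.diag(np.diag(K)), 0.0, atol=1e-10)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(2), -0.1)

    def test_kkt_conditions_at_zero_entries(self):
        # subgradient optimality: |S_ij - (K^-1)_ij| <= lam wherever K_ij = 0
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 4))
        S = np.corrcoef(X, rowvar=False)
        lam = 0.15
        K = graphical_lasso(S, lam, EstimationConfig(convergence_tol=1e-8, max_iter=500))
        G = S - np.linalg.inv(K)
        for i in range(4):
            for j in range(4):
                if i != j and abs(K[i, j]) < 1e-10:
                    assert abs(G[i, j]) <= lam + 1e-4


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 5))
        S = np.corrcoef(X, rowvar=False)
        K = graphical_lasso(S, 0.1)
        n = 300
        score = ebic_score(K, S, n, gamma=0.0)
        iu = np.triu_indices(5, 1)
        E = int((np.abs(K[iu]) > 1e-6).sum())
        sign, logdet = np.linalg.slogdet(K)
        L = n / 2 * (logdet - np.trace(S @ K))
        assert score == pytest.approx(-2 * L + E * np.log(n))

    def test_empty_identity_model_has_no_penalty_term(self):
        # with E = 0 the score is the bare -2L = n*p baseline, independent
        # of gamma: the empty model incurs no complexity penalty at all
        for gamma in (0.0, 0.5, 0.7):
            assert ebic_score(np.eye(2), np.eye(2), n=100, gamma=gamma) == pytest.approx(200.0)

    def test_three_node_hand_oracle(self):
        # two edges: (0,1) and (1,2); direct determinant/trace arithmetic
        K = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, -0.2], [0.0, -0.2, 1.0]])
        S = np.eye(3)
        n, gamma, p, E = 457, 0.5, 3, 2
        det = np.linalg.det(K)
        L = n / 2 * (np.log(det) - np.trace(K))
        expected = -2 * L + E * np.log(n) + 4 * E * gamma * np.log(p)
        assert ebic_score(K, S, n, gamma) == pytest.approx(expected, rel=1e-12)

    def test_non_positive_definite_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ebic_score(K, np.eye(2), 100)


class TestPrecisionToPcor:
    def test_two_by_two_formula(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        W = precision_to_pcor(K)
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0.0

    def test_diagonal_gives_zero_weights(self):
        assert np.all(precision_to_pcor(np.diag([2.0, 3.0, 1.0])) == 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 4))
        K = A @ A.T + 4 * np.eye(4)
        np.testing.assert_allclose(
            precision_to_pcor(K), precision_to_pcor(7.3 * K), atol=1e-12
        )

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_pcor(np.array([[0.0, 0.1], [0.1, 1.0]]))

    def test_unpenalized_pipeline_matches_regression_partial_correlation(self):
        """pcor from inverse correlation equals the residual-based definition."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 4))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 2] -= 0.4 * X[:, 0]
        S = np.corrcoef(X, rowvar=False)
        W = precision_to_pcor(graphical_lasso(S, 0.0))
        # oracle: correlate the residuals of i and j on all other columns
        for i, j in [(0, 1), (1, 2), (0, 3)]:
            others = [k for k in range(4) if k not in (i, j)]
            Z = np.column_stack([np.ones(400), X[:, others]])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            oracle = np.corrcoef(ri, rj)[0, 1]
            assert W[i, j] == pytest.approx(oracle, abs=1e-6)


class TestEstimateNetwork:
    def test_diagonal_truth_recovers_near_empty_network(self):
        model = make_multilayer_precision(
            [3, 3], within_density=0, between_density=0, seed=4,
            ordinal_layers=(), age_effect=0.0, tiv_effect=0.0, site_effect_sd=0.0,
        )
        table = sample_cohort(model, n=2000, seed=5)
        net = estimate_network(table)
        assert net.density <= 0.05

    def test_dense_within_model_recovered_with_signs(self):
        model = make_multilayer_precision(
            [3, 3], within_density=1.0, between_density=0.0, seed=6,
            weight_range=(0.3, 0.45),
            ordinal_layers=(), age_effect=0.0, tiv_effect=0.0, site_effect_sd=0.0,
        )
        table = sample_cohort(model, n=2000, seed=7)
        net = estimate_network(table)
        Wt = model.partial_correlations()
        We = net.weights.to_numpy()
        membership = model.layer_spec.membership()
        for i in range(6):
            for j in range(i + 1, 6):
                if membership[i] == membership[j]:
                    assert abs(We[i, j]) > 1e-6, (i, j)
                    assert np.sign(We[i, j]) == np.sign(Wt[i, j])

    def test_determinism(self, default_table, fast_config):
        a = estimate_network(default_table, fast_config)
        b = estimate_network(default_table, fast_config)
        assert a.weights.equals(b.weights)
        assert a.selected_lambda == b.selected_lambda

    def test_path_monotonicity_and_selection(self, default_table, fast_config):
        net = estimate_network(default_table, fast_config)
        path = net.ebic_path
        # sparser at the strongly penalized end of the path
        assert path["n_edges"].iloc[0] <= path["n_edges"].iloc[-1]
        selected = path.loc[path["lambda"] == net.selected_lambda, "ebic"].iloc[0]
        assert selected <= path["ebic"].min() + 1e-12

    def test_weights_are_partial_correlations(self, default_table, fast_config):
        net = estimate_network(default_table, fast_config)
        W = net.weights.to_numpy()
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0.0)
        assert np.abs(W).max() < 1.0


class TestDensityBand:
    @pytest.mark.parametrize(
        "edges,possible,pct,band",
        [
            (28, 45, 62.2, "high"),
            (53, 153, 34.6, "medium"),
            (0, 45, 0.0, "low"),
            (13, 45, 28.9, "low"),
        ],
    )
    def test_bands_and_percentages(self, edges, possible, pct, band):
        fraction = edges / possible
        got_band, got_fraction = density_band(fraction)
        assert got_band == band
        assert round(100 * got_fraction, 1) == pct

    def test_on_network_object(self, four_node_network):
        band, fraction = density_band(four_node_network)
        assert fraction == pytest.approx(4 / 6)
        assert band == "high"

    def test_possible_edge_combinatorics(self, four_node_network):
        assert four_node_network.n_possible_edges == 4 * 3 // 2
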