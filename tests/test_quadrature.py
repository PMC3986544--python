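import warnings

import numpy as np
import pytest
from scipy.special import expit, ndtr

import mtmmirt as mt
from mtmmirt.model import ModelParameters, ResponseMatrix, params_to_vector
from mtmmirt.quadrature import (CapacityError, build_grid, fit_quadrature,
                                marginal_log_likelihood, person_posterior_mode)
from mtmmirt.simulate import SimulationSpec, simulate_responses


class TestBuildGrid:
    def test_tensor_node_counts(self):
        assert build_grid(8, 6).n_nodes == 262_144
        assert build_grid(3, 4).n_nodes == 81

    def test_single_point_rule_is_prior_mean(self):
        g = build_grid(1, 5)
        np.testing.assert_allclose(g.nodes, 0.0, atol=1e-12)
        assert np.exp(g.log_weights[0]) == pytest.approx(1.0)

    def test_two_point_rule(self):
        g = build_grid(2, 1)
        np.testing.assert_allclose(np.sort(g.nodes.ravel()), [-1.0, 1.0],
                                   atol=1e-12)
        np.testing.assert_allclose(np.exp(g.log_weights), 0.5, atol=1e-12)

    @pytest.mark.parametrize("points,dims", [(3, 2), (7, 3), (15, 1), (5, 5)])
    def test_weights_sum_to_one(self, points, dims):
        g = build_grid(points, dims)
        assert np.exp(g.log_weights).sum() == pytest.approx(1.0, abs=1e-10)

    def test_node_budget_enforced(self):
        with pytest.raises(CapacityError, match="262,144"):
            build_grid(8, 6, node_budget=100_000)

    def test_gaussian_moments_integrated_exactly(self):
        # degree-(2k-1) exactness: E[x^4] = 3 under the standard normal
        g = build_grid(3, 1)
        w = np.exp(g.log_weights)
        assert (w * g.nodes[:, 0] ** 4).sum() == pytest.approx(3.0, abs=1e-10)


class TestPersonPosteriorMode:
    def test_zero_loadings_give_prior(self):
        d = mt.crossed_design(["t"], ["m"], items_per_cell=3)
        p = ModelParameters(np.zeros(3), np.zeros(3), np.zeros(3), np.eye(1))
        mode, curv = person_posterior_mode(d, p, np.array([1.0, 0.0, 1.0]))
        np.testing.assert_allclose(mode, 0.0, atol=1e-10)
        np.testing.assert_allclose(curv, np.eye(2), atol=1e-10)

    def test_mode_matches_dense_grid_argmax(self):
        """1-trait 2PL posterior mode vs a 2001-point dense grid."""
        d = mt.crossed_design(["t"], ["m"], items_per_cell=4)
        p = ModelParameters(np.array([1.4, 0.9, 1.1, 0.7]), np.zeros(4),
                            np.array([-0.5, 0.2, 0.8, -1.0]), np.eye(1))
        y = np.array([1.0, 1.0, 0.0, 1.0])
        mode, _ = person_posterior_mode(d, p, y)
        grid = np.linspace(-5, 5, 2001)
        lp = -0.5 * grid**2
        for i in range(4):
            eta = p.trait_loadings[i] * grid + p.intercepts[i]
            lp += y[i] * np.log(expit(eta)) + (1 - y[i]) * np.log(expit(-eta))
        assert abs(mode[0] - grid[np.argmax(lp)]) < (grid[1] - grid[0])

    def test_gaussian_pseudo_posterior_closed_form(self):
        """With small loadings the logit log-likelihood is locally
        quadratic; check the Newton solution against the conjugate
        normal algebra at a crafted symmetric configuration."""
        d = mt.crossed_design(["t"], ["m"])
        p = ModelParameters(np.array([0.01]), np.zeros(1), np.zeros(1), np.eye(1))
        mode, curv = person_posterior_mode(d, p, np.array([1.0]))
        # prior N(0,1), likelihood gradient ~ a*(y-1/2) at 0
        assert mode[0] == pytest.approx(0.01 * 0.5, rel=1e-2)
        assert curv[0, 0] == pytest.approx(1.0 + 0.01**2 * 0.25, rel=1e-3)


class TestMarginalLogLikelihood:
    def test_zero_model_closed_form(self):
        d = mt.crossed_design(["t1", "t2"], ["m1"], items_per_cell=2)
        p = ModelParameters(np.zeros(4), np.zeros(4), np.zeros(4), np.eye(2))
        y = ResponseMatrix(np.random.default_rng(0).integers(0, 2, (30, 4)).astype(float))
        ll = marginal_log_likelihood(d, p, y, points_per_dim=3)
        assert ll == pytest.approx(30 * 4 * np.log(0.5), abs=1e-10)

    def test_probit_one_factor_closed_form(self):
        """Per-item marginal P(y=1) = Phi(beta / sqrt(1 + a^2))."""
        d = mt.crossed_design(["t"], ["m"], items_per_cell=4)
        a = np.array([0.8, 1.2, 0.5, 1.0])
        b = np.array([-0.5, 0.3, 1.0, -1.2])
        p = ModelParameters(a, np.zeros(4), b, np.eye(1), link="probit")
        for i in range(4):
            y = np.full((1, 4), np.nan)
            y[0, i] = 1.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                data = ResponseMatrix(y)
            ll = marginal_log_likelihood(d, p, data, points_per_dim=30)
            assert np.exp(ll) == pytest.approx(
                ndtr(b[i] / np.sqrt(1 + a[i] ** 2)), abs=1e-6)

    def test_grid_refinement_converges(self, crossed22, crossed22_data):
        d, p = crossed22.design, crossed22.params
        sub = ResponseMatrix(crossed22_data.responses[:20])
        coarse = marginal_log_likelihood(d, p, sub, points_per_dim=10)
        dense = marginal_log_likelihood(d, p, sub, points_per_dim=50)
        assert coarse == pytest.approx(dense, abs=1e-4)

    def test_adaptive_beats_unadapted_at_equal_points(self):
        d = mt.crossed_design(["t"], ["m"], items_per_cell=4)
        p = ModelParameters(np.full(4, 1.8), np.full(4, 1.2),
                            np.array([-1.0, 0.0, 0.5, 1.0]), np.eye(1))
        rng = np.random.default_rng(5)
        data = simulate_responses(SimulationSpec(d, p, 50), rng)
        dense = marginal_log_likelihood(d, p, data, points_per_dim=50)
        for k in (3, 5, 7):
            plain = marginal_log_likelihood(d, p, data, points_per_dim=k)
            adapt = marginal_log_likelihood(d, p, data, points_per_dim=k,
                                            adaptive=True)
            assert abs(adapt - dense) <= abs(plain - dense) + 1e-9


class TestFitQuadrature:
    def test_zero_loading_data_recovers_small_loadings(self):
        """At a = 0 the loadings enter the likelihood quadratically, so
        the Fisher information vanishes and MLE noise decays only like
        N^(-1/4); the assertion bounds reflect that rate (verified by
        simulation across N)."""
        d = mt.crossed_design(["t"], ["m"], items_per_cell=4)
        p = ModelParameters(np.zeros(4), np.zeros(4),
                            np.array([-0.5, 0.0, 0.5, 1.0]), np.eye(1))
        rng = np.random.default_rng(42)
        data = simulate_responses(SimulationSpec(d, p, 500), rng)
        fit = fit_quadrature(d, data, points_per_dim=7)
        assert np.abs(fit.estimates.trait_loadings).max() < 0.55
        assert np.abs(fit.estimates.method_loadings).max() < 0.55
        big = simulate_responses(SimulationSpec(d, p, 20_000),
                                 np.random.default_rng(42))
        fit_big = fit_quadrature(d, big, points_per_dim=7)
        assert np.abs(fit_big.estimates.trait_loadings).max() < 0.25

    def test_2pl_parameter_recovery_within_3_se(self, small_1d_2pl):
        rng = np.random.default_rng(99)
        data = simulate_responses(small_1d_2pl, rng)
        d = small_1d_2pl.design
        start = ModelParameters(np.full(6, 0.5), np.zeros(6), np.zeros(6),
                                np.eye(1))
        # plain 2PL: the method block is frozen at zero (a free 1x1
        # two-factor fit is rotation-unidentified)
        fit = fit_quadrature(d, data, points_per_dim=9,
                             estimate_loadings="trait", start=start)
        # N = 1000 2PL: loading SEs ~ 0.1, intercept SEs ~ 0.08
        err_a = fit.estimates.trait_loadings - small_1d_2pl.params.trait_loadings
        err_b = fit.estimates.intercepts - small_1d_2pl.params.intercepts
        assert np.abs(err_a).max() < 3 * 0.12
        assert np.abs(err_b).max() < 3 * 0.10

    def test_item_permutation_leaves_likelihood_unchanged(self, crossed22,
                                                          crossed22_data):
        d, p = crossed22.design, crossed22.params
        ll = marginal_log_likelihood(d, p, crossed22_data, points_per_dim=5)
        perm = np.random.default_rng(1).permutation(d.n_items)
        d2 = mt.MTMMDesign(d.trait_of_item[perm], d.method_of_item[perm],
                           tuple(np.array(d.item_labels)[perm]),
                           d.trait_labels, d.method_labels)
        p2 = ModelParameters(p.trait_loadings[perm], p.method_loadings[perm],
                             p.intercepts[perm], p.trait_correlation)
        data2 = ResponseMatrix(crossed22_data.responses[:, perm])
        ll2 = marginal_log_likelihood(d2, p2, data2, points_per_dim=5)
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_mle_dominates_truth(self, crossed22, crossed22_data, quad_fit22):
        ll_truth = marginal_log_likelihood(crossed22.design, crossed22.params,
                                           crossed22_data, points_per_dim=5)
        assert quad_fit22.log_likelihood >= ll_truth
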