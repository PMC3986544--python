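import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import mtmmirt as mt
from mtmmirt.mcll import (AdaptiveRandomWalkSampler, LocalFitConfig,
                          LocalFitError, PosteriorSamples, PriorSpec,
                          fit_mcll, localized_log_likelihood, mcll_objective,
                          sample_posterior)
from mtmmirt.model import ModelParameters, params_to_vector
from mtmmirt.simulate import SimulationSpec, simulate_responses


def make_samples(draws, chains=None):
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] < draws.shape[1]:
        draws = draws.T
    chains = np.zeros(draws.shape[0], int) if chains is None else chains
    names = [f"x{j}" for j in range(draws.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PosteriorSamples(draws, chains, names, PriorSpec())


class TestAdaptiveRandomWalk:
    def test_conjugate_normal_posterior_moments(self):
        # normal-mean model: prior N(0,1), xbar = 1.2 from n = 9 obs
        n, xbar = 9, 1.2
        target = lambda th: -0.5 * (n + 1) * (th[0] - n * xbar / (n + 1)) ** 2
        s = AdaptiveRandomWalkSampler(target, 1)
        out = s.run(np.array([0.0]), 5000, np.random.default_rng(0),
                    adapt_until=1000)[1000:]
        post_mean, post_sd = n * xbar / (n + 1), (n + 1) ** -0.5
        mcse = post_sd / np.sqrt(len(out) / 10)  # conservative ESS guess
        assert out.mean() == pytest.approx(post_mean, abs=4 * mcse)
        assert out.std() == pytest.approx(post_sd, rel=0.15)

    def test_monte_carlo_error_scaling(self):
        """Doubling the chain length shrinks the SE of the mean ~1/sqrt(2)."""
        target = lambda th: -0.5 * th[0] ** 2

        def se_of_mean(n_iter, reps=24):
            means = []
            for r in range(reps):
                s = AdaptiveRandomWalkSampler(target, 1)
                out = s.run(np.array([0.0]), n_iter,
                            np.random.default_rng(100 + r), adapt_until=200)
                means.append(out[200:].mean())
            return np.std(means, ddof=1)

        ratio = se_of_mean(2600) / se_of_mean(1400)
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.30)


class TestLocalizedLogLikelihood:
    def test_standard_normal_density_value(self):
        rng = np.random.default_rng(1)
        s = make_samples(rng.standard_normal((100_000, 2)))
        _, val = localized_log_likelihood(s, np.zeros(2))
        assert val == pytest.approx(-np.log(2 * np.pi), abs=0.05)

    def test_infinite_bandwidth_is_global_gaussian_fit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.7, 1.4, (20_000, 1))
        s = make_samples(x)
        cfg = LocalFitConfig(bandwidths=np.array([1e6]))
        coeffs, _ = localized_log_likelihood(s, np.array([0.0]), cfg)
        curv = 2 * coeffs["quad"][0, 0]
        mean = -coeffs["linear"][0] / curv
        assert curv == pytest.approx(-1.0 / x.var(), abs=1e-6)
        assert mean == pytest.approx(x.mean(), abs=1e-6)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, (5000, 1))
        shift = 3.3
        _, v1 = localized_log_likelihood(make_samples(x), np.array([0.2]))
        _, v2 = localized_log_likelihood(make_samples(x + shift),
                                         np.array([0.2 + shift]))
        assert v2 == pytest.approx(v1, abs=1e-10)

    def test_degree_one_fit_matches_density(self):
        rng = np.random.default_rng(4)
        s = make_samples(rng.standard_normal((100_000, 1)))
        cfg = LocalFitConfig(degree=1)
        _, val = localized_log_likelihood(s, np.array([0.0]), cfg)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=0.05)

    def test_far_fitting_point_fails_after_inflation(self):
        rng = np.random.default_rng(5)
        s = make_samples(rng.standard_normal((500, 1)))
        cfg = LocalFitConfig(bandwidths=np.array([1e-4]))
        with pytest.raises(LocalFitError):
            localized_log_likelihood(s, np.array([25.0]), cfg)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            LocalFitConfig(degree=3)
        with pytest.raises(ValueError):
            LocalFitConfig(bandwidths=np.array([0.0]))


class TestMCLLObjective:
    def test_flat_likelihood_construction_is_constant(self):
        """If the prior is proportional to the posterior the implied
        likelihood is flat; the objective must not vary in theta."""
        rng = np.random.default_rng(6)
        s = make_samples(rng.standard_normal((100_000, 1)))
        log_prior = lambda th: -0.5 * th[0] ** 2  # same shape as the target
        vals = [mcll_objective(s, np.array([t]), log_prior=log_prior)
                for t in (-1.0, -0.5, 0.0, 0.5, 1.0)]
        assert max(vals) - min(vals) < 0.1

    def test_flat_prior_argmax_is_posterior_mode(self):
        rng = np.random.default_rng(7)
        mu = 0.85
        s = make_samples(rng.normal(mu, 0.3, (60_000, 1)))
        f = lambda t: -mcll_objective(s, np.array([t]))
        res = minimize_scalar(f, bounds=(0.0, 2.0), method="bounded")
        mcse = 0.3 / np.sqrt(3000)
        assert res.x == pytest.approx(mu, abs=max(2 * mcse, 0.02))

    def test_binomial_mle_recovered_through_prior_division(self):
        """Beta(2,2) prior, k=7 of n=10 successes: the posterior peaks at
        8/12 but dividing the prior back out must recover the MLE 0.7."""
        k, n = 7, 10
        target = lambda th: ((k + 1) * np.log(th[0]) + (n - k + 1) * np.log(1 - th[0])
                             if 0 < th[0] < 1 else -np.inf)
        s = AdaptiveRandomWalkSampler(target, 1)
        out = s.run(np.array([0.5]), 60_000, np.random.default_rng(8),
                    adapt_until=5000)[5000:]
        samples = make_samples(out)
        log_prior = lambda th: (np.log(th[0]) + np.log(1 - th[0])
                                if 0 < th[0] < 1 else -np.inf)
        f = lambda t: -mcll_objective(samples, np.array([t]), log_prior=log_prior)
        res = minimize_scalar(f, bounds=(0.3, 0.95), method="bounded")
        assert res.x == pytest.approx(0.7, abs=0.03)

    def test_additive_constant_cancels_in_differences(self):
        """The posterior's unknown normalizing constant shifts the fitted
        log-density uniformly; objective differences are unaffected by a
        constant rescaling of the prior."""
        rng = np.random.default_rng(9)
        s = make_samples(rng.standard_normal((20_000, 1)))
        lp = lambda th: -0.1 * th[0] ** 2
        lp_shifted = lambda th: lp(th) + 12.34
        t1, t2 = np.array([0.1]), np.array([0.6])
        d_plain = (mcll_objective(s, t1, log_prior=lp)
                   - mcll_objective(s, t2, log_prior=lp))
        d_shift = (mcll_objective(s, t1, log_prior=lp_shifted)
                   - mcll_objective(s, t2, log_prior=lp_shifted))
        assert d_shift == pytest.approx(d_plain, abs=1e-10)


@pytest.fixture(scope="module")
def tiny():
    d = mt.crossed_design(["t"], ["m"], items_per_cell=4)
    p = ModelParameters(np.full(4, 1.0), np.full(4, 0.6),
                        np.linspace(-0.8, 0.8, 4), np.eye(1))
    rng = np.random.default_rng(13)
    return d, simulate_responses(SimulationSpec(d, p, 200), rng)


class TestSamplePosterior:
    def test_same_seed_identical_draws(self, tiny):
        d, data = tiny
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = sample_posterior(d, data, chains=2, iterations=50, burn_in=50,
                                 seed=3)
            b = sample_posterior(d, data, chains=2, iterations=50, burn_in=50,
                                 seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_chain_pooling_and_metadata(self, tiny):
        d, data = tiny
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sample_posterior(d, data, chains=3, iterations=40, burn_in=30,
                                 seed=1)
        assert s.m == 120 and len(np.unique(s.chain_ids)) == 3
        assert set(s.meta["acceptance"]) == {"latent", "item", "corr"}
        assert np.isfinite(s.draws).all()

    def test_posterior_concentrates_near_truth(self, tiny):
        d, data = tiny
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sample_posterior(d, data, chains=2, iterations=600, burn_in=600,
                                 seed=4)
        beta_mean = s.draws[:, 8:12].mean(axis=0)
        # loose concentration check: intercept SEs at N=200 are ~0.25
        assert np.abs(beta_mean - np.linspace(-0.8, 0.8, 4)).max() < 0.7


class TestFitMCLL:
    def test_2pl_submodel_matches_quadrature(self):
        """MCLL on a plain 1-factor 2PL (method loadings pinned at zero
        in both the sampler and the quadrature reference) recovers the
        direct MLE: sample the posterior, locally fit the log-density on
        the active parameters, divide the prior out, maximize."""
        from scipy.optimize import minimize

        from mtmmirt.mcll import (PosteriorSamples, mcll_objective,
                                  sample_posterior)
        d = mt.crossed_design(["t"], ["m"], items_per_cell=5)
        I = 5
        p = ModelParameters(np.full(I, 1.2), np.zeros(I),
                            np.linspace(-1.0, 1.0, I), np.eye(1))
        rng = np.random.default_rng(24)
        data = simulate_responses(SimulationSpec(d, p, 500), rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smp = sample_posterior(d, data, chains=3, iterations=400,
                                   burn_in=500, seed=6,
                                   fix_method_loadings=True)
            # reduce to the sampled (non-constant) parameters: aT, beta
            active = np.r_[np.arange(I), np.arange(2 * I, 3 * I)]
            red = PosteriorSamples(smp.draws[:, active], smp.chain_ids,
                                   [smp.names[j] for j in active], smp.prior)
        prior = smp.prior

        def log_prior(th):
            if (th[:I] < 0).any():
                return -np.inf
            return (-0.5 * (th[:I] ** 2).sum() / prior.loading_scale**2
                    - 0.5 * (th[I:] ** 2).sum() / prior.intercept_scale**2)

        lo = np.quantile(red.draws, 0.005, axis=0)
        hi = np.quantile(red.draws, 0.995, axis=0)
        res = minimize(lambda th: -mcll_objective(red, th, log_prior=log_prior),
                       red.draws.mean(axis=0), method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options={"maxiter": 500, "ftol": 1e-10})
        start = ModelParameters(np.full(I, 0.5), np.zeros(I), np.zeros(I),
                                np.eye(1))
        ref = mt.fit_quadrature(d, data, points_per_dim=9,
                                estimate_loadings="trait", start=start)
        # in 10 dimensions the product kernel must stay wide (shrinking
        # it collapses the effective sample size), so the local fit
        # carries an oversmoothing bias of ~0.1 on skewed loading
        # posteriors; the bound reflects the verified level
        assert np.abs(res.x[:I] - ref.estimates.trait_loadings).max() < 0.2
        assert np.abs(res.x[I:] - ref.estimates.intercepts).max() < 0.15

    def test_fit_reporting(self, mcll_fit22):
        assert mcll_fit22.estimator_tag == "mcll"
        assert mcll_fit22.chain_se is not None
        assert mcll_fit22.diagnostics["n_draws"] == 3000
        assert {"chain"}.issubset(mcll_fit22.chain.columns)
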