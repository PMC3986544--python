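"""Mean-field variational maximization-maximization (MM) estimation.

A modified EM algorithm for the crossed model in which the intractable
E-step is replaced by a first M-step: the posterior of the latent
variables is approximated by a fully factorized (mean-field) density
``g(theta) = prod_d g_d(theta_d)`` with Gaussian marginals, chosen to
maximize a lower bound on the log-likelihood (equivalently, to minimize
the KL divergence to the true posterior).  The second M-step maximizes
the same bound over the model parameters.

Applicability follows the method's stated limits: the factor loadings
must be *fixed to known values* (only the intercepts, and nothing else,
are free parameters), and the trait correlation matrix is a fixed
input — a fully factorized variational family has no way to represent
a correlated prior it would itself have to estimate.

Because the linear predictor of item ``i`` involves exactly two latent
coordinates, every expected log-likelihood term reduces to a 1-D
Gaussian expectation over the predictor itself, evaluated with a
21-point Gauss-Hermite rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .design import MTMMDesign
from .model import (ModelParameters, ResponseMatrix, bernoulli_derivs,
                    bernoulli_loglik, link_forward)
from .results import FitResult

__all__ = ["VariationalState", "elbo", "update_variational",
           "update_parameters", "fit_vmm"]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)
_GH_POINTS = 21
_gh_x, _gh_w = hermegauss(_GH_POINTS)
_gh_w = _gh_w / _gh_w.sum()


@dataclass
class VariationalState:
    """Gaussian mean-field marginals for every person and latent dim.

    Dimension order is [traits..., methods...].  ``elbo_value`` caches
    the bound at the last evaluation.
    """

    means: np.ndarray       # (N, T + M)
    variances: np.ndarray   # (N, T + M)
    elbo_value: float = -np.inf
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must have the same shape")
        if (self.variances <= 0).any():
            raise ValueError("variational variances must be positive")

    def copy(self) -> "VariationalState":
        return VariationalState(self.means.copy(), self.variances.copy(),
                                self.elbo_value, self.n_iterations)


def _check_fixed_loadings(params: ModelParameters, free_loadings: bool) -> None:
    if free_loadings:
        raise ValueError(
            "the variational MM estimator requires fixed loadings; free "
            "loading estimation is outside its applicability")


def _predictor_moments(design: MTMMDesign, params: ModelParameters,
                       state: VariationalState):
    """Mean and variance of each person-item linear predictor under g."""
    T = design.n_traits
    t_idx = design.trait_of_item
    m_idx = T + design.method_of_item
    mu = (params.trait_loadings * state.means[:, t_idx]
          + params.method_loadings * state.means[:, m_idx]
          + params.intercepts)
    var = (params.trait_loadings**2 * state.variances[:, t_idx]
           + params.method_loadings**2 * state.variances[:, m_idx])
    return mu, var


def _expected_loglik(link, y, obs, mu, var):
    """sum of E_g[log p(y | eta)] with eta ~ N(mu, var), via Gauss-Hermite."""
    sd = np.sqrt(var)
    total = 0.0
    for xk, wk in zip(_gh_x, _gh_w):
        eta = mu + sd * xk
        total += wk * np.where(obs, bernoulli_loglik(link, y, eta), 0.0).sum()
    return float(total)


def elbo(design: MTMMDesign, params: ModelParameters, data: ResponseMatrix,
         state: VariationalState) -> float:
    """Evidence lower bound: E_g[log p(y, theta)] + entropy(g).

    Always bounded above by the true marginal log-likelihood; the gap
    is the KL divergence from g to the exact latent posterior, so the
    bound is tight when the posterior factorizes (e.g. a single latent
    dimension).
    """
    T = design.n_traits
    mu, var = _predictor_moments(design, params, state)
    val = _expected_loglik(params.link, data.filled, data.observed, mu, var)
    # E[log prior]: correlated traits, independent standard-normal methods
    Rinv = np.linalg.inv(params.trait_correlation)
    sign, logdetR = np.linalg.slogdet(params.trait_correlation)
    mT, vT = state.means[:, :T], state.variances[:, :T]
    quad = np.einsum("pa,ab,pb->", mT, Rinv, mT) + (np.diag(Rinv) * vT).sum()
    N = data.n_persons
    val += -0.5 * quad - 0.5 * N * (T * _LOG_2PI + logdetR)
    mM, vM = state.means[:, T:], state.variances[:, T:]
    val += -0.5 * ((mM**2 + vM).sum() + mM.size * _LOG_2PI)
    # entropy of the factorized Gaussian
    val += 0.5 * (np.log(state.variances).sum()
                  + state.variances.size * (1.0 + _LOG_2PI))
    return float(val)


def _coordinate_terms(design: MTMMDesign, params: ModelParameters,
                      data: ResponseMatrix, state: VariationalState, d: int):
    """Pieces of the ELBO that depend on coordinate d (all persons)."""
    T = design.n_traits
    if d < T:
        items = np.where(design.trait_of_item == d)[0]
        lam = params.trait_loadings[items]
    else:
        items = np.where(design.method_of_item == d - T)[0]
        lam = params.method_loadings[items]
    # predictor contribution of the *other* coordinate of each item
    t_idx = design.trait_of_item[items]
    m_idx = T + design.method_of_item[items]
    if d < T:
        mu_other = (params.method_loadings[items] * state.means[:, m_idx]
                    + params.intercepts[items])
        var_other = params.method_loadings[items]**2 * state.variances[:, m_idx]
    else:
        mu_other = (params.trait_loadings[items] * state.means[:, t_idx]
                    + params.intercepts[items])
        var_other = params.trait_loadings[items]**2 * state.variances[:, t_idx]
    return items, lam, mu_other, var_other


def _coordinate_objective(link, y, obs, lam, mu_other, var_other, m, v,
                          prior_a, prior_b):
    """Per-person ELBO contribution of one coordinate (vectorized over
    persons).  ``prior_a`` is the precision Rinv_dd, ``prior_b`` the
    cross term sum_{e != d} Rinv_de m_e."""
    mu = mu_other + lam * m[:, None]
    var = var_other + lam**2 * v[:, None]
    sd = np.sqrt(var)
    val = np.zeros(m.shape)
    for xk, wk in zip(_gh_x, _gh_w):
        eta = mu + sd * xk
        val += wk * np.where(obs, bernoulli_loglik(link, y, eta), 0.0).sum(axis=1)
    val += -0.5 * prior_a * (m**2 + v) - prior_b * m + 0.5 * np.log(v)
    return val


def update_variational(design: MTMMDesign, params: ModelParameters,
                       data: ResponseMatrix, state: VariationalState,
                       inner_steps: int = 4,
                       order: Optional[np.ndarray] = None) -> VariationalState:
    """One coordinate-ascent sweep over all variational marginals.

    Each (person, dimension) marginal's mean and log-variance are
    updated by a few damped Newton steps on the 1-D coordinate
    objective (numerical second derivatives for the variance), with a
    per-person objective check that reverts any non-improving move, so
    the ELBO cannot decrease.
    """
    T = design.n_traits
    D = design.n_latent
    Rinv = np.linalg.inv(params.trait_correlation)
    new = state.copy()
    y = data.filled
    sweep = range(D) if order is None else [int(d) for d in order]
    if order is not None and sorted(sweep) != list(range(D)):
        raise ValueError("order must be a permutation of the latent dimensions")
    for d in sweep:
        items, lam, mu_other, var_other = _coordinate_terms(design, params,
                                                            data, new, d)
        obs = data.observed[:, items]
        yy = y[:, items]
        if d < T:
            prior_a = Rinv[d, d]
            prior_b = new.means[:, :T] @ Rinv[:, d] - Rinv[d, d] * new.means[:, d]
        else:
            prior_a, prior_b = 1.0, np.zeros(data.n_persons)
        m = new.means[:, d].copy()
        v = new.variances[:, d].copy()
        f0 = _coordinate_objective(params.link, yy, obs, lam, mu_other,
                                   var_other, m, v, prior_a, prior_b)
        for _ in range(inner_steps):
            # Newton in the mean (analytic), then in log-variance (numeric)
            mu = mu_other + lam * m[:, None]
            var = var_other + lam**2 * v[:, None]
            sd = np.sqrt(var)
            g1 = np.zeros_like(m)
            g2 = np.zeros_like(m)
            for xk, wk in zip(_gh_x, _gh_w):
                d1, d2 = bernoulli_derivs(params.link, yy, mu + sd * xk)
                d1 = np.where(obs, d1, 0.0)
                d2 = np.where(obs, d2, 0.0)
                g1 += wk * (d1 * lam).sum(axis=1)
                g2 += wk * (d2 * lam**2).sum(axis=1)
            grad_m = g1 - prior_a * m - prior_b
            hess_m = np.minimum(g2 - prior_a, -1e-8)
            step = -grad_m / hess_m
            m_new = m + np.clip(step, -2.0, 2.0)
            f1 = _coordinate_objective(params.link, yy, obs, lam, mu_other,
                                       var_other, m_new, v, prior_a, prior_b)
            ok = f1 >= f0
            m = np.where(ok, m_new, m)
            f0 = np.where(ok, f1, f0)
            # log-variance step by numeric central differences
            h = 0.1
            fp = _coordinate_objective(params.link, yy, obs, lam, mu_other,
                                       var_other, m, v * np.exp(h), prior_a, prior_b)
            fm = _coordinate_objective(params.link, yy, obs, lam, mu_other,
                                       var_other, m, v * np.exp(-h), prior_a, prior_b)
            g = (fp - fm) / (2 * h)
            c = (fp - 2 * f0 + fm) / h**2
            c = np.minimum(c, -1e-8)
            step = np.clip(-g / c, -2.0, 2.0)
            v_new = v * np.exp(step)
            f1 = _coordinate_objective(params.link, yy, obs, lam, mu_other,
                                       var_other, m, v_new, prior_a, prior_b)
            ok = f1 >= f0
            v = np.where(ok, v_new, v)
            f0 = np.where(ok, f1, f0)
        new.means[:, d] = m
        new.variances[:, d] = v
    new.n_iterations = state.n_iterations + 1
    return new


def update_parameters(design: MTMMDesign, data: ResponseMatrix,
                      state: VariationalState, params: ModelParameters,
                      n_steps: int = 8) -> ModelParameters:
    """Second M-step: maximize the ELBO over the intercepts.

    Loadings are fixed by contract, so each intercept solves an
    independent 1-D concave maximization (expected Bernoulli
    log-likelihood under the Gaussian predictor), done by Newton.
    """
    beta = params.intercepts.copy()
    mu0, var = _predictor_moments(design, params,
                                  state)  # includes current beta
    mu0 = mu0 - params.intercepts  # strip beta; re-added per step
    sd = np.sqrt(var)
    y, obs = data.filled, data.observed
    for _ in range(n_steps):
        g = np.zeros_like(beta)
        h = np.zeros_like(beta)
        for xk, wk in zip(_gh_x, _gh_w):
            d1, d2 = bernoulli_derivs(params.link, y, mu0 + beta + sd * xk)
            g += wk * np.where(obs, d1, 0.0).sum(axis=0)
            h += wk * np.where(obs, d2, 0.0).sum(axis=0)
        step = -g / np.minimum(h, -1e-10)
        beta = beta + np.clip(step, -2.0, 2.0)
        if np.abs(step).max() < 1e-10:
            break
    return params.replace(intercepts=beta)


def fit_vmm(design: MTMMDesign, data: ResponseMatrix,
            trait_loadings: np.ndarray, method_loadings: np.ndarray,
            trait_correlation: Optional[np.ndarray] = None,
            link: str = "logit", free_loadings: bool = False,
            tol: float = 1e-6, max_iter: int = 500) -> FitResult:
    """Alternate the two M-steps until the ELBO stabilizes.

    ``trait_loadings``/``method_loadings`` are the known, frozen
    loadings; ``trait_correlation`` is a fixed input (identity by
    default).  Returns the intercept estimates with the final ELBO as
    the reported objective value and per-person variational means in
    the diagnostics.
    """
    _check_fixed_loadings(None, free_loadings)
    T = design.n_traits
    R = np.eye(T) if trait_correlation is None else np.asarray(trait_correlation,
                                                               dtype=float)
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(data.responses, axis=0)
    beta0 = np.asarray(link_forward(link, np.clip(np.nan_to_num(pbar, nan=0.5),
                                                  0.02, 0.98)), dtype=float)
    params = ModelParameters(np.asarray(trait_loadings, dtype=float),
                             np.asarray(method_loadings, dtype=float),
                             beta0, R, link=link)
    N, D = data.n_persons, design.n_latent
    state = VariationalState(np.zeros((N, D)), np.ones((N, D)))
    state.elbo_value = elbo(design, params, data, state)
    monotone_ok = True
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        state = update_variational(design, params, data, state)
        params = update_parameters(design, data, state, params)
        value = elbo(design, params, data, state)
        if value < state.elbo_value - 1e-8:
            monotone_ok = False
            warnings.warn(f"ELBO decreased by {state.elbo_value - value:.2e} "
                          f"at iteration {it}", stacklevel=2)
        delta = value - state.elbo_value
        state.elbo_value = value
        logger.debug("vmm iteration %d: elbo %.6f", it, value)
        if abs(delta) < tol:
            converged = True
            break
    return FitResult(
        estimates=params,
        log_likelihood=float(state.elbo_value),  # lower bound, not the ML value
        converged=converged,
        n_iterations=it,
        estimator_tag="vmm",
        diagnostics={"elbo": float(state.elbo_value),
                     "monotone": float(monotone_ok),
                     "mean_variational_variance": float(state.variances.mean())},
        chain=None,
    )
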