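"""Marginal maximum likelihood by tensor-product Gauss-Hermite quadrature.

The observed-data likelihood of the crossed trait/method model
integrates the conditional response probabilities over all T + M latent
dimensions.  This module evaluates that integral on a tensor product of
probabilists' Gauss-Hermite rules (exact for polynomials of degree
2k - 1 per dimension against the standard normal) and maximizes it by
quasi-Newton.  The node count grows as ``points_per_dim ** (T + M)``,
which is exactly why this estimator is an *oracle for small models*
rather than a general-purpose tool: an 8-point rule over six latent
dimensions already needs 262,144 evaluations per likelihood call.

Correlated traits are handled by pre-multiplying the trait block of the
(standard-normal) nodes by the Cholesky factor of the trait correlation
matrix, so the grid itself always lives in an uncorrelated standard
space.  Optionally the grid is adapted per person: recentered at the
posterior mode of the latent vector and rescaled by the curvature
there, which concentrates the nodes where the integrand has mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from .design import MTMMDesign
from .model import (ModelParameters, ResponseMatrix, bernoulli_derivs,
                    bernoulli_loglik, link_forward)
from .results import FitResult
from .transforms import corr_matrix, unconstrain_corr

__all__ = [
    "CapacityError",
    "QuadratureGrid",
    "build_grid",
    "person_posterior_mode",
    "marginal_log_likelihood",
    "fit_quadrature",
]

DEFAULT_NODE_BUDGET = 10_000_000
_LOG_2PI = math.log(2.0 * math.pi)


class CapacityError(RuntimeError):
    """Raised when a requested grid exceeds the node budget."""


@dataclass
class QuadratureGrid:
    """Tensor-product Gauss-Hermite grid on the standard-normal scale.

    ``nodes`` is (K, n_dims) with K = points_per_dim ** n_dims and
    ``log_weights`` sums (in probability) to 1 for the unadapted grid.
    When ``adapted`` the grid is understood relative to per-person
    centers/scales stored alongside.
    """

    nodes: np.ndarray
    log_weights: np.ndarray
    points_per_dim: int
    n_dims: int
    adapted: bool = False
    center: Optional[np.ndarray] = None  # (N, n_dims) posterior modes
    scale: Optional[np.ndarray] = None   # (N, n_dims, n_dims) Cholesky of inv curvature

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


def build_grid(points_per_dim: int, n_dims: int,
               node_budget: int = DEFAULT_NODE_BUDGET) -> QuadratureGrid:
    """Probabilists' Gauss-Hermite tensor grid over ``n_dims`` dimensions.

    Weights are normalized so that ``exp(log_weights)`` sums to 1 (the
    rule integrates against the standard normal density).  Refuses to
    build grids whose node count exceeds ``node_budget``.
    """
    if points_per_dim < 1 or n_dims < 1:
        raise ValueError("points_per_dim and n_dims must be positive")
    count = float(points_per_dim) ** n_dims
    if count > node_budget:
        raise CapacityError(
            f"grid of {points_per_dim}^{n_dims} = {points_per_dim ** n_dims:,} nodes "
            f"exceeds the node budget of {node_budget:,}")
    x, w = hermegauss(points_per_dim)
    logw1 = np.log(w) - 0.5 * _LOG_2PI  # normalize: sum w = sqrt(2*pi)
    K = points_per_dim ** n_dims
    idx = np.indices((points_per_dim,) * n_dims).reshape(n_dims, K).T
    nodes = x[idx]
    log_weights = logw1[idx].sum(axis=1)
    return QuadratureGrid(nodes, log_weights, points_per_dim, n_dims)


def _z_design_matrix(design: MTMMDesign, params: ModelParameters) -> np.ndarray:
    """Item-by-dimension loading matrix in the standardized node space.

    Dimension order is [traits..., methods...].  The trait block absorbs
    the Cholesky factor of the trait correlation so that nodes can stay
    standard normal: eta = A z + beta.
    """
    I, T, M = design.n_items, design.n_traits, design.n_methods
    L = np.linalg.cholesky(params.trait_correlation)
    A = np.zeros((I, T + M))
    A[:, :T] = params.trait_loadings[:, None] * L[design.trait_of_item, :]
    A[np.arange(I), T + design.method_of_item] = params.method_loadings
    return A


def _batch_posterior_modes(A: np.ndarray, y: np.ndarray, obs: np.ndarray,
                           offsets: Optional[np.ndarray], link: str,
                           max_iter: int = 100, tol: float = 1e-8):
    """Newton ascent to the latent posterior mode for every person at once.

    The prior over the standardized latent vector z is N(0, I); the
    posterior mode maximizes sum_i obs * log p(y_i | eta_i(z)) - z'z/2.
    Returns (modes (N, D), curvatures (N, D, D), failed mask).  Persons
    whose Newton iteration fails fall back to mode 0 / identity
    curvature and are flagged.
    """
    N, I = y.shape
    D = A.shape[1]
    Z = np.zeros((N, D))
    off = np.zeros((N, I)) if offsets is None else offsets
    eye = np.eye(D)

    def logpost(Zc):
        eta = Zc @ A.T + off
        ll = np.where(obs, bernoulli_loglik(link, y, eta), 0.0).sum(axis=1)
        return ll - 0.5 * (Zc**2).sum(axis=1)

    lp = logpost(Z)
    converged = np.zeros(N, dtype=bool)
    for _ in range(max_iter):
        eta = Z @ A.T + off
        d1, d2 = bernoulli_derivs(link, y, eta)
        d1 = np.where(obs, d1, 0.0)
        d2 = np.where(obs, d2, 0.0)
        G = d1 @ A - Z
        gmax = np.abs(G).max(axis=1)
        converged = gmax < tol
        if converged.all():
            break
        H = -np.einsum("pi,ia,ib->pab", d2, A, A) + eye  # negative Hessian, PD
        step = np.linalg.solve(H, G[..., None])[..., 0]
        # backtracking line search, vectorized over persons
        scale = np.ones(N)
        improved = np.zeros(N, dtype=bool)
        Znew = Z.copy()
        for _ in range(20):
            trial = Z + scale[:, None] * step
            lpt = logpost(trial)
            better = (lpt >= lp - 1e-12) & ~improved & ~converged
            Znew[better] = trial[better]
            lp = np.where(better, lpt, lp)
            improved |= better
            scale = np.where(improved | converged, scale, scale * 0.5)
            if (improved | converged).all():
                break
        Z = Znew
    failed = ~converged
    if failed.any():
        Z[failed] = 0.0
    eta = Z @ A.T + off
    _, d2 = bernoulli_derivs(link, y, eta)
    d2 = np.where(obs, d2, 0.0)
    H = -np.einsum("pi,ia,ib->pab", d2, A, A) + eye
    H[failed] = eye
    return Z, H, failed


def person_posterior_mode(design: MTMMDesign, params: ModelParameters,
                          responses: np.ndarray, max_iter: int = 100):
    """Posterior mode and curvature of one person's latent vector.

    The mode maximizes ``log p(y | z) + log phi(z)`` in the standardized
    space (trait correlation absorbed into the loadings); the curvature
    is the negative Hessian there.  With all loadings zero this is the
    prior: mode 0, curvature identity.
    """
    y = np.asarray(responses, dtype=float).reshape(1, -1)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("at least one observed response is required")
    A = _z_design_matrix(design, params)
    yf = np.nan_to_num(y, nan=0.0)
    off = np.broadcast_to(params.intercepts, y.shape).copy()
    mode, curv, failed = _batch_posterior_modes(A, yf, obs, off, params.link,
                                                max_iter=max_iter)
    if failed[0]:
        warnings.warn("posterior mode search did not converge; falling back to "
                      "the prior mode", stacklevel=2)
    return mode[0], curv[0]


def _log_joint_at_nodes(A, beta, y, obs, nodes, link):
    """Per-person, per-node conditional log-likelihood sums."""
    eta = nodes @ A.T + beta  # (K, I)
    l1 = bernoulli_loglik(link, 1.0, eta)
    l0 = bernoulli_loglik(link, 0.0, eta)
    return (obs * y) @ l1.T + (obs * (1.0 - y)) @ l0.T  # (N, K)


def marginal_log_likelihood(design: MTMMDesign, params: ModelParameters,
                            data: ResponseMatrix, points_per_dim: int = 7,
                            adaptive: bool = False,
                            node_budget: int = DEFAULT_NODE_BUDGET,
                            return_per_person: bool = False):
    """Observed-data log-likelihood via (optionally adaptive) quadrature.

    Sums, over persons, the log of the weighted node-sum of the joint
    conditional probability of the person's responses.  Deterministic
    for a fixed grid.  Underflow is guarded by log-sum-exp throughout.
    """
    D = design.n_latent
    grid = build_grid(points_per_dim, D, node_budget=node_budget)
    A = _z_design_matrix(design, params)
    y, obs = data.filled, data.observed
    beta = params.intercepts
    if not adaptive:
        N = data.n_persons
        K = grid.n_nodes
        chunk = max(1, int(4_000_000 // max(N, 1)))
        parts = []
        for s in range(0, K, chunk):
            nodes = grid.nodes[s:s + chunk]
            S = _log_joint_at_nodes(A, beta, y, obs, nodes, params.link)
            parts.append(logsumexp(S + grid.log_weights[s:s + chunk], axis=1))
        llp = logsumexp(np.column_stack(parts), axis=1) if len(parts) > 1 else parts[0]
    else:
        llp = _adaptive_loglik(A, beta, y, obs, grid, params.link)
    if not np.isfinite(llp).all():
        raise FloatingPointError("non-finite person log-likelihood contribution")
    if return_per_person:
        return llp
    return float(llp.sum())


def _adaptive_loglik(A, beta, y, obs, grid, link, offsets=None):
    """Adapted-grid person log-likelihoods (grid recentered per person)."""
    N, I = y.shape
    D = A.shape[1]
    off = np.broadcast_to(beta, (N, I)) if offsets is None else offsets + beta
    modes, curv, _ = _batch_posterior_modes(A, y, obs, off, link)
    # Cholesky of inverse curvature gives the per-person rescaling
    Lc = np.linalg.cholesky(np.linalg.inv(curv))
    logdet = np.log(np.einsum("pii->pi", Lc)).sum(axis=1)
    z = grid.nodes  # (K, D)
    K = z.shape[0]
    log_phi_z = -0.5 * (z**2).sum(axis=1) - 0.5 * D * _LOG_2PI
    llp = np.empty(N)
    chunk = max(1, int(4_000_000 // max(K * I, 1)))
    for s in range(0, N, chunk):
        e = min(N, s + chunk)
        zeta = modes[s:e, None, :] + np.einsum("kd,ped->pke", z, Lc[s:e])  # (B,K,D)
        eta = np.einsum("pkd,id->pki", zeta, A) + off[s:e, None, :]
        ll = np.where(obs[s:e, None, :],
                      bernoulli_loglik(link, y[s:e, None, :], eta), 0.0).sum(axis=2)
        log_phi_zeta = -0.5 * (zeta**2).sum(axis=2) - 0.5 * D * _LOG_2PI
        S = ll + log_phi_zeta + logdet[s:e, None] - log_phi_z + grid.log_weights
        llp[s:e] = logsumexp(S, axis=1)
    return llp


# ---------------------------------------------------------------------------
# Maximization


def _unpack(u, design, estimate_correlation):
    I, T = design.n_items, design.n_traits
    q = T * (T - 1) // 2 if estimate_correlation else 0
    tl = np.abs(u[:I])
    ml = np.abs(u[I:2 * I])
    beta = u[2 * I:3 * I]
    ycorr = u[3 * I:3 * I + q]
    R = corr_matrix(ycorr, T) if q else np.eye(T)
    return tl, ml, beta, ycorr, R


def _fast_value(u, design, data, link, grid, estimate_correlation):
    tl, ml, beta, _, R = _unpack(u, design, estimate_correlation)
    params = ModelParameters(tl, ml, beta, R, link=link)
    A = _z_design_matrix(design, params)
    S = _log_joint_at_nodes(A, beta, data.filled, data.observed, grid.nodes, link)
    return logsumexp(S + grid.log_weights, axis=1).sum()


def _fast_value_and_grad(u, design, data, link, grid, estimate_correlation,
                         corr_step=1e-5):
    """Log-likelihood and gradient on the unadapted grid.

    Loading/intercept gradients use the posterior-weight identity
    d loglik_p / d psi = E_post[d log p(y_p | z) / d psi]; the few
    correlation parameters are differenced numerically.
    """
    I, T = design.n_items, design.n_traits
    tl, ml, beta, ycorr, R = _unpack(u, design, estimate_correlation)
    params = ModelParameters(tl, ml, beta, R, link=link)
    A = _z_design_matrix(design, params)
    y, obs = data.filled, data.observed
    eta = grid.nodes @ A.T + beta  # (K, I)
    l1 = bernoulli_loglik(link, 1.0, eta)
    l0 = bernoulli_loglik(link, 0.0, eta)
    Y1 = obs * y
    Y0 = obs * (1.0 - y)
    Sw = Y1 @ l1.T + Y0 @ l0.T + grid.log_weights  # (N, K)
    llp = logsumexp(Sw, axis=1)
    r = np.exp(Sw - llp[:, None])  # posterior node weights per person
    d11, _ = bernoulli_derivs(link, 1.0, eta)
    d10, _ = bernoulli_derivs(link, 0.0, eta)
    R1 = r.T @ Y1  # (K, I)
    R0 = r.T @ Y0
    G = R1 * d11 + R0 * d10
    dbeta = G.sum(axis=0)
    L = np.linalg.cholesky(params.trait_correlation)
    thetaT = grid.nodes[:, :T] @ L.T  # (K, T) correlated trait coordinates
    dtl = (G * thetaT[:, design.trait_of_item]).sum(axis=0)
    dml = (G * grid.nodes[:, T + design.method_of_item]).sum(axis=0)
    grad = np.concatenate([
        dtl * np.sign(u[:I]),
        dml * np.sign(u[I:2 * I]),
        dbeta,
    ])
    if estimate_correlation and ycorr.size:
        gcorr = np.empty(ycorr.size)
        for j in range(ycorr.size):
            up = u.copy(); up[3 * I + j] += corr_step
            um = u.copy(); um[3 * I + j] -= corr_step
            fp = _fast_value(up, design, data, link, grid, estimate_correlation)
            fm = _fast_value(um, design, data, link, grid, estimate_correlation)
            gcorr[j] = (fp - fm) / (2 * corr_step)
        grad = np.concatenate([grad, gcorr])
    return float(llp.sum()), grad


def starting_values(design: MTMMDesign, data: ResponseMatrix,
                    link: str = "logit") -> ModelParameters:
    """Conventional starts: intercepts from marginal item means through
    the link, loadings 0.5, trait correlations 0."""
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(data.responses, axis=0)
    pbar = np.clip(np.nan_to_num(pbar, nan=0.5), 0.02, 0.98)
    beta = np.asarray(link_forward(link, pbar), dtype=float)
    half = np.full(design.n_items, 0.5)
    return ModelParameters(half, half, beta, np.eye(design.n_traits), link=link)


def fit_quadrature(design: MTMMDesign, data: ResponseMatrix,
                   link: str = "logit", points_per_dim: int = 7,
                   adaptive: bool = False, estimate_correlation: bool = True,
                   estimate_loadings: bool = True,
                   start: Optional[ModelParameters] = None,
                   gtol: float = 1e-5, max_iter: int = 500,
                   node_budget: int = DEFAULT_NODE_BUDGET) -> FitResult:
    """Maximize the quadrature marginal likelihood over all parameters.

    Works on an unconstrained parameterization: loadings through an
    absolute-value map (nonnegative by convention), trait correlations
    through tanh-transformed canonical partial correlations of the
    Cholesky factor.  Gradients are analytic for loadings/intercepts on
    the fixed grid and numerically differenced for the correlation
    block (and for the adaptive grid).
    """
    if data.n_items != design.n_items:
        raise ValueError("data and design disagree on the number of items")
    D = design.n_latent
    grid = build_grid(points_per_dim, D, node_budget=node_budget)
    est_corr = estimate_correlation and design.n_traits > 1
    I, T = design.n_items, design.n_traits
    q = T * (T - 1) // 2 if est_corr else 0
    if start is None:
        start = starting_values(design, data, link)
    # estimate_loadings: True (both blocks free), False (both frozen at the
    # start values), "trait" or "method" (only that block free)
    free_trait = estimate_loadings in (True, "trait")
    free_method = estimate_loadings in (True, "method")
    u0_full = np.concatenate([
        np.maximum(start.trait_loadings, 1e-3) if free_trait
        else start.trait_loadings,
        np.maximum(start.method_loadings, 1e-3) if free_method
        else start.method_loadings,
        start.intercepts,
        unconstrain_corr(start.trait_correlation) if q else np.empty(0),
    ])
    free = np.ones(u0_full.size, dtype=bool)
    free[:I] = free_trait
    free[I:2 * I] = free_method
    u_fixed = u0_full.copy()

    def embed(uf):
        u = u_fixed.copy()
        u[free] = uf
        return u

    if adaptive:
        def negloglik(uf):
            tl, ml, beta, _, R = _unpack(embed(uf), design, est_corr)
            params = ModelParameters(tl, ml, beta, R, link=link)
            A = _z_design_matrix(design, params)
            llp = _adaptive_loglik(A, beta, data.filled, data.observed, grid, link)
            return -llp.sum()
        res = minimize(negloglik, u0_full[free], method="L-BFGS-B",
                       options={"maxiter": max_iter, "gtol": gtol})
        grad_norm = float(np.abs(res.jac).max()) if res.jac is not None else np.nan
    else:
        def fun(uf):
            val, grad = _fast_value_and_grad(embed(uf), design, data, link,
                                             grid, est_corr)
            return -val, -grad[free]
        # wide box bounds: a numerical guard against likelihood ridges in
        # under-identified configurations, far outside any plausible value
        bounds_full = ([(-8.0, 8.0)] * (2 * I) + [(-12.0, 12.0)] * I
                       + [(-6.0, 6.0)] * q)
        bounds = [b for b, fr in zip(bounds_full, free) if fr]
        res = minimize(fun, u0_full[free], jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": max_iter, "gtol": gtol})
        grad_norm = float(np.abs(res.jac).max())

    tl, ml, beta, _, R = _unpack(embed(res.x), design, est_corr)
    estimates = ModelParameters(tl, ml, beta, R, link=link)
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        warnings.warn(f"quadrature optimizer did not converge: {res.message}",
                      stacklevel=2)
    return FitResult(
        estimates=estimates,
        log_likelihood=float(-res.fun),
        converged=converged,
        n_iterations=int(res.nit),
        estimator_tag="quadrature",
        diagnostics={"grad_inf_norm": grad_norm,
                     "n_function_evals": float(res.nfev),
                     "points_per_dim": float(points_per_dim),
                     "adaptive": float(adaptive)},
    )
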