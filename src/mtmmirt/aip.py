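"""Alternating imputation posterior (AIP) estimation.

AIP sidesteps the full (T + M)-dimensional integral by splitting the
random part of the crossed model into two *wings*: the trait wing
(terms ``aT_i * thetaT``) and the method wing (terms ``aM_i * thetaM``).
Each outer iteration visits both wings; within a wing the other wing's
contribution to the linear predictor is frozen at its current sampled
values and entered as a known per-person-item offset, so the wing only
ever fits a low-dimensional 2PL-type model by adaptive quadrature.

A wing visit consists of a P-step (fit the wing's item parameters by
adaptive-quadrature ML with the offset, yielding estimates and their
covariance) and an I-step (draw the item parameters from a normal
centered at those estimates, then draw each person's wing latent
variables from a normal approximation to their conditional posterior).
The post-burn-in parameter draws form a chain whose mean is the point
estimate.

Intercepts are estimated in the method wing only and frozen inside the
trait wing's offset.  Updating them in both wings (each wing refitting
the full 2PL) would let the two wings tug the intercepts back and
forth; single ownership keeps the alternation stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .design import MTMMDesign
from .model import (ModelParameters, ResponseMatrix, bernoulli_loglik,
                    parameter_names, params_to_vector)
from .quadrature import _batch_posterior_modes, build_grid, starting_values
from .results import FitResult
from .transforms import corr_matrix, unconstrain_corr

__all__ = ["Wing", "partition_wings", "fit_wing_2pl", "draw_item_parameters",
           "draw_person_effects", "run_aip"]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)
DEFAULT_WING_DIM_CAP = 4


@dataclass
class Wing:
    """One half of the random part of the crossed model.

    ``dim_of_item[i]`` gives the wing-latent dimension item ``i`` loads
    on; ``owns_intercepts`` marks the (single) wing that updates beta.
    """

    kind: str  # "trait" | "method"
    n_dims: int
    dim_of_item: np.ndarray
    owns_intercepts: bool
    correlated: bool = False  # trait wing estimates the correlation matrix


def partition_wings(design: MTMMDesign, intercept_owner: str = "method"):
    """Split the random part into the trait wing and the method wing.

    Every item's trait term goes to the trait wing and its method term
    to the method wing; together they cover the full random part.
    """
    if intercept_owner not in ("trait", "method"):
        raise ValueError("intercept_owner must be 'trait' or 'method'")
    trait = Wing("trait", design.n_traits, design.trait_of_item.copy(),
                 owns_intercepts=intercept_owner == "trait",
                 correlated=design.n_traits > 1)
    method = Wing("method", design.n_methods, design.method_of_item.copy(),
                  owns_intercepts=intercept_owner == "method")
    return trait, method


def _wing_unpack(u: np.ndarray, wing: Wing, n_items: int):
    """(loadings, intercepts-or-None, corr-matrix) from the wing's
    unconstrained vector [u_loadings, (beta), (y_corr)]."""
    I = n_items
    load = np.abs(u[:I])
    pos = I
    beta = None
    if wing.owns_intercepts:
        beta = u[pos:pos + I]
        pos += I
    R = np.eye(wing.n_dims)
    if wing.correlated and wing.n_dims > 1:
        q = wing.n_dims * (wing.n_dims - 1) // 2
        R = corr_matrix(u[pos:pos + q], wing.n_dims)
    return load, beta, R


def _wing_design_matrix(load: np.ndarray, R: np.ndarray, wing: Wing) -> np.ndarray:
    L = np.linalg.cholesky(R)
    A = load[:, None] * L[wing.dim_of_item, :]
    return A


def _wing_negloglik(u, wing, data, offsets, link, grid, modes=None, Lc=None,
                    logdet=None):
    """Negative marginal log-likelihood of the wing 2PL with offsets.

    When ``modes``/``Lc`` are given the grid is adapted: recentered at
    per-person posterior modes with curvature-based rescaling (computed
    once per P-step and held fixed during the optimization).
    """
    load, beta, R = _wing_unpack(u, wing, data.n_items)
    A = _wing_design_matrix(load, R, wing)
    y, obs = data.filled, data.observed
    off = offsets if beta is None else offsets + beta
    N, I = y.shape
    z = grid.nodes
    K = z.shape[0]
    D = A.shape[1]
    llp = np.empty(N)
    chunk = max(1, int(4_000_000 // max(K * I, 1)))
    log_phi_z = -0.5 * (z**2).sum(axis=1) - 0.5 * D * _LOG_2PI
    for s in range(0, N, chunk):
        e = min(N, s + chunk)
        if modes is not None:
            zeta = modes[s:e, None, :] + np.einsum("kd,ped->pke", z, Lc[s:e])
            corr = (-0.5 * (zeta**2).sum(axis=2) - 0.5 * D * _LOG_2PI
                    + logdet[s:e, None] - log_phi_z)
        else:
            zeta = np.broadcast_to(z, (e - s, K, D))
            corr = 0.0
        eta = np.einsum("pkd,id->pki", zeta, A) + off[s:e, None, :]
        ll = np.where(obs[s:e, None, :],
                      bernoulli_loglik(link, y[s:e, None, :], eta), 0.0).sum(axis=2)
        llp[s:e] = logsumexp(ll + corr + grid.log_weights, axis=1)
    return -llp.sum()


def _wing_negloglik_and_grad(u, wing, data, offsets, link, grid, modes=None,
                             Lc=None, logdet=None, corr_step=1e-5):
    """Value and gradient of the wing negative log-likelihood.

    Loading/intercept gradients use the posterior-node-weight identity
    on the (frozen) grid; the few correlation parameters of a
    correlated trait wing are differenced numerically.
    """
    from .model import bernoulli_derivs

    I = data.n_items
    load, beta, R = _wing_unpack(u, wing, I)
    A = _wing_design_matrix(load, R, wing)
    L = np.linalg.cholesky(R)
    y, obs = data.filled, data.observed
    off = offsets if beta is None else offsets + beta
    N = y.shape[0]
    z = grid.nodes
    K, D = z.shape
    log_phi_z = -0.5 * (z**2).sum(axis=1) - 0.5 * D * _LOG_2PI
    value = 0.0
    g_load = np.zeros(I)
    g_beta = np.zeros(I)
    chunk = max(1, int(4_000_000 // max(K * I, 1)))
    for s in range(0, N, chunk):
        e = min(N, s + chunk)
        if modes is not None:
            zeta = modes[s:e, None, :] + np.einsum("kd,ped->pke", z, Lc[s:e])
            corr = (-0.5 * (zeta**2).sum(axis=2) - 0.5 * D * _LOG_2PI
                    + logdet[s:e, None] - log_phi_z)
        else:
            zeta = np.broadcast_to(z, (e - s, K, D))
            corr = 0.0
        eta = np.einsum("pkd,id->pki", zeta, A) + off[s:e, None, :]
        ll = np.where(obs[s:e, None, :],
                      bernoulli_loglik(link, y[s:e, None, :], eta), 0.0)
        S = ll.sum(axis=2) + corr + grid.log_weights
        llp = logsumexp(S, axis=1)
        value -= llp.sum()
        r = np.exp(S - llp[:, None])  # (B, K)
        d1, _ = bernoulli_derivs(link, y[s:e, None, :], eta)
        d1 = np.where(obs[s:e, None, :], d1, 0.0)
        rw = r[:, :, None] * d1  # (B, K, I)
        g_beta -= rw.sum(axis=(0, 1))
        c = np.einsum("pkd,ed->pke", zeta, L)  # correlated wing coordinates
        g_load -= np.einsum("pki,pki->i", rw, c[:, :, wing.dim_of_item])
    g_load *= np.sign(u[:I])
    parts = [g_load]
    pos = I
    if wing.owns_intercepts:
        parts.append(g_beta)
        pos += I
    if wing.correlated and wing.n_dims > 1:
        q = wing.n_dims * (wing.n_dims - 1) // 2
        gq = np.empty(q)
        for j in range(q):
            up = u.copy(); up[pos + j] += corr_step
            um = u.copy(); um[pos + j] -= corr_step
            fp = _wing_negloglik(up, wing, data, offsets, link, grid,
                                 modes=modes, Lc=Lc, logdet=logdet)
            fm = _wing_negloglik(um, wing, data, offsets, link, grid,
                                 modes=modes, Lc=Lc, logdet=logdet)
            gq[j] = (fp - fm) / (2 * corr_step)
        parts.append(gq)
    return value, np.concatenate(parts)


def fit_wing_2pl(wing: Wing, data: ResponseMatrix, offsets: np.ndarray,
                 link: str = "logit", start: Optional[np.ndarray] = None,
                 points_per_dim: int = 5, adaptive: bool = True,
                 dim_cap: int = DEFAULT_WING_DIM_CAP,
                 compute_covariance: bool = True):
    """Adaptive-quadrature ML fit of one wing's 2PL model.

    The frozen wing's contribution (and the intercepts, when this wing
    does not own them) enters through ``offsets`` (N x I).  Returns
    ``(psi_hat, cov, info)`` where ``psi_hat`` is the wing's
    unconstrained parameter vector at the optimum, ``cov`` its
    covariance from the inverse numerical Hessian (None when not
    requested), and ``info`` a small diagnostics dict.
    """
    if wing.n_dims > dim_cap:
        raise ValueError(f"wing dimension {wing.n_dims} exceeds the cap {dim_cap}")
    offsets = np.asarray(offsets, dtype=float)
    if not np.isfinite(offsets).all():
        raise ValueError("offsets must be finite")
    I = data.n_items
    if start is None:
        start = np.concatenate([
            np.full(I, 0.5),
            np.zeros(I) if wing.owns_intercepts else np.empty(0),
            np.zeros(wing.n_dims * (wing.n_dims - 1) // 2) if wing.correlated else np.empty(0),
        ])
    grid = build_grid(points_per_dim, wing.n_dims)
    modes = Lc = logdet = None

    def adapt_at(u):
        load, beta, R = _wing_unpack(u, wing, I)
        A = _wing_design_matrix(load, R, wing)
        off = offsets if beta is None else offsets + beta
        md, curv, _ = _batch_posterior_modes(A, data.filled, data.observed,
                                             off, link)
        L = np.linalg.cholesky(np.linalg.inv(curv))
        return md, L, np.log(np.einsum("pii->pi", L)).sum(axis=1)

    def f(u):
        return _wing_negloglik_and_grad(u, wing, data, offsets, link, grid,
                                        modes=modes, Lc=Lc, logdet=logdet)

    # adaptation is iterated to a fixed point: recenter the grid at the
    # modes implied by the current estimates, refit, repeat until the
    # estimates stop moving (a grid frozen at a poor start can otherwise
    # place its own spurious optimum)
    res = None
    x = np.asarray(start, dtype=float)
    max_passes = 6 if adaptive else 1
    for p in range(max_passes):
        if adaptive:
            modes, Lc, logdet = adapt_at(x)
        res = minimize(f, x, jac=True, method="L-BFGS-B",
                       bounds=_wing_bounds(wing, I),
                       options={"maxiter": 200, "gtol": 1e-5, "ftol": 1e-9})
        shift = np.abs(res.x - x).max() if p > 0 or not adaptive else np.inf
        x = res.x
        if shift < 5e-3:
            break
    cov = None
    if compute_covariance:
        # Hessian from central differences of the analytic gradient
        p = res.x.size
        H = np.empty((p, p))
        hstep = 1e-4
        for j in range(p):
            up = res.x.copy(); up[j] += hstep
            um = res.x.copy(); um[j] -= hstep
            _, gp = f(up)
            _, gm = f(um)
            H[j] = (gp - gm) / (2 * hstep)
        cov = _nearest_psd_inverse(H)
    info = {"converged": bool(res.success), "negloglik": float(res.fun),
            "n_iterations": int(res.nit)}
    return res.x, cov, info


def _wing_bounds(wing: Wing, n_items: int):
    """Wide box bounds: a numerical guard against likelihood ridges of
    weakly identified items (same rationale as in fit_quadrature)."""
    bounds = [(-8.0, 8.0)] * n_items
    if wing.owns_intercepts:
        bounds += [(-12.0, 12.0)] * n_items
    if wing.correlated and wing.n_dims > 1:
        bounds += [(-6.0, 6.0)] * (wing.n_dims * (wing.n_dims - 1) // 2)
    return bounds


def _clip_to_wing_bounds(psi: np.ndarray, wing: Wing, n_items: int) -> np.ndarray:
    lo, hi = np.array(_wing_bounds(wing, n_items)).T
    return np.clip(psi, lo, hi)


def _nearest_psd_inverse(H: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Inverse of a Hessian, projected to PSD by flooring eigenvalues."""
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    if w.min() < floor:
        logger.info("Hessian eigenvalues floored at %g (min was %g)", floor, w.min())
    w = np.maximum(w, floor)
    return (V / w) @ V.T


def _stabilized(cov: np.ndarray, sd_cap: float = 1.0) -> np.ndarray:
    """Cap per-parameter draw standard deviations.

    A wing with a weakly identified item can report a near-flat Hessian
    and hence an enormous sampling variance; an I-step draw from it
    throws the alternation into a degenerate region it cannot leave.
    Capping the marginal sd (rescaling the corresponding rows/columns)
    keeps the imputation noise at the scale of a poorly-measured but
    sane parameter.
    """
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    scale = np.where(sd > sd_cap, sd_cap / np.maximum(sd, 1e-12), 1.0)
    return cov * np.outer(scale, scale)


def nearest_psd(S: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Nearest (in eigenvalue clipping sense) PSD matrix to ``S``."""
    Ss = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(Ss)
    if w.min() < floor:
        logger.info("covariance eigenvalues floored at %g (min was %g)",
                    floor, w.min())
        w = np.maximum(w, floor)
        return (V * w) @ V.T
    return Ss


def draw_item_parameters(psi_hat: np.ndarray, cov: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One multivariate-normal draw of wing parameters around the fit."""
    psi_hat = np.asarray(psi_hat, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if not np.any(cov):
        return psi_hat.copy()
    cov = nearest_psd(cov)
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError:
        cov = nearest_psd(cov, floor=1e-10)
        L = np.linalg.cholesky(cov)
    return psi_hat + L @ rng.standard_normal(psi_hat.size)


def draw_person_effects(wing: Wing, data: ResponseMatrix, load: np.ndarray,
                        R: np.ndarray, offsets: np.ndarray, link: str,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw each person's wing latent variables from the normal
    approximation to their conditional posterior (mode, inverse
    curvature).  Returns draws on the wing's *correlated* scale
    (N x n_dims): standardized draws mapped through the Cholesky factor
    of ``R``.  Persons whose mode search fails draw from the prior.
    """
    A = _wing_design_matrix(load, R, wing)
    modes, curv, failed = _batch_posterior_modes(A, data.filled, data.observed,
                                                 offsets, link)
    if failed.any():
        warnings.warn(f"{int(failed.sum())} person(s) fell back to prior draws "
                      "in the I-step", stacklevel=2)
    Lc = np.linalg.cholesky(np.linalg.inv(curv))
    z = modes + np.einsum("pde,pe->pd", Lc, rng.standard_normal(modes.shape))
    L = np.linalg.cholesky(R)
    return z @ L.T


def run_aip(design: MTMMDesign, data: ResponseMatrix, iterations: int = 200,
            burn_in: int = 100, seed: int = 0, link: str = "logit",
            points_per_dim: int = 5, adaptive: bool = True,
            clamp_method: bool = False, cov_refresh: int = 25,
            dim_cap: int = DEFAULT_WING_DIM_CAP,
            init: Optional[ModelParameters] = None) -> FitResult:
    """Run the full AIP alternation and average the post-burn-in draws.

    ``clamp_method`` freezes the method wing at zero (loadings and
    effects), reducing the model to its trait part; intercept ownership
    then moves to the trait wing.  The wing covariance used in the
    I-step is refreshed by a full numerical Hessian every
    ``cov_refresh`` iterations and reused in between (parameter
    estimates move little from one alternation to the next).
    """
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    rng = np.random.default_rng(seed)
    I, T, M = design.n_items, design.n_traits, design.n_methods
    trait_wing, method_wing = partition_wings(
        design, intercept_owner="trait" if clamp_method else "method")
    if init is None:
        start = starting_values(design, data, link)
        beta = start.intercepts.copy()
        tl = np.full(I, 0.5)
        ml = np.zeros(I) if clamp_method else np.full(I, 0.5)
        R = np.eye(T)
    else:
        beta = init.intercepts.copy()
        tl = init.trait_loadings.copy()
        ml = np.zeros(I) if clamp_method else init.method_loadings.copy()
        R = init.trait_correlation.copy()
    theta_T = np.zeros((data.n_persons, T))
    theta_M = np.zeros((data.n_persons, M))
    names = parameter_names(design)
    chain: list[np.ndarray] = []
    fitted_chain: list[np.ndarray] = []
    cur_fit = {"tl": tl.copy(), "ml": ml.copy(), "beta": beta.copy(),
               "R": R.copy()}
    warm: dict[str, np.ndarray] = {}
    covs: dict[str, np.ndarray] = {}
    n_wing_failures = 0

    def pack_trait():
        parts = [tl]
        if trait_wing.owns_intercepts:
            parts.append(beta)
        if trait_wing.correlated:
            parts.append(unconstrain_corr(R))
        return np.concatenate(parts)

    for k in range(iterations):
        refresh = (k % cov_refresh == 0)
        # ----- trait wing: method contribution (and beta if not owned) frozen
        off = ml * theta_M[:, design.method_of_item]
        if not trait_wing.owns_intercepts:
            off = off + beta
        try:
            psi, cov, info = fit_wing_2pl(
                trait_wing, data, off, link=link,
                start=warm.get("trait", pack_trait()),
                points_per_dim=points_per_dim, adaptive=adaptive,
                dim_cap=dim_cap, compute_covariance=refresh or "trait" not in covs)
            warm["trait"] = psi
            if cov is not None:
                covs["trait"] = cov
        except Exception as exc:  # noqa: BLE001
            n_wing_failures += 1
            warnings.warn(f"trait wing fit failed at iteration {k}: {exc}; "
                          "reusing previous draw", stacklevel=2)
            psi = warm.get("trait", pack_trait())
        tl_hat, beta_hat, R_hat = _wing_unpack(psi, trait_wing, I)
        cur_fit["tl"], cur_fit["R"] = tl_hat, R_hat
        if beta_hat is not None:
            cur_fit["beta"] = beta_hat
        draw = draw_item_parameters(psi, _stabilized(covs["trait"]), rng)
        draw = _clip_to_wing_bounds(draw, trait_wing, I)
        tl, beta_t, R = _wing_unpack(draw, trait_wing, I)
        if beta_t is not None:
            beta = beta_t
        theta_T = draw_person_effects(trait_wing, data, tl, R, off, link, rng)

        # ----- method wing: trait contribution frozen at the drawn values
        if clamp_method:
            pass  # method part pinned to zero
        else:
            off = tl * theta_T[:, design.trait_of_item]
            start_m = warm.get("method", np.concatenate([ml, beta]))
            try:
                psi, cov, info = fit_wing_2pl(
                    method_wing, data, off, link=link, start=start_m,
                    points_per_dim=points_per_dim, adaptive=adaptive,
                    dim_cap=dim_cap,
                    compute_covariance=refresh or "method" not in covs)
                warm["method"] = psi
                if cov is not None:
                    covs["method"] = cov
            except Exception as exc:  # noqa: BLE001
                n_wing_failures += 1
                warnings.warn(f"method wing fit failed at iteration {k}: {exc}; "
                              "reusing previous draw", stacklevel=2)
                psi = start_m
            ml_hat, beta_hat, _ = _wing_unpack(psi, method_wing, I)
            cur_fit["ml"], cur_fit["beta"] = ml_hat, beta_hat
            draw = draw_item_parameters(psi, _stabilized(covs["method"]), rng)
            draw = _clip_to_wing_bounds(draw, method_wing, I)
            ml, beta_m, _ = _wing_unpack(draw, method_wing, I)
            beta = beta_m
            theta_M = draw_person_effects(method_wing, data, ml, np.eye(M),
                                          off + beta, link, rng)

        if k >= burn_in:
            params_k = ModelParameters(tl, ml, beta, R, link=link)
            chain.append(params_to_vector(params_k, design))
            fitted_chain.append(params_to_vector(
                ModelParameters(cur_fit["tl"], cur_fit["ml"], cur_fit["beta"],
                                cur_fit["R"], link=link), design))
        logger.debug("AIP iteration %d done", k)

    if n_wing_failures >= iterations:
        raise RuntimeError("AIP: every iteration had a wing failure")
    draws = pd.DataFrame(np.array(chain), columns=names)
    mean = draws.mean(axis=0).to_numpy()
    sd = draws.std(axis=0, ddof=1).to_numpy()
    from .model import vector_to_params
    estimates = vector_to_params(mean, design, link=link)
    from .quadrature import marginal_log_likelihood
    try:
        ll = marginal_log_likelihood(design, estimates, data,
                                     points_per_dim=points_per_dim)
    except Exception:  # CapacityError for very large latent spaces
        ll = np.nan
    half = len(chain) // 2
    half_shift = float(np.max(np.abs(draws.iloc[:half].mean()
                                     - draws.iloc[half:].mean())))
    return FitResult(
        estimates=estimates,
        log_likelihood=float(ll),
        converged=n_wing_failures == 0,
        n_iterations=iterations,
        estimator_tag="aip",
        seed=seed,
        diagnostics={"max_chain_sd": float(sd.max()),
                     "mean_chain_sd": float(sd.mean()),
                     "n_wing_failures": float(n_wing_failures),
                     "half_mean_max_shift": half_shift},
        chain=draws,
        chain_se=sd / np.sqrt(max(len(chain), 1)),
        aux={"fitted_chain": pd.DataFrame(np.array(fitted_chain),
                                          columns=names)},
    )
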