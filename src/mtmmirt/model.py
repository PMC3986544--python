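"""Conditional response model for crossed trait/method factors.

The model for a binary response of person ``p`` to item ``i`` is

    g(pi_pi) = aT_i * thetaT_{p,t(i)} + aM_i * thetaM_{p,m(i)} + beta_i,

with ``g`` a logit or probit link, ``t(i)``/``m(i)`` the trait and
method factor item ``i`` belongs to, trait scores jointly normal with
correlation matrix ``Sigma_T`` (unit variances) and method scores
independent standard normal, uncorrelated with the traits (the
correlated-trait, uncorrelated-method — CT-UM — structure).  All latent
variances are fixed to 1 for factor standardization, so the loadings
carry the full scale of each factor's influence.

This module also computes per-item consistency and method-specificity
coefficients: the share of the non-error (latent) variance of an item
attributable to its trait factor versus its method factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import special

from .design import MTMMDesign

__all__ = [
    "LINKS",
    "ConfigurationError",
    "ModelParameters",
    "ResponseMatrix",
    "LatentState",
    "CoefficientTable",
    "link_inverse",
    "link_forward",
    "response_probability",
    "joint_conditional_probability",
    "validity_coefficients",
    "parameter_names",
    "params_to_vector",
    "vector_to_params",
]

logger = logging.getLogger(__name__)

LINKS = ("logit", "probit")
Link = Literal["logit", "probit"]


class ConfigurationError(ValueError):
    """Raised for invalid model or estimator configuration."""


def link_inverse(link: str, x):
    """Inverse link: response probability for linear predictor ``x``.

    ``logit`` maps through the logistic function, ``probit`` through the
    standard-normal CDF.  Vectorized over ``x``.
    """
    if link == "logit":
        return special.expit(x)
    if link == "probit":
        return special.ndtr(np.asarray(x, dtype=float))
    raise ConfigurationError(f"unknown link {link!r}; expected one of {LINKS}")


def link_forward(link: str, p):
    """Link function: linear predictor for probability ``p``."""
    if link == "logit":
        return special.logit(p)
    if link == "probit":
        return special.ndtri(np.asarray(p, dtype=float))
    raise ConfigurationError(f"unknown link {link!r}; expected one of {LINKS}")


def bernoulli_loglik(link: str, y, eta):
    """log p(y | eta) for binary y, vectorized (missing handled upstream)."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if link == "logit":
        # y*eta - log(1 + e^eta), stable via logaddexp
        return y * eta - np.logaddexp(0.0, eta)
    if link == "probit":
        return y * special.log_ndtr(eta) + (1.0 - y) * special.log_ndtr(-eta)
    raise ConfigurationError(f"unknown link {link!r}; expected one of {LINKS}")


def bernoulli_derivs(link: str, y, eta):
    """First and second derivatives of log p(y|eta) w.r.t. eta.

    Returns ``(d1, d2)``.  For the logit link these are ``y - sigma`` and
    ``-sigma (1 - sigma)``; for probit the usual Mills-ratio forms.
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if link == "logit":
        p = special.expit(eta)
        return y - p, -p * (1.0 - p)
    if link == "probit":
        # lam = phi/Phi at +eta (y=1), s = phi/Phi(-eta) (y=0)
        log_phi = -0.5 * eta**2 - 0.5 * np.log(2.0 * np.pi)
        lam = np.exp(log_phi - special.log_ndtr(eta))
        s = np.exp(log_phi - special.log_ndtr(-eta))
        d1 = y * lam - (1.0 - y) * s
        d2 = y * (-lam * (lam + eta)) + (1.0 - y) * (-s * (s - eta))
        return d1, d2
    raise ConfigurationError(f"unknown link {link!r}; expected one of {LINKS}")


@dataclass(frozen=True)
class ModelParameters:
    """Item and population parameters of the CT-UM model.

    ``trait_loadings[i]`` is the loading of item ``i`` on its own trait
    factor ``t(i)`` (there is one trait loading per item, not a full
    I x T matrix, because each item measures exactly one trait); same
    for ``method_loadings``.  ``trait_correlation`` is the T x T
    correlation matrix of the trait scores.  All latent variances are 1,
    and loadings are nonnegative under the sign-identifiability
    convention adopted throughout the package.
    """

    trait_loadings: np.ndarray
    method_loadings: np.ndarray
    intercepts: np.ndarray
    trait_correlation: np.ndarray
    link: Link = "logit"

    def __post_init__(self) -> None:
        tl = np.atleast_1d(np.asarray(self.trait_loadings, dtype=float))
        ml = np.atleast_1d(np.asarray(self.method_loadings, dtype=float))
        b = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        R = np.atleast_2d(np.asarray(self.trait_correlation, dtype=float))
        object.__setattr__(self, "trait_loadings", tl)
        object.__setattr__(self, "method_loadings", ml)
        object.__setattr__(self, "intercepts", b)
        object.__setattr__(self, "trait_correlation", R)
        if self.link not in LINKS:
            raise ConfigurationError(f"unknown link {self.link!r}")
        if not (tl.shape == ml.shape == b.shape):
            raise ConfigurationError("loading and intercept vectors must share one length I")
        if not (np.isfinite(tl).all() and np.isfinite(ml).all() and np.isfinite(b).all()):
            raise ConfigurationError("parameters must be finite")
        if tl.min(initial=0.0) < -1e-10 or ml.min(initial=0.0) < -1e-10:
            raise ConfigurationError("loadings must be nonnegative (sign identifiability)")
        if R.shape[0] != R.shape[1]:
            raise ConfigurationError("trait_correlation must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ConfigurationError("trait_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ConfigurationError("trait_correlation must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigurationError("trait_correlation must be positive semi-definite")

    @property
    def n_items(self) -> int:
        return self.trait_loadings.size

    @property
    def n_traits(self) -> int:
        return self.trait_correlation.shape[0]

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatentState:
    """One person's latent position: trait and method scores."""

    trait_scores: np.ndarray
    method_scores: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.trait_scores, dtype=float))
        m = np.atleast_1d(np.asarray(self.method_scores, dtype=float))
        object.__setattr__(self, "trait_scores", t)
        object.__setattr__(self, "method_scores", m)
        if not (np.isfinite(t).all() and np.isfinite(m).all()):
            raise ValueError("latent scores must be finite")


@dataclass
class ResponseMatrix:
    """Person-by-item binary responses with an implicit missingness mask.

    ``responses`` is an N x I float array with values 0.0, 1.0 or NaN
    (missing).  Missing responses are ignorable: they simply drop out of
    the likelihood product.
    """

    responses: np.ndarray
    person_ids: tuple = ()

    def __post_init__(self) -> None:
        y = np.atleast_2d(np.asarray(self.responses, dtype=float))
        obs = ~np.isnan(y)
        vals = y[obs]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))][0]
            raise ValueError(f"observed responses must be 0 or 1; found {bad!r}")
        if not self.person_ids:
            self.person_ids = tuple(f"p{k + 1}" for k in range(y.shape[0]))
        if len(self.person_ids) != y.shape[0]:
            raise ValueError("person_ids length must match the number of rows")
        if obs.size and (~obs.any(axis=1)).any():
            warnings.warn("some persons have no observed responses; they "
                          "contribute nothing to the likelihood", stacklevel=2)
        self.responses = y

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean N x I mask of non-missing responses."""
        return ~np.isnan(self.responses)

    @property
    def filled(self) -> np.ndarray:
        """Responses with missing entries replaced by 0 (use with ``observed``)."""
        return np.nan_to_num(self.responses, nan=0.0)


@dataclass(frozen=True)
class CoefficientTable:
    """Per-item consistency (trait) and method-specificity coefficients."""

    consistency: np.ndarray
    method_specificity: np.ndarray
    convention: Literal["squared", "literal"] = "squared"

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.consistency, dtype=float))
        m = np.atleast_1d(np.asarray(self.method_specificity, dtype=float))
        object.__setattr__(self, "consistency", c)
        object.__setattr__(self, "method_specificity", m)
        if c.shape != m.shape:
            raise ValueError("coefficient vectors must share one length")
        both = np.isfinite(c) & np.isfinite(m)
        if both.any():
            if (c[both] < -1e-12).any() or (c[both] > 1 + 1e-12).any():
                raise ValueError("coefficients must lie in [0, 1]")
            if not np.allclose(c[both] + m[both], 1.0, atol=1e-12):
                raise ValueError("consistency + method_specificity must equal 1 per item")


def linear_predictor(design: MTMMDesign, params: ModelParameters,
                     trait_scores: np.ndarray, method_scores: np.ndarray) -> np.ndarray:
    """Linear predictor eta for all items, batched over leading axes.

    ``trait_scores`` has shape (..., T) and ``method_scores`` (..., M);
    the result has shape (..., I).
    """
    t = np.asarray(trait_scores, dtype=float)
    m = np.asarray(method_scores, dtype=float)
    eta = (params.trait_loadings * t[..., design.trait_of_item]
           + params.method_loadings * m[..., design.method_of_item]
           + params.intercepts)
    return eta


def response_probability(design: MTMMDesign, params: ModelParameters,
                         latent: LatentState, item: int | str) -> float:
    """P(y_pi = 1 | latent state) for one item (0-based index or label)."""
    i = design.item_index(item)
    eta = (params.trait_loadings[i] * latent.trait_scores[design.trait_of_item[i]]
           + params.method_loadings[i] * latent.method_scores[design.method_of_item[i]]
           + params.intercepts[i])
    return float(link_inverse(params.link, eta))


def joint_conditional_probability(design: MTMMDesign, params: ModelParameters,
                                  latent: LatentState, responses: np.ndarray) -> float:
    """Probability of one person's response vector given the latent state.

    Local independence: the joint probability is the product over
    observed items of the per-item Bernoulli probabilities; missing
    items contribute a factor of 1.  An all-missing row returns 1 with a
    logged warning.
    """
    y = np.asarray(responses, dtype=float).ravel()
    if y.size != design.n_items:
        raise ValueError("response vector length must equal the number of items")
    obs = ~np.isnan(y)
    if not obs.any():
        logger.warning("all responses missing for this person; joint probability is 1")
        return 1.0
    eta = linear_predictor(design, params, latent.trait_scores, latent.method_scores)
    ll = bernoulli_loglik(params.link, y[obs], eta[obs])
    return float(np.exp(ll.sum()))


def validity_coefficients(params: ModelParameters,
                          convention: Literal["squared", "literal"] = "squared") -> CoefficientTable:
    """Consistency and method-specificity coefficients per item.

    With all latent variances fixed at 1, the ``squared`` convention
    reads the coefficients as a variance decomposition,

        gammaT_i = aT_i^2 / (aT_i^2 + aM_i^2),

    while the ``literal`` convention uses the loadings themselves,

        gammaT_i = aT_i / (aT_i + aM_i).

    Both satisfy gammaT + gammaM = 1 per item.  Items with both loadings
    zero have undefined coefficients and come back as NaN with a warning.
    """
    if convention not in ("squared", "literal"):
        raise ConfigurationError(f"unknown convention {convention!r}")
    at = params.trait_loadings
    am = params.method_loadings
    # normalize by the larger loading per item so that squaring cannot
    # underflow for subnormal but nonzero loadings
    scale = np.maximum(at, am)
    ok = scale > 0
    safe = np.where(ok, scale, 1.0)
    a, b = at / safe, am / safe
    if convention == "squared":
        num, den = a**2, a**2 + b**2
    else:
        num, den = a, a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        gt = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    undefined = ~ok
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} item(s) have both loadings zero; "
                      "their coefficients are undefined (NaN)", stacklevel=2)
        gt = np.where(undefined, np.nan, gt)
    gm = 1.0 - gt
    return CoefficientTable(gt, gm, convention=convention)


# ---------------------------------------------------------------------------
# Flat parameter vector layout shared by the samplers and serialization.
# Order: trait loadings (I), method loadings (I), intercepts (I), then the
# upper-triangular off-diagonals of the trait correlation (row-major).


def parameter_names(design: MTMMDesign) -> list[str]:
    names = [f"aT_{lab}" for lab in design.item_labels]
    names += [f"aM_{lab}" for lab in design.item_labels]
    names += [f"beta_{lab}" for lab in design.item_labels]
    T = design.n_traits
    for a in range(T):
        for b in range(a + 1, T):
            names.append(f"rho_{design.trait_labels[a]}_{design.trait_labels[b]}")
    return names


def params_to_vector(params: ModelParameters, design: MTMMDesign) -> np.ndarray:
    T = design.n_traits
    iu = np.triu_indices(T, k=1)
    return np.concatenate([params.trait_loadings, params.method_loadings,
                           params.intercepts, params.trait_correlation[iu]])


def vector_to_params(vec: np.ndarray, design: MTMMDesign,
                     link: Link = "logit") -> ModelParameters:
    vec = np.asarray(vec, dtype=float)
    I, T = design.n_items, design.n_traits
    q = T * (T - 1) // 2
    if vec.size != 3 * I + q:
        raise ValueError(f"expected parameter vector of length {3 * I + q}, got {vec.size}")
    R = np.eye(T)
    iu = np.triu_indices(T, k=1)
    R[iu] = vec[3 * I:]
    R[(iu[1], iu[0])] = vec[3 * I:]
    return ModelParameters(vec[:I], vec[I:2 * I], vec[2 * I:3 * I], R, link=link)
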