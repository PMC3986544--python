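"""Unconstrained parameterizations used by the optimizers.

Loadings are kept nonnegative through an absolute-value
reparameterization (the optimizer works on a signed copy, the model
sees ``|u|``).  Correlation matrices are parameterized through
canonical partial correlations: an unconstrained vector is mapped
through ``tanh`` to partial correlations in (-1, 1) and assembled into
a Cholesky factor row by row, which guarantees a valid (unit-diagonal,
positive-definite) correlation matrix for any input.
"""

from __future__ import annotations

import numpy as np

__all__ = ["corr_cholesky", "corr_matrix", "unconstrain_corr", "corr_offdiag", "corr_from_offdiag"]


def corr_cholesky(y: np.ndarray, n: int) -> np.ndarray:
    """Lower Cholesky factor of an n x n correlation matrix from
    unconstrained vector ``y`` of length n(n-1)/2 (row-major)."""
    y = np.asarray(y, dtype=float)
    z = np.tanh(y)
    L = np.zeros((n, n))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, n):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[k] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(rem, 1e-14))
    return L


def corr_matrix(y: np.ndarray, n: int) -> np.ndarray:
    L = corr_cholesky(y, n)
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return R


def unconstrain_corr(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_matrix`: unconstrained vector from a
    positive-definite correlation matrix."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    L = np.linalg.cholesky(R)
    y = []
    for i in range(1, n):
        rem = 1.0
        for j in range(i):
            z = L[i, j] / np.sqrt(max(rem, 1e-14))
            z = np.clip(z, -1 + 1e-12, 1 - 1e-12)
            y.append(np.arctanh(z))
            rem -= L[i, j] ** 2
    return np.array(y)


def corr_offdiag(R: np.ndarray) -> np.ndarray:
    """Upper-triangular off-diagonals, row-major."""
    n = R.shape[0]
    return np.asarray(R, dtype=float)[np.triu_indices(n, k=1)]


def corr_from_offdiag(r: np.ndarray, n: int) -> np.ndarray:
    R = np.eye(n)
    iu = np.triu_indices(n, k=1)
    R[iu] = r
    R[(iu[1], iu[0])] = r
    return R
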