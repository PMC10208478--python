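"""Block-tridiagonal Gaussian chain solver.

The latent trajectory posterior of a linear-Gaussian state-space model is a
Gaussian Markov chain whose joint precision is block tridiagonal.  Working in
information (precision) form lets a single solver serve both the fixed-parameter
Kalman/RTS smoother and the variational state update, where parameter
uncertainty adds extra quadratic terms that have no filter-form equivalent.

Exponent convention: log q(s) = -1/2 s^T J s + h^T s + const, with J given by
diagonal blocks ``Jdiag[t]`` and sub-diagonal blocks ``Jsub[t] = J[t+1, t]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["chain_solve", "chain_solve_dense"]


@njit(cache=True)
def _chain_solve_impl(Jdiag, Jsub, h):  # pragma: no cover - exercised via wrapper
    T, n, _ = Jdiag.shape
    D = np.empty((T, n, n))
    c = np.empty((T, n))
    # forward block elimination (block Thomas)
    D[0] = Jdiag[0]
    c[0] = h[0]
    for t in range(1, T):
        G = np.linalg.solve(D[t - 1].T, Jsub[t - 1].T).T  # Jsub @ inv(D)
        D[t] = Jdiag[t] - G @ Jsub[t - 1].T
        c[t] = h[t] - G @ c[t - 1]
    # means
    mu = np.empty((T, n))
    mu[T - 1] = np.linalg.solve(D[T - 1], c[T - 1])
    for t in range(T - 2, -1, -1):
        mu[t] = np.linalg.solve(D[t], c[t] - Jsub[t].T @ mu[t + 1])
    # marginal and lag-one covariances (Takahashi recursion on the block
    # tridiagonal inverse) and log-determinant of J
    Sig = np.empty((T, n, n))
    Crs = np.empty((max(T - 1, 0), n, n))
    logdet = 0.0
    sign, ld = np.linalg.slogdet(D[T - 1])
    logdet += ld
    Sig[T - 1] = np.linalg.inv(D[T - 1])
    for t in range(T - 2, -1, -1):
        sign, ld = np.linalg.slogdet(D[t])
        logdet += ld
        Dinv = np.linalg.inv(D[t])
        U = -Dinv @ Jsub[t].T
        Crs[t] = U @ Sig[t + 1]
        Sig[t] = Dinv + Crs[t] @ U.T
        # symmetrize against round-off drift
        Sig[t] = 0.5 * (Sig[t] + Sig[t].T)
    return mu, Sig, Crs, logdet


def chain_solve(Jdiag: np.ndarray, Jsub: np.ndarray, h: np.ndarray):
    """Solve a Gaussian chain given its block-tridiagonal natural parameters.

    Parameters
    ----------
    Jdiag : (T, n, n) diagonal precision blocks (symmetric, J positive definite).
    Jsub : (T-1, n, n) sub-diagonal blocks ``J[t+1, t]``.
    h : (T, n) linear term.

    Returns
    -------
    mu : (T, n) marginal means.
    Sig : (T, n, n) marginal covariances.
    Crs : (T-1, n, n) lag-one covariances ``Cov(s_t, s_{t+1})``.
    logdet : float, ``log det J`` (needed for the chain entropy).
    """
    Jdiag = np.ascontiguousarray(Jdiag, dtype=np.float64)
    h = np.ascontiguousarray(h, dtype=np.float64)
    T, n = h.shape
    if T == 1:
        Sig0 = np.linalg.inv(Jdiag[0])
        mu = (Sig0 @ h[0])[None, :]
        _, logdet = np.linalg.slogdet(Jdiag[0])
        return mu, Sig0[None, :, :], np.empty((0, n, n)), float(logdet)
    Jsub = np.ascontiguousarray(Jsub, dtype=np.float64)
    return _chain_solve_impl(Jdiag, Jsub, h)


def chain_solve_dense(Jdiag: np.ndarray, Jsub: np.ndarray, h: np.ndarray):
    """Reference solver: assemble the full T*n precision and invert it.

    Quadratic memory; intended for small-instance cross-checks only.
    """
    T, n, _ = Jdiag.shape
    J = np.zeros((T * n, T * n))
    for t in range(T):
        J[t * n:(t + 1) * n, t * n:(t + 1) * n] = Jdiag[t]
    for t in range(T - 1):
        J[(t + 1) * n:(t + 2) * n, t * n:(t + 1) * n] = Jsub[t]
        J[t * n:(t + 1) * n, (t + 1) * n:(t + 2) * n] = Jsub[t].T
    Sig = np.linalg.inv(J)
    mu = Sig @ h.ravel()
    _, logdet = np.linalg.slogdet(J)
    marg = np.array([Sig[t * n:(t + 1) * n, t * n:(t + 1) * n] for t in range(T)])
    crs = np.array([Sig[t * n:(t + 1) * n, (t + 1) * n:(t + 2) * n] for t in range(T - 1)])
    return mu.reshape(T, n), marg, crs, float(logdet)
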