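"""Ridge-penalized logistic regression and leave-one-out AUC kernels.

Sliding-window single-trial discrimination needs tens of thousands of tiny
logistic fits (one per window x permutation x left-out trial), so the
Newton/IRLS solver and the rank-based AUC are compiled with numba.  The
intercept is never penalized; features are standardized by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_logistic", "loo_scores", "auc_from_scores", "loo_auc"]


@njit(cache=True)
def _fit_logistic_impl(X, y, ridge, max_iter, tol, beta0):  # pragma: no cover
    n, d = X.shape
    beta = beta0.copy()             # [weights; intercept]
    Xa = np.empty((n, d + 1))
    Xa[:, :d] = X
    Xa[:, d] = 1.0
    pen = np.full(d + 1, ridge)
    pen[d] = 0.0                    # intercept unpenalized

    def _loss(b):
        eta = Xa @ b
        # log(1 + exp(-y*eta)) stably
        m = -y * eta
        val = 0.0
        for i in range(n):
            if m[i] > 30.0:
                val += m[i]
            else:
                val += np.log(1.0 + np.exp(m[i]))
        return val + 0.5 * np.sum(pen * b * b)

    loss = _loss(beta)
    for _ in range(max_iter):
        eta = Xa @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Xa.T @ (p - (y + 1.0) / 2.0) + pen * beta
        w = p * (1.0 - p) + 1e-10
        Hm = (Xa * w.reshape(-1, 1)).T @ Xa
        for j in range(d + 1):
            Hm[j, j] += pen[j] + 1e-12
        step = np.linalg.solve(Hm, grad)
        # backtracking keeps Newton globally convergent on this convex loss
        lr = 1.0
        new_loss = loss
        for _ in range(30):
            cand = beta - lr * step
            new_loss = _loss(cand)
            if new_loss <= loss + 1e-12:
                beta = cand
                break
            lr *= 0.5
        if loss - new_loss < tol * (1.0 + abs(loss)):
            loss = new_loss
            break
        loss = new_loss
    return beta


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1.0,
                 max_iter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """Minimize sum log-loss + ridge/2 * ||w||^2; returns [w; intercept].

    ``y`` in {-1, +1}.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    return _fit_logistic_impl(X, y, ridge, max_iter, tol,
                              np.zeros(X.shape[1] + 1))


@njit(cache=True)
def _loo_scores_impl(X, y, ridge, max_iter, tol):  # pragma: no cover
    n, d = X.shape
    scores = np.empty(n)
    Xs = np.empty((n - 1, d))
    ys = np.empty(n - 1)
    # warm start every left-out fit from the full-data solution
    beta0 = _fit_logistic_impl(X, y, ridge, max_iter, tol,
                               np.zeros(d + 1))
    for i in range(n):
        k = 0
        for j in range(n):
            if j != i:
                Xs[k] = X[j]
                ys[k] = y[j]
                k += 1
        beta = _fit_logistic_impl(Xs, ys, ridge, max_iter, tol, beta0)
        scores[i] = X[i] @ beta[:d] + beta[d]
    return scores


def loo_scores(X: np.ndarray, y: np.ndarray, ridge: float = 1.0,
               max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Leave-one-out decision score for every trial."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if min((y > 0).sum(), (y < 0).sum()) < 2:
        raise ValueError("leave-one-out needs at least 2 trials per class")
    return _loo_scores_impl(X, y, ridge, max_iter, tol)


@njit(cache=True)
def _auc_impl(scores, y):  # pragma: no cover
    n_pos = 0
    n_neg = 0
    acc = 0.0
    for i in range(scores.size):
        if y[i] > 0:
            n_pos += 1
            for j in range(scores.size):
                if y[j] < 0:
                    if scores[i] > scores[j]:
                        acc += 1.0
                    elif scores[i] == scores[j]:
                        acc += 0.5
        else:
            n_neg += 1
    return acc / (n_pos * n_neg)


def auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC of positive vs negative scores; ties count 1/2."""
    scores = np.ascontiguousarray(scores, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if (y > 0).sum() == 0 or (y < 0).sum() == 0:
        raise ValueError("AUC needs both classes")
    return float(_auc_impl(scores, y))


@njit(cache=True)
def _loo_auc_windows_impl(F, y, ridge, max_iter, tol):  # pragma: no cover
    n_win = F.shape[0]
    out = np.empty(n_win)
    for w in range(n_win):
        scores = _loo_scores_impl(F[w], y, ridge, max_iter, tol)
        out[w] = _auc_impl(scores, y)
    return out


def loo_auc(features: np.ndarray, y: np.ndarray, ridge: float = 1.0,
            max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """LOO AUC per window for standardized features (windows, trials, dims)."""
    F = np.ascontiguousarray(features, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if min((y > 0).sum(), (y < 0).sum()) < 2:
        raise ValueError("leave-one-out needs at least 2 trials per class")
    return _loo_auc_windows_impl(F, y, ridge, max_iter, tol)
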