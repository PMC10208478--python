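"""Effective connectivity via a bilinear MVAR state-space model.

The generative model couples scalp EEG to latent node activity:

    y_t = L x_t + e_t                      (lead-field observation)
    x_t = G s_t + eps_t                    (source-to-node indicator)
    s_t = A s_{t-1} + sum_k B^k m^k_t s_{t-1} + D u_t + w_t

``A`` holds the intrinsic (baseline) directed couplings between nodes,
``B^k`` the modulation of those couplings by the k-th experimental input
(unit-height boxcars, one per stimulus class), ``D`` a diagonal gain on the
exogenous stimulus drive ``u_t``, and ``w_t`` Gaussian state noise.  Entry
(i, j) of a coupling matrix is the influence of node j on node i one time
step later.

Estimation is mean-field variational Bayes.  The sources are collapsed into
an effective observation matrix ``H = L G`` with a single observation noise
precision absorbing both ``e_t`` and ``L eps_t``; the factorization is
q(s_{1:T}) q(rows of [A|B|D]) q(precisions) with conjugate Gaussian/Gamma
updates and an exact Gaussian-chain state update, so each sweep is coordinate
ascent on the evidence lower bound (ELBO) and the ELBO is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from ._chain import chain_solve

__all__ = [
    "ECModelSpec",
    "InputSet",
    "StatePosterior",
    "ECPosterior",
    "build_inputs",
    "kalman_smoother",
    "vb_fit",
    "elbo",
]

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# model specification and containers
# ---------------------------------------------------------------------------

@dataclass
class ECModelSpec:
    """Specification of the state-space model and its priors.

    Parameters
    ----------
    node_names : node labels; one latent state per node (MVAR order 1).
    leadfield : (channels, sources) forward model L.
    indicator : (sources, nodes) binary matrix G mapping nodes to sources.
    n_modulatory : number K of modulatory inputs (oddball, standard -> 2).
    coupling_prior_precision : zero-mean Gaussian prior precision on each row
        of the stacked coupling matrix [A | B^1..B^K | D].
    noise_prior_shape, noise_prior_rate : Gamma prior on each node's state
        noise precision (mean shape/rate).
    obs_prior_shape, obs_prior_rate : Gamma prior on the combined observation
        noise precision.
    fit_fs : sampling rate (Hz) the model is fit at.
    init_state_precision : precision of the N(0, tau0^-1 I) prior on s_1.
    max_iter, elbo_tol : VB stopping rule (relative ELBO change).
    """

    node_names: list[str]
    leadfield: np.ndarray
    indicator: np.ndarray
    n_modulatory: int = 2
    coupling_prior_precision: float = 1.0
    noise_prior_shape: float = 0.01
    noise_prior_rate: float = 0.01
    obs_prior_shape: float = 0.01
    obs_prior_rate: float = 0.01
    fit_fs: float = 100.0
    init_state_precision: float = 1.0
    max_iter: int = 200
    elbo_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.indicator = np.asarray(self.indicator, dtype=float)
        if not np.isin(self.indicator, (0.0, 1.0)).all():
            raise ValueError("indicator matrix G must be binary")
        if (self.indicator.sum(axis=0) < 1).any():
            raise ValueError("every node needs at least one source in G")
        if self.n_modulatory < 1:
            raise ValueError("need at least one modulatory input")
        if min(self.coupling_prior_precision, self.noise_prior_shape,
               self.noise_prior_rate, self.obs_prior_shape,
               self.obs_prior_rate, self.init_state_precision) <= 0:
            raise ValueError("priors must be strictly positive")
        if self.leadfield.shape[1] != self.indicator.shape[0]:
            raise ValueError("leadfield source count does not match indicator")
        if self.indicator.shape[1] != len(self.node_names):
            raise ValueError("indicator node count does not match node_names")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def observation_matrix(self) -> np.ndarray:
        """Effective observation matrix H = L G."""
        return self.leadfield @ self.indicator

    @property
    def regressor_dim(self) -> int:
        """Per-row regressor length: [s; m^1 s; ..; m^K s; u]."""
        return self.n_nodes * (self.n_modulatory + 1) + 1


@dataclass
class InputSet:
    """Experimental inputs on the fit sampling grid.

    ``modulatory`` is (K, T) with unit-height boxcars, ``exogenous`` is (T,)
    and defaults to the union of all stimulus boxcars (every node receives the
    same drive, scaled by its diagonal entry of D).
    """

    modulatory: np.ndarray
    exogenous: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.modulatory = np.atleast_2d(np.asarray(self.modulatory, dtype=float))
        self.exogenous = np.asarray(self.exogenous, dtype=float)
        if not np.isin(self.modulatory, (0.0, 1.0)).all():
            raise ValueError("modulatory inputs must be unit-height boxcars")
        if self.modulatory.shape[1] != self.exogenous.shape[0]:
            raise ValueError("modulatory and exogenous input lengths differ")


@dataclass
class StatePosterior:
    """Smoothed Gaussian posterior over the latent trajectory."""

    mean: np.ndarray          # (T, n)
    cov: np.ndarray           # (T, n, n)
    lag_one_cov: np.ndarray   # (T-1, n, n), Cov(s_t, s_{t+1})
    log_det_precision: float


@dataclass
class ECPosterior:
    """Posterior over coupling parameters and noise precisions for one run."""

    spec: ECModelSpec
    W_mean: np.ndarray        # (n, d) rows of [A | B^1..B^K | D]
    W_cov: np.ndarray         # (n, d, d)
    state_noise_shape: np.ndarray   # (n,)
    state_noise_rate: np.ndarray    # (n,)
    obs_noise_shape: float
    obs_noise_rate: float
    elbo_trace: np.ndarray
    converged: bool
    failure_reason: str | None = None
    states: StatePosterior | None = None

    # -- views on the stacked coupling matrix --------------------------------
    def _block(self, k: int) -> slice:
        n = self.spec.n_nodes
        return slice(k * n, (k + 1) * n)

    @property
    def A_mean(self) -> np.ndarray:
        return self.W_mean[:, self._block(0)].copy()

    @property
    def B_mean(self) -> np.ndarray:
        """(K, n, n) posterior means of the modulatory matrices."""
        return np.stack([self.W_mean[:, self._block(k + 1)]
                         for k in range(self.spec.n_modulatory)])

    @property
    def D_mean(self) -> np.ndarray:
        return self.W_mean[:, -1].copy()

    def marginal_sd(self) -> np.ndarray:
        """(n, d) posterior standard deviation of every coupling entry."""
        return np.sqrt(np.einsum("ijj->ij", self.W_cov))

    @property
    def A_sd(self) -> np.ndarray:
        return self.marginal_sd()[:, self._block(0)]

    @property
    def B_sd(self) -> np.ndarray:
        return np.stack([self.marginal_sd()[:, self._block(k + 1)]
                         for k in range(self.spec.n_modulatory)])

    @property
    def mean_elbo(self) -> float:
        """Mean ELBO over iterations; model-fit covariate for group analyses."""
        return float(np.mean(self.elbo_trace))


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def build_inputs(events: pd.DataFrame, fs: float, duration: float | None = None,
                 trial_types: tuple[str, str] = ("oddball", "standard")) -> InputSet:
    """Rasterize the event table into modulatory boxcars and stimulus drive.

    One unit-height boxcar per trial type (K = 2: oddball then standard),
    spanning each stimulus presentation.  The exogenous input ``u_t`` is the
    union of the two.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration is None:
        duration = 0.0 if len(events) == 0 else float(
            (events["onset"] + events["duration"]).max()) + 1.0 / fs
    T = int(np.ceil(duration * fs))
    m = np.zeros((len(trial_types), T))
    for k, name in enumerate(trial_types):
        sub = events[events["trial_type"] == name]
        for onset, dur in zip(sub["onset"], sub["duration"]):
            i0 = int(np.round(onset * fs))
            i1 = int(np.round((onset + dur) * fs))
            m[k, i0:min(i1, T)] = 1.0
    u = (m.sum(axis=0) > 0).astype(float)
    return InputSet(modulatory=m, exogenous=u, fs=fs)


# ---------------------------------------------------------------------------
# chain assembly shared by the smoother and the VB state update
# ---------------------------------------------------------------------------

def _pattern_index(modulatory: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map each time step to one of the 2^K on/off input patterns."""
    K, T = modulatory.shape
    codes = (modulatory.T.astype(int) * (1 << np.arange(K))).sum(axis=1)
    patterns = np.unique(codes)
    remap = np.searchsorted(patterns, codes)
    return remap, patterns


def _stack_matrix(pattern_code: int, K: int, n: int) -> np.ndarray:
    """S_p with z_t = [S_p s_{t-1}; u_t] for input pattern p."""
    d = n * (K + 1) + 1
    S = np.zeros((d, n))
    S[:n, :] = np.eye(n)
    for k in range(K):
        if (pattern_code >> k) & 1:
            S[(k + 1) * n:(k + 2) * n, :] = np.eye(n)
    return S


def _assemble_chain(y: np.ndarray, H: np.ndarray, obs_prec: float,
                    state_prec: np.ndarray, G1: np.ndarray, G2: np.ndarray,
                    inputs: InputSet, tau0: float):
    """Natural parameters of q(s_{1:T}) for given parameter expectations.

    ``G1 = E[Lambda W]`` (n, d) and ``G2 = E[W^T Lambda W]`` (d, d), where
    Lambda = diag(state precisions) and W = [A|B|D].  For fixed parameters
    (the plain smoother) these are Lambda W and W^T Lambda W exactly; under
    the VB posterior G2 carries the parameter-covariance correction.
    """
    T, p = y.shape
    n = H.shape[1]
    K = inputs.modulatory.shape[0]
    Lam = np.diag(state_prec)
    HtH = obs_prec * (H.T @ H)

    remap, patterns = _pattern_index(inputs.modulatory)
    Ss = [_stack_matrix(int(c), K, n) for c in patterns]
    # per-pattern blocks (S drops the u row; G2's last row/col handled apart)
    Gs1 = G1[:, :-1]       # (n, d-1)
    G2ss = G2[:-1, :-1]
    G2su = G2[:-1, -1]
    sub_p = np.stack([-(Gs1 @ S[:-1]) for S in Ss])          # -> Jsub
    quad_p = np.stack([S[:-1].T @ G2ss @ S[:-1] for S in Ss])  # -> Jdiag[t-1]
    gu_p = np.stack([S[:-1].T @ G2su for S in Ss])           # (patterns, n)

    Jdiag = np.broadcast_to(HtH + Lam, (T, n, n)).copy()
    Jdiag[0] = HtH + tau0 * np.eye(n)
    Jdiag[:-1] += quad_p[remap[1:]]
    Jsub = sub_p[remap[1:]]
    h = obs_prec * (y @ H)
    u = inputs.exogenous
    h[1:] += u[1:, None] * G1[:, -1]
    h[:-1] -= u[1:, None] * gu_p[remap[1:]]
    return Jdiag, Jsub, h


# ---------------------------------------------------------------------------
# smoother
# ---------------------------------------------------------------------------

def kalman_smoother(eeg: np.ndarray, spec: ECModelSpec, inputs: InputSet,
                    A: np.ndarray, B: np.ndarray, D: np.ndarray,
                    state_prec: np.ndarray | float,
                    obs_prec: float) -> StatePosterior:
    """Exact Gaussian smoothing under fixed coupling parameters.

    The transition matrix is time-varying, ``A_t = A + sum_k B^k m^k_t``; the
    smoother returns marginal means, covariances and lag-one cross
    covariances of the latent trajectory.
    """
    y = np.ascontiguousarray(eeg, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite EEG samples")
    n = spec.n_nodes
    K = spec.n_modulatory
    B = np.asarray(B, dtype=float).reshape(K, n, n)
    state_prec = np.broadcast_to(np.asarray(state_prec, dtype=float), (n,)).copy()
    if (state_prec <= 0).any() or obs_prec <= 0:
        raise ValueError("noise precisions must be positive")
    W = np.concatenate([A] + list(B) + [np.asarray(D, float).reshape(n, 1)], axis=1)
    Lam = np.diag(state_prec)
    G1 = Lam @ W
    G2 = W.T @ Lam @ W
    H = spec.observation_matrix
    Jdiag, Jsub, h = _assemble_chain(y, H, obs_prec, state_prec, G1, G2,
                                     inputs, spec.init_state_precision)
    mu, Sig, Crs, logdet = chain_solve(Jdiag, Jsub, h)
    return StatePosterior(mean=mu, cov=Sig, lag_one_cov=Crs,
                          log_det_precision=logdet)


# ---------------------------------------------------------------------------
# moment bookkeeping for the VB parameter updates
# ---------------------------------------------------------------------------

def _regressor_moments(states: StatePosterior, inputs: InputSet):
    """Sums over transitions of E[z_t z_t^T], E[z_t s_t^T] and E[s_t s_t^T].

    z_t stacks [s_{t-1}; m^1_t s_{t-1}; ...; m^K_t s_{t-1}; u_t]; moments are
    exact under the chain posterior (they use the lag-one covariances).
    """
    mu, Sig, Crs = states.mean, states.cov, states.lag_one_cov
    T, n = mu.shape
    m = inputs.modulatory
    K = m.shape[0]
    u = inputs.exogenous
    d = n * (K + 1) + 1
    M2 = Sig + np.einsum("ti,tj->tij", mu, mu)          # E[s_t s_t^T]
    M1 = Crs + np.einsum("ti,tj->tij", mu[:-1], mu[1:])  # E[s_t s_{t+1}^T]

    # weights per transition (target index t = 1..T-1, source index t-1)
    mm = np.vstack([np.ones(T), m])                      # m^0 == 1
    wt = mm[:, 1:]                                       # (K+1, T-1)
    Zzz = np.zeros((d, d))
    Zs = np.zeros((d, n))
    for a in range(K + 1):
        for b in range(a, K + 1):
            blk = np.einsum("t,tij->ij", wt[a] * wt[b], M2[:-1])
            Zzz[a * n:(a + 1) * n, b * n:(b + 1) * n] = blk
            if b != a:
                Zzz[b * n:(b + 1) * n, a * n:(a + 1) * n] = blk.T
        zu = np.einsum("t,ti->i", wt[a] * u[1:], mu[:-1])
        Zzz[a * n:(a + 1) * n, -1] = zu
        Zzz[-1, a * n:(a + 1) * n] = zu
        Zs[a * n:(a + 1) * n] = np.einsum("t,tij->ij", wt[a], M1)
    Zzz[-1, -1] = float(u[1:] @ u[1:])
    Zs[-1] = u[1:] @ mu[1:]
    target_ss = np.einsum("tii->i", M2[1:])              # E[s_{t,i}^2], t>=2
    return Zzz, Zs, target_ss


def _transition_sq_err(Zzz, Zs, target_ss, W_mean, W_cov):
    """Per-node sums of E[(s_{t,i} - w_i^T z_t)^2] over transitions."""
    n = W_mean.shape[0]
    S = np.empty(n)
    for i in range(n):
        Eww = W_cov[i] + np.outer(W_mean[i], W_mean[i])
        S[i] = target_ss[i] - 2.0 * W_mean[i] @ Zs[:, i] + np.sum(Eww * Zzz)
    return np.maximum(S, 0.0)


def _obs_sq_err(y, H, states):
    resid = y - states.mean @ H.T
    return float(np.sum(resid * resid) +
                 np.einsum("ij,tjk,ik->", H, states.cov, H))


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

def _gamma_elbo_terms(a, b, a0, b0):
    """E_q[log p(lam)] + H[q(lam)] for Gamma prior/posterior pairs."""
    elog = digamma(a) - np.log(b)
    emean = a / b
    prior = a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * elog - b0 * emean
    entropy = a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a)
    return float(np.sum(prior + entropy))


def elbo(states: StatePosterior, post: "ECPosterior", y: np.ndarray,
         spec: ECModelSpec, moments=None, inputs: InputSet | None = None) -> float:
    """Evidence lower bound of the current factorized posterior.

    Standard decomposition: expected complete-data log likelihood under q,
    plus parameter and precision prior cross-entropies, plus all entropies.
    """
    if moments is None:
        if inputs is None:
            raise ValueError("need either precomputed moments or inputs")
        moments = _regressor_moments(states, inputs)
    Zzz, Zs, target_ss = moments
    T, p = y.shape
    n = spec.n_nodes
    d = spec.regressor_dim
    H = spec.observation_matrix
    alpha = spec.coupling_prior_precision
    tau0 = spec.init_state_precision

    a_s, b_s = post.state_noise_shape, post.state_noise_rate
    a_y, b_y = post.obs_noise_shape, post.obs_noise_rate
    elog_s = digamma(a_s) - np.log(b_s)
    e_s = a_s / b_s
    elog_y = digamma(a_y) - np.log(b_y)
    e_y = a_y / b_y

    Sy = _obs_sq_err(y, H, states)
    Si = _transition_sq_err(Zzz, Zs, target_ss, post.W_mean, post.W_cov)

    val = 0.5 * T * p * (elog_y - LOG2PI) - 0.5 * e_y * Sy
    val += float(np.sum(0.5 * (T - 1) * (elog_s - LOG2PI) - 0.5 * e_s * Si))
    val += 0.5 * n * (np.log(tau0) - LOG2PI) - 0.5 * tau0 * (
        states.mean[0] @ states.mean[0] + np.trace(states.cov[0]))
    # coupling prior and entropy
    for i in range(n):
        val += 0.5 * d * (np.log(alpha) - LOG2PI) - 0.5 * alpha * (
            post.W_mean[i] @ post.W_mean[i] + np.trace(post.W_cov[i]))
        sign, ld = np.linalg.slogdet(post.W_cov[i])
        val += 0.5 * (d * (1.0 + LOG2PI) + ld)
    # precision priors and entropies
    val += _gamma_elbo_terms(a_s, b_s, spec.noise_prior_shape, spec.noise_prior_rate)
    val += _gamma_elbo_terms(np.array([a_y]), np.array([b_y]),
                             spec.obs_prior_shape, spec.obs_prior_rate)
    # state entropy
    val += 0.5 * (T * n * (1.0 + LOG2PI) - states.log_det_precision)
    return float(val)


# ---------------------------------------------------------------------------
# VB fit
# ---------------------------------------------------------------------------

def vb_fit(eeg: np.ndarray, events: pd.DataFrame | InputSet, spec: ECModelSpec,
           keep_states: bool = False, verbose: bool = False) -> ECPosterior:
    """Fit the state-space model to one run by mean-field variational Bayes.

    Alternates (i) the exact Gaussian-chain state update under expected
    parameters and precisions, (ii) conjugate row-wise Gaussian updates of
    [A|B^1..B^K|D], (iii) Gamma precision updates, and (iv) ELBO evaluation,
    until the relative ELBO change falls below ``spec.elbo_tol``.

    A run that produces a non-finite ELBO, a persistent ELBO decrease or no
    convergence within ``spec.max_iter`` iterations is returned with
    ``converged=False`` and a failure reason, for exclusion downstream.
    """
    y = np.ascontiguousarray(eeg, dtype=float)
    if isinstance(events, InputSet):
        inputs = events
        if inputs.modulatory.shape[1] != y.shape[0]:
            raise ValueError("input length does not match EEG length")
    else:
        inputs = build_inputs(events, spec.fit_fs, duration=y.shape[0] / spec.fit_fs)
        inputs.modulatory = inputs.modulatory[:, :y.shape[0]]
        inputs.exogenous = inputs.exogenous[:y.shape[0]]
    T, p = y.shape
    n = spec.n_nodes
    K = spec.n_modulatory
    d = spec.regressor_dim
    if inputs.modulatory.shape[0] != K:
        raise ValueError("input set K does not match model spec")
    if T < 10 * n * d:
        import warnings
        warnings.warn("run length is short relative to the parameter count; "
                      "posteriors may be prior-dominated", stacklevel=2)
    H = spec.observation_matrix
    alpha = spec.coupling_prior_precision

    # initialization: stable intrinsic dynamics, no modulation, precisions at
    # their prior means, parameter covariance at the prior
    W_mean = np.zeros((n, d))
    W_mean[:, :n] = 0.9 * np.eye(n)
    W_cov = np.broadcast_to(np.eye(d) / alpha, (n, d, d)).copy()
    a_s = np.full(n, spec.noise_prior_shape)
    b_s = np.full(n, spec.noise_prior_rate)
    a_y, b_y = spec.obs_prior_shape, spec.obs_prior_rate

    trace: list[float] = []
    converged = False
    reason: str | None = None
    n_decrease = 0
    states = None
    moments = None

    for it in range(spec.max_iter):
        e_s = a_s / b_s
        e_y = a_y / b_y
        # expected natural parameters of the transition
        G1 = np.diag(e_s) @ W_mean
        G2 = np.einsum("i,ij,ik->jk", e_s, W_mean, W_mean)
        G2 += np.einsum("i,ijk->jk", e_s, W_cov)
        Jdiag, Jsub, h = _assemble_chain(y, H, e_y, e_s, G1, G2, inputs,
                                         spec.init_state_precision)
        try:
            mu, Sig, Crs, logdet = chain_solve(Jdiag, Jsub, h)
        except np.linalg.LinAlgError:
            reason = "state update failed (singular chain precision)"
            break
        states = StatePosterior(mu, Sig, Crs, logdet)
        moments = _regressor_moments(states, inputs)
        Zzz, Zs, target_ss = moments

        # conjugate row updates of [A | B | D]
        for i in range(n):
            Lw = alpha * np.eye(d) + e_s[i] * Zzz
            W_cov[i] = np.linalg.inv(Lw)
            W_cov[i] = 0.5 * (W_cov[i] + W_cov[i].T)
            W_mean[i] = e_s[i] * (W_cov[i] @ Zs[:, i])

        # Gamma precision updates
        Si = _transition_sq_err(Zzz, Zs, target_ss, W_mean, W_cov)
        a_s = np.full(n, spec.noise_prior_shape + 0.5 * (T - 1))
        b_s = spec.noise_prior_rate + 0.5 * Si
        Sy = _obs_sq_err(y, H, states)
        a_y = spec.obs_prior_shape + 0.5 * T * p
        b_y = spec.obs_prior_rate + 0.5 * Sy

        post = ECPosterior(spec=spec, W_mean=W_mean.copy(), W_cov=W_cov.copy(),
                           state_noise_shape=a_s, state_noise_rate=b_s,
                           obs_noise_shape=a_y, obs_noise_rate=b_y,
                           elbo_trace=np.empty(0), converged=False)
        val = elbo(states, post, y, spec, moments=moments)
        if not np.isfinite(val):
            trace.append(val)
            reason = "non-finite ELBO"
            break
        if trace:
            rel = (val - trace[-1]) / max(abs(trace[-1]), 1.0)
            if rel < -1e-6:
                n_decrease += 1
                if n_decrease >= 3:
                    trace.append(val)
                    reason = "ELBO decreased on 3 consecutive iterations"
                    break
            else:
                n_decrease = 0
            if verbose:
                print(f"iter {it}: elbo={val:.4f} rel={rel:.3e}")
            if abs(rel) < spec.elbo_tol:
                trace.append(val)
                converged = True
                break
        trace.append(val)
    else:
        reason = f"no convergence within {spec.max_iter} iterations"

    return ECPosterior(
        spec=spec, W_mean=W_mean, W_cov=W_cov,
        state_noise_shape=a_s, state_noise_rate=b_s,
        obs_noise_shape=float(a_y), obs_noise_rate=float(b_y),
        elbo_trace=np.asarray(trace), converged=converged,
        failure_reason=None if converged else reason,
        states=states if keep_states else None,
    )
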