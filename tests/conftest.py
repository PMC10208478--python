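import numpy as np
import pytest

from pupilec.ec_statespace import ECModelSpec, InputSet
from pupilec.synthetic_data import ParadigmSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_paradigm():
    """A short run that still honors all schedule constraints."""
    return ParadigmSpec(n_trials_per_run=20, n_runs=1, n_subjects=3,
                        rng_seed=7)


def random_chain_problem(rng, T=6, n=2):
    """A random SPD block-tridiagonal Gaussian chain."""
    Jd = np.empty((T, n, n))
    Js = rng.normal(0.0, 0.3, (T - 1, n, n))
    for t in range(T):
        M = rng.normal(size=(n, n))
        Jd[t] = M @ M.T + 3.0 * np.eye(n)
    h = rng.normal(size=(T, n))
    return Jd, Js, h


def random_state_space(rng, T=6, n=2, p=4, K=2, tau0=2.0):
    """A random stable bilinear state-space instance with data."""
    L = rng.normal(size=(p, n))
    spec = ECModelSpec(node_names=[f"n{i}" for i in range(n)], leadfield=L,
                       indicator=np.eye(n), n_modulatory=K,
                       init_state_precision=tau0)
    A = rng.normal(0.0, 0.25, size=(n, n)) + 0.3 * np.eye(n)
    B = rng.normal(0.0, 0.1, size=(K, n, n))
    D = rng.normal(0.0, 0.5, size=n)
    m = (rng.random((K, T)) < 0.4).astype(float)
    u = (m.sum(axis=0) > 0).astype(float)
    inputs = InputSet(modulatory=m, exogenous=u, fs=100.0)
    q = rng.uniform(0.5, 2.0, size=n)
    r = rng.uniform(1.0, 4.0)
    y = rng.normal(size=(T, p))
    return spec, inputs, A, B, D, q, r, y


def joint_gaussian_smoother_oracle(spec, inputs, A, B, D, q, r, y):
    """Brute-force smoothing by conditioning the full joint Gaussian.

    Builds s = M z + c in covariance form (z standard normal) and conditions
    on y; independent of the information-form chain implementation.
    """
    T, p = y.shape
    n = spec.n_nodes
    K = inputs.modulatory.shape[0]
    m, u = inputs.modulatory, inputs.exogenous
    H = spec.observation_matrix
    Mb = np.zeros((T, T, n, n))
    c = np.zeros((T, n))
    for t in range(T):
        At = A + sum(m[k, t] * B[k] for k in range(K))
        if t == 0:
            Mb[0, 0] = np.eye(n) / np.sqrt(spec.init_state_precision)
        else:
            for j in range(t):
                Mb[t, j] = At @ Mb[t - 1, j]
            Mb[t, t] = np.diag(1.0 / np.sqrt(q))
            c[t] = At @ c[t - 1] + D * u[t]
    M = np.block([[Mb[i, j] for j in range(T)] for i in range(T)])
    cvec = c.ravel()
    Sss = M @ M.T
    Hbig = np.kron(np.eye(T), H)
    Syy = Hbig @ Sss @ Hbig.T + np.eye(T * p) / r
    Ssy = Sss @ Hbig.T
    mean = cvec + Ssy @ np.linalg.solve(Syy, y.ravel() - Hbig @ cvec)
    cov = Sss - Ssy @ np.linalg.solve(Syy, Ssy.T)
    marg = np.array([cov[t * n:(t + 1) * n, t * n:(t + 1) * n]
                     for t in range(T)])
    crs = np.array([cov[t * n:(t + 1) * n, (t + 1) * n:(t + 2) * n]
                    for t in range(T - 1)])
    return mean.reshape(T, n), marg, crs
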