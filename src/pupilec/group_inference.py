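"""Group-level inference: Bayesian parameter averaging, significance
thresholding, connection strengths, and brain-pupil correlation.

Run-level Gaussian posteriors over the coupling parameters are combined by
Bayesian parameter averaging (BPA): a product of Gaussians with a correction
that removes the (K-1)-fold over-counted prior, so each run's contribution is
weighted by its precision.  Node and network connection strengths summarize
the combined coupling matrices, and Pearson correlation relates the
network-level modulatory strength to the task-evoked pupillary response
across subjects (optionally controlling median reaction time and mean ELBO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ec_statespace import ECPosterior

__all__ = [
    "GroupPosterior",
    "NetworkDefinition",
    "CorrelationResult",
    "bayesian_parameter_averaging",
    "bpa_ec",
    "significant_connections",
    "total_connection_strength",
    "network_strength",
    "brain_pupil_correlation",
]


@dataclass
class GroupPosterior:
    """BPA-combined Gaussian posterior over the rows of [A | B^1..B^K | D]."""

    node_names: list[str]
    n_modulatory: int
    W_mean: np.ndarray      # (n, d)
    W_cov: np.ndarray       # (n, d, d)
    n_runs: int = 1

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def _block(self, k: int) -> slice:
        n = self.n_nodes
        return slice(k * n, (k + 1) * n)

    @property
    def A_mean(self) -> np.ndarray:
        return self.W_mean[:, self._block(0)].copy()

    @property
    def B_mean(self) -> np.ndarray:
        return np.stack([self.W_mean[:, self._block(k + 1)]
                         for k in range(self.n_modulatory)])

    @property
    def D_mean(self) -> np.ndarray:
        return self.W_mean[:, -1].copy()

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.einsum("ijj->ij", self.W_cov))


@dataclass
class NetworkDefinition:
    """Named, disjoint node sets (e.g. early-time / middle-time / late-time)."""

    sets: dict[str, list[str]]
    node_names: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, nodes in self.sets.items():
            for node in nodes:
                if node in seen:
                    raise ValueError(f"node {node!r} appears in two sets")
                if node not in self.node_names:
                    raise ValueError(f"node {node!r} not in the fitted model")
                seen.add(node)

    def indices(self, set_name: str) -> list[int]:
        return [self.node_names.index(v) for v in self.sets[set_name]]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    level: str = "between-subject"
    controlled: bool = False


# ---------------------------------------------------------------------------
# Bayesian parameter averaging
# ---------------------------------------------------------------------------

def bayesian_parameter_averaging(means, covs, prior_mean, prior_cov):
    """Combine K Gaussian posteriors that share one prior.

    Combined precision  Lam = sum_i Lam_i - (K-1) Lam_0 and mean
    mu = Lam^-1 (sum_i Lam_i mu_i - (K-1) Lam_0 mu_0): the product of the
    individual posterior densities divided by the (K-1)-fold repeated prior.
    Raises if the combined precision is not positive definite.
    """
    means = [np.atleast_1d(np.asarray(m, dtype=float)) for m in means]
    covs = [np.atleast_2d(np.asarray(c, dtype=float)) for c in covs]
    if len(means) == 0 or len(means) != len(covs):
        raise ValueError("need matching, non-empty mean/cov lists")
    K = len(means)
    mu0 = np.atleast_1d(np.asarray(prior_mean, dtype=float))
    L0 = np.linalg.inv(np.atleast_2d(np.asarray(prior_cov, dtype=float)))
    Lam = -(K - 1) * L0
    eta = -(K - 1) * (L0 @ mu0)
    for m, c in zip(means, covs):
        Li = np.linalg.inv(c)
        Lam = Lam + Li
        eta = eta + Li @ m
    Lam = 0.5 * (Lam + Lam.T)
    eig = np.linalg.eigvalsh(Lam)
    if eig.min() <= 0:
        raise ValueError("combined precision is not positive definite; "
                         "run posteriors are inconsistent with the prior")
    cov = np.linalg.inv(Lam)
    cov = 0.5 * (cov + cov.T)
    return cov @ eta, cov


def bpa_ec(posteriors: list[ECPosterior]) -> GroupPosterior:
    """BPA across run-level EC posteriors, row by row of [A|B|D].

    All runs must share the model spec; the prior is the spec's zero-mean
    Gaussian on each row.
    """
    if not posteriors:
        raise ValueError("no run posteriors to combine")
    spec = posteriors[0].spec
    n, d = posteriors[0].W_mean.shape
    alpha = spec.coupling_prior_precision
    prior_mean = np.zeros(d)
    prior_cov = np.eye(d) / alpha
    W_mean = np.empty((n, d))
    W_cov = np.empty((n, d, d))
    for i in range(n):
        m, c = bayesian_parameter_averaging(
            [p.W_mean[i] for p in posteriors],
            [p.W_cov[i] for p in posteriors], prior_mean, prior_cov)
        W_mean[i], W_cov[i] = m, c
    return GroupPosterior(node_names=list(spec.node_names),
                          n_modulatory=spec.n_modulatory,
                          W_mean=W_mean, W_cov=W_cov, n_runs=len(posteriors))


# ---------------------------------------------------------------------------
# significance and strengths
# ---------------------------------------------------------------------------

def significant_connections(group: GroupPosterior | ECPosterior,
                            alpha: float = 0.05,
                            m_tests: int | None = None) -> dict[str, np.ndarray]:
    """Bonferroni-corrected posterior-probability threshold on couplings.

    A connection is significant when the posterior probability of the
    opposite sign is below (alpha / m_tests) / 2 (two-sided).  ``m_tests``
    defaults to the number of estimated A plus B entries.
    """
    if m_tests is None:
        n = len(group.node_names) if isinstance(group, GroupPosterior) \
            else group.spec.n_nodes
        K = group.n_modulatory if isinstance(group, GroupPosterior) \
            else group.spec.n_modulatory
        m_tests = n * n * (K + 1)
    if m_tests < 1:
        raise ValueError("m_tests must be at least 1")
    mean = group.W_mean
    sd = group.marginal_sd()
    with np.errstate(divide="ignore"):
        opp = stats.norm.sf(np.abs(mean) / np.where(sd > 0, sd, np.inf))
    flags = opp < (alpha / m_tests) / 2.0
    n = mean.shape[0]
    K = (mean.shape[1] - 1) // n - 1
    return {
        "A": flags[:, :n],
        "B": np.stack([flags[:, (k + 1) * n:(k + 2) * n] for k in range(K)]),
        "D": flags[:, -1],
        "m_tests": m_tests,
    }


def total_connection_strength(params: np.ndarray, node: int) -> float:
    """Sum of unsigned afferent, efferent, and self couplings of one node.

    Self-connection |params[node, node]| is counted once.
    """
    M = np.asarray(params, dtype=float)
    if not 0 <= node < M.shape[0]:
        raise IndexError("node outside the coupling matrix")
    return float(np.abs(M[node]).sum() + np.abs(M[:, node]).sum()
                 - np.abs(M[node, node]))


def network_strength(params: np.ndarray, from_set, to_set,
                     sign: str = "+") -> float:
    """Signed network coupling strength from one node set to another.

    Entry (i, j) is the influence of node j on node i, so the from->to block
    is ``params[to_set, from_set]``; the positive (negative) strength sums
    the positive (negative) entries of that block.
    """
    M = np.asarray(params, dtype=float)
    block = M[np.ix_(list(to_set), list(from_set))]
    if sign == "+":
        return float(block[block > 0].sum())
    if sign == "-":
        return float(block[block < 0].sum())
    raise ValueError("sign must be '+' or '-'")


# ---------------------------------------------------------------------------
# brain-pupil correlation
# ---------------------------------------------------------------------------

def _residualize_on(x: np.ndarray, control: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(control), control])
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ coef


def brain_pupil_correlation(strengths: np.ndarray, teprs: np.ndarray,
                            controls: dict[str, np.ndarray] | None = None,
                            level: str = "between-subject",
                            alternative: str = "two-sided") -> CorrelationResult:
    """Pearson correlation between network EC strength and mean TEPR.

    With ``controls``, the median reaction time is regressed out of the TEPR
    and the mean ELBO out of the strength before correlating (keys
    ``rt_median`` and ``elbo_mean``).  ``level`` tags whether points are
    subjects or pooled runs.
    """
    x = np.asarray(strengths, dtype=float)
    y = np.asarray(teprs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("strengths and TEPRs must be aligned 1-d arrays")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    controlled = False
    scale_x, scale_y = max(x.std(), 1e-30), max(y.std(), 1e-30)
    if controls:
        if "elbo_mean" in controls:
            x = _residualize_on(x, np.asarray(controls["elbo_mean"], float))
            controlled = True
        if "rt_median" in controls:
            y = _residualize_on(y, np.asarray(controls["rt_median"], float))
            controlled = True
    if x.std() <= 1e-10 * scale_x or y.std() <= 1e-10 * scale_y:
        raise ValueError("zero variance in a correlated variable "
                         "(degenerate input or control)")
    res = stats.pearsonr(x, y, alternative=alternative)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=x.size, level=level, controlled=controlled)
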