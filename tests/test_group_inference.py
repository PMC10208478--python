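"""BPA, significance thresholding, strengths, and brain-pupil correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pupilec.group_inference import (CorrelationResult, GroupPosterior,
                                     NetworkDefinition,
                                     bayesian_parameter_averaging,
                                     brain_pupil_correlation,
                                     network_strength,
                                     significant_connections,
                                     total_connection_strength)


def _grid_log_density(x, mean, var):
    return -0.5 * np.log(2 * np.pi * var) - 0.5 * (x - mean) ** 2 / var


class TestBPA:
    def test_single_run_is_identity(self, rng):
        m = rng.normal(size=3)
        C = np.diag(rng.uniform(0.5, 2.0, 3))
        mean, cov = bayesian_parameter_averaging([m], [C], np.zeros(3),
                                                 100.0 * np.eye(3))
        assert np.allclose(mean, m, atol=1e-10)
        assert np.allclose(cov, C, atol=1e-10)

    def test_equal_precisions_flat_prior_average_means(self, rng):
        m1, m2 = rng.normal(size=2), rng.normal(size=2)
        C = np.eye(2) * 0.7
        mean, _ = bayesian_parameter_averaging(
            [m1, m2], [C, C], np.zeros(2), 1e8 * np.eye(2))
        assert np.allclose(mean, (m1 + m2) / 2, atol=1e-6)

    def test_matches_density_product_oracle_on_grid(self, rng):
        """BPA equals prod_i q_i(x) / p(x)^(K-1), normalized on a fine grid."""
        K = 4
        means = rng.normal(size=(K, 1))
        vars_ = rng.uniform(0.2, 1.5, size=K)
        covs = [np.array([[v]]) for v in vars_]
        prior_var = 4.0
        mean, cov = bayesian_parameter_averaging(
            means, covs, np.zeros(1), np.array([[prior_var]]))
        x = np.linspace(-8, 8, 20001)
        logq = sum(_grid_log_density(x, m[0], v)
                   for m, v in zip(means, vars_))
        logq -= (K - 1) * _grid_log_density(x, 0.0, prior_var)
        logq -= logq.max()
        q = np.exp(logq)
        q /= np.trapezoid(q, x)
        p = np.exp(_grid_log_density(x, mean[0], cov[0, 0]))
        kl = np.trapezoid(q * (np.log(q + 1e-300) - np.log(p + 1e-300)), x)
        assert abs(kl) < 1e-8

    def test_order_invariance_and_associativity(self, rng):
        K = 5
        means = [rng.normal(size=2) for _ in range(K)]
        covs = []
        for _ in range(K):
            M = rng.normal(size=(2, 2))
            covs.append(M @ M.T + 0.5 * np.eye(2))
        mu0, C0 = np.zeros(2), 5.0 * np.eye(2)
        m_fwd, c_fwd = bayesian_parameter_averaging(means, covs, mu0, C0)
        perm = [3, 1, 4, 0, 2]
        m_perm, c_perm = bayesian_parameter_averaging(
            [means[i] for i in perm], [covs[i] for i in perm], mu0, C0)
        assert np.allclose(m_fwd, m_perm, atol=1e-10)
        assert np.allclose(c_fwd, c_perm, atol=1e-10)
        # associativity: combine first three, then fold in the rest
        m_a, c_a = bayesian_parameter_averaging(means[:3], covs[:3], mu0, C0)
        m_b, c_b = bayesian_parameter_averaging(
            [m_a] + means[3:], [c_a] + covs[3:], mu0, C0)
        assert np.allclose(m_b, m_fwd, atol=1e-10)
        assert np.allclose(c_b, c_fwd, atol=1e-10)

    def test_inconsistent_prior_rejected(self):
        # posterior much wider than the prior makes the correction negative
        with pytest.raises(ValueError, match="positive definite"):
            bayesian_parameter_averaging(
                [np.zeros(1), np.zeros(1)],
                [np.array([[50.0]]), np.array([[50.0]])],
                np.zeros(1), np.array([[1.0]]))


def _group_posterior(mean, sd, n=2, K=1):
    d = n * (K + 1) + 1
    W_mean = np.full((n, d), mean)
    W_cov = np.tile((sd ** 2) * np.eye(d), (n, 1, 1))
    return GroupPosterior(node_names=[f"n{i}" for i in range(n)],
                          n_modulatory=K, W_mean=W_mean, W_cov=W_cov)


class TestSignificance:
    def test_zero_mean_never_significant(self):
        flags = significant_connections(_group_posterior(0.0, 1.0))
        assert not flags["A"].any() and not flags["B"].any()

    def test_ten_sigma_with_bonferroni_significant(self):
        g = _group_posterior(10.0, 1.0)
        flags = significant_connections(g, alpha=0.05, m_tests=100)
        assert flags["A"].all() and flags["B"].all()

    def test_default_m_tests_counts_A_and_B_entries(self):
        g = _group_posterior(0.0, 1.0, n=3, K=2)
        flags = significant_connections(g)
        assert flags["m_tests"] == 3 * 3 * 3


class TestStrengths:
    def test_spec_arithmetic_example(self):
        M = np.array([[0.5, -0.2], [0.1, 0.0]])
        assert total_connection_strength(M, 0) == pytest.approx(0.8)

    def test_zero_matrix_zero_strength(self):
        assert total_connection_strength(np.zeros((4, 4)), 2) == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            M = rng.normal(size=(10, 10))
            node = int(rng.integers(10))
            total = 0.0
            for i in range(10):
                for j in range(10):
                    if i == node or j == node:
                        total += abs(M[i, j])
            assert total_connection_strength(M, node) == pytest.approx(total)

    def test_network_strength_signs_and_conservation(self, rng):
        M = rng.normal(size=(6, 6))
        frm, to = [0, 1, 2], [3, 4, 5]
        pos = network_strength(M, frm, to, "+")
        neg = network_strength(M, frm, to, "-")
        blk = M[np.ix_(to, frm)]
        assert pos >= 0 and neg <= 0
        assert pos + neg == pytest.approx(blk.sum())

    def test_all_positive_block(self):
        M = np.zeros((4, 4))
        M[0:2, 2:4] = 0.3          # influence of nodes {2,3} on {0,1}
        assert network_strength(M, [2, 3], [0, 1], "+") == pytest.approx(1.2)
        assert network_strength(M, [2, 3], [0, 1], "-") == 0.0

    def test_spec_negative_block_example(self):
        M = np.zeros((3, 3))
        M[0, 2], M[1, 2], M[0, 1] = -0.3, 0.2, -0.1
        assert network_strength(M, [1, 2], [0, 1], "-") == pytest.approx(-0.4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, (5, 5),
                  elements=st.floats(-10, 10, allow_nan=False)))
    def test_strength_identity_property(self, M):
        frm, to = [0, 1], [2, 3, 4]
        pos = network_strength(M, frm, to, "+")
        neg = network_strength(M, frm, to, "-")
        assert pos + neg == pytest.approx(M[np.ix_(to, frm)].sum(), abs=1e-9)


class TestNetworkDefinition:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="two sets"):
            NetworkDefinition(sets={"early": ["a"], "late": ["a"]},
                              node_names=["a", "b"])

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="not in the fitted model"):
            NetworkDefinition(sets={"early": ["zz"]}, node_names=["a"])


class TestBrainPupilCorrelation:
    def test_identity_gives_r_one(self):
        x = np.arange(10.0)
        res = brain_pupil_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_planted_rho_within_fisher_sampling_interval(self, rng):
        """Estimated r falls in the analytic 95% interval ~95% of the time."""
        rho, n = 0.65, 19
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
        C = np.array([[1.0, rho], [rho, 1.0]])
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            xy = rng.multivariate_normal(np.zeros(2), C, size=n,
                                         method="cholesky")
            r = brain_pupil_correlation(xy[:, 0], xy[:, 1]).r
            hits += lo <= r <= hi
        assert hits / n_rep >= 0.93

    def test_controls_are_regressed_out(self, rng):
        n = 30
        elbo = rng.normal(size=n)
        rt = rng.normal(size=n)
        x = 2.0 * elbo + rng.normal(size=n)     # strength driven by ELBO
        y = -1.0 * rt + rng.normal(size=n)      # TEPR driven by RT
        raw = brain_pupil_correlation(x, y)
        ctrl = brain_pupil_correlation(
            x, y, controls={"rt_median": rt, "elbo_mean": elbo})
        assert ctrl.controlled and not raw.controlled

    def test_degenerate_control_raises(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="zero variance"):
            brain_pupil_correlation(x, y, controls={"elbo_mean": x.copy()})

    def test_result_fields(self):
        res = brain_pupil_correlation(np.arange(5.0),
                                      np.array([1.0, 3, 2, 5, 4]))
        assert isinstance(res, CorrelationResult)
        assert -1 <= res.r <= 1 and res.n == 5
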