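"""Functional connectivity: nuisance model, residualization, FC, tSNR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pupilec.fmri_connectivity import (ROITimeSeries, fc_matrix,
                                       group_fc_test, nuisance_design_24,
                                       residualize_series, tsnr)

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _motion(rng, n=100):
    return pd.DataFrame(rng.normal(size=(n, 6)), columns=MOTION_COLS)


class TestNuisance24:
    def test_six_motion_columns_become_24(self, rng):
        out = nuisance_design_24(_motion(rng), np.zeros(100), np.zeros(100))
        motion_cols = [c for c in out.columns
                       if c not in ("white_matter", "ventricles")]
        assert len(motion_cols) == 24
        assert out.shape[1] == 26

    def test_wrong_motion_count_rejected(self, rng):
        with pytest.raises(ValueError, match="6 motion"):
            nuisance_design_24(_motion(rng).iloc[:, :5], np.zeros(100),
                               np.zeros(100))

    def test_zero_motion_gives_zero_columns(self):
        m = pd.DataFrame(np.zeros((50, 6)), columns=MOTION_COLS)
        out = nuisance_design_24(m, np.zeros(50), np.zeros(50))
        assert not out.to_numpy().any()

    def test_polynomial_symbolic_structure(self):
        """Derivative of a linear drift is constant; its square quadratic."""
        n = 60
        t = np.arange(n, dtype=float)
        m = pd.DataFrame(np.zeros((n, 6)), columns=MOTION_COLS)
        m["trans_x"] = 3.0 * t
        out = nuisance_design_24(m, np.zeros(n), np.zeros(n))
        d = out["trans_x_derivative"].to_numpy()
        assert np.allclose(d[1:], 3.0) and d[0] == 0.0
        assert np.allclose(out["trans_x_sq"], 9.0 * t ** 2)
        assert np.allclose(out["trans_x_derivative_sq"][1:], 9.0)


class TestResidualize:
    def test_series_equal_to_nuisance_column_removed(self, rng):
        nuis = _motion(rng)
        y = nuis["rot_x"].to_numpy()[None, :].copy()
        resid = residualize_series(y, nuis)
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_regressors(self, rng):
        nuis = _motion(rng)
        task = rng.normal(size=(100, 2))
        Y = rng.normal(size=(3, 100))
        resid = residualize_series(Y, nuis, task)
        X = np.column_stack([np.ones(100), nuis.to_numpy(), task])
        assert np.abs(resid @ X).max() < 1e-9

    def test_planted_task_effect_removed(self, rng):
        task = rng.normal(size=(100, 1))
        Y = 2.5 * task.T + 0.1 * rng.normal(size=(1, 100))
        resid = residualize_series(Y, None, task)
        r = np.corrcoef(resid[0], task[:, 0])[0, 1]
        assert abs(r) < 1e-10

    def test_rank_deficient_regressors_rejected(self, rng):
        nuis = _motion(rng)
        nuis["rot_x"] = nuis["trans_x"] * 2.0 + nuis["trans_y"]
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            residualize_series(rng.normal(size=(2, 100)), nuis)


class TestFCMatrix:
    def test_self_correlation_and_zero_diagonal_z(self, rng):
        Y = rng.normal(size=(4, 80))
        fc = fc_matrix(Y)
        assert np.allclose(np.diag(fc.r), 1.0)
        assert np.allclose(np.diag(fc.z), 0.0)
        assert np.allclose(fc.r, fc.r.T) and np.allclose(fc.z, fc.z.T)

    def test_fisher_z_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 400)
        # two series correlated at exactly r: x, rx + sqrt(1-r^2) y
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= (y @ x) / (x @ x) * x
        y /= y.std()
        r = 0.5
        pair = np.vstack([x, r * x + np.sqrt(1 - r * r) * y])
        fc = fc_matrix(pair)
        assert fc.r[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert fc.z[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_zero_variance_roi_named(self, rng):
        Y = rng.normal(size=(3, 50))
        Y[1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            fc_matrix(Y)

    def test_two_block_covariance_recovered(self, rng):
        rho, T = 0.6, 500
        n_per = 3
        C = np.kron(np.eye(2), np.full((n_per, n_per), rho)
                    + (1 - rho) * np.eye(n_per))
        Y = rng.multivariate_normal(np.zeros(6), C, size=T).T
        fc = fc_matrix(Y)
        within = []
        for b in range(2):
            blk = fc.r[b * n_per:(b + 1) * n_per, b * n_per:(b + 1) * n_per]
            within.extend(blk[np.triu_indices(n_per, 1)])
        assert np.mean(within) == pytest.approx(0.6, abs=0.05)
        between = fc.r[:n_per, n_per:]
        assert abs(between.mean()) < 0.15

    def test_fisher_z_null_variance(self, rng):
        """Independent series give Fisher z with variance ~ 1/(T-3)."""
        T = 120
        zs = []
        for _ in range(300):
            Y = rng.normal(size=(2, T))
            zs.append(fc_matrix(Y).z[0, 1])
        assert np.var(zs) == pytest.approx(1.0 / (T - 3), rel=0.2)


class TestROITimeSeries:
    def test_container_accepted_by_fc_and_tsnr(self, rng):
        roi = ROITimeSeries(rng.normal(100.0, 3.0, size=(3, 60)), tr=2.1,
                            names=["lSPL", "rM1", "mPFC-SMA"],
                            coordinates=np.array([[-34, -52, 64],
                                                  [18, -22, 76],
                                                  [4, 18, 56]]))
        fc = fc_matrix(roi)
        assert fc.r.shape == (3, 3)
        assert np.allclose(tsnr(roi)["tsnr"], tsnr(roi.data)["tsnr"])

    def test_invalid_container_rejected(self, rng):
        with pytest.raises(ValueError, match="TR"):
            ROITimeSeries(rng.normal(size=(2, 10)), tr=0.0)
        with pytest.raises(ValueError, match="one name per ROI"):
            ROITimeSeries(rng.normal(size=(2, 10)), tr=2.1, names=["a"])


class TestGroupFC:
    def test_null_cohort_false_positive_rate(self, rng):
        n_roi = 25
        Z = rng.normal(0, 0.1, size=(12, n_roi, n_roi))
        out = group_fc_test(Z)
        off = ~np.eye(n_roi, dtype=bool)
        assert np.mean(out["p"][off] < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_consistent_positive_z_highly_significant(self, rng):
        Z = 0.5 + rng.normal(0, 0.01, size=(10, 3, 3))
        out = group_fc_test(Z)
        assert np.all(out["p"] < 1e-6)

    def test_scale_invariance_of_t(self, rng):
        Z = rng.normal(size=(8, 3, 3))
        a = group_fc_test(Z)
        b = group_fc_test(3.7 * Z)
        assert np.allclose(a["t"], b["t"])


class TestTSNR:
    def test_mean_over_sd_and_cutoff(self, rng):
        Y = rng.normal(100.0, 2.0, size=(1, 5000))
        out = tsnr(Y)
        assert out["tsnr"][0] == pytest.approx(50.0, rel=0.05)
        assert out["passes"][0]

    def test_zero_mean_noise_near_zero(self, rng):
        out = tsnr(rng.normal(0.0, 1.0, size=(1, 2000)))
        assert abs(out["tsnr"][0]) < 0.1
        assert not out["passes"][0]

    def test_invariant_to_positive_rescaling(self, rng):
        Y = rng.normal(50.0, 5.0, size=(2, 300))
        a, b = tsnr(Y)["tsnr"], tsnr(7.3 * Y)["tsnr"]
        assert np.allclose(a, b)

    def test_zero_sd_flagged_infinite(self):
        out = tsnr(np.full((1, 10), 3.0))
        assert out["infinite"][0] and not out["passes"][0]
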