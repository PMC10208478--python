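"""ROI functional connectivity: nuisance regression, Pearson/Fisher-z, tSNR.

Connectivity is computed on residual BOLD after removing a 24-parameter
motion model (6 parameters, their temporal derivatives, and the squares of
those 12) plus white-matter and ventricle signals, and the task-evoked
variance, so the correlations reflect background coupling rather than
stimulus-locked coactivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROITimeSeries",
    "FCMatrix",
    "nuisance_design_24",
    "residualize_series",
    "fc_matrix",
    "group_fc_test",
    "tsnr",
]

TSNR_CUTOFF = 30.0


@dataclass
class ROITimeSeries:
    """ROI-by-volume BOLD matrix with names and (optional) MNI coordinates."""

    data: np.ndarray                  # (rois, volumes)
    tr: float
    names: list[str] | None = None
    coordinates: np.ndarray | None = None   # (rois, 3) MNI mm

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.names is None:
            self.names = [f"roi_{i}" for i in range(self.data.shape[0])]
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per ROI required")


def _as_matrix(rois) -> np.ndarray:
    if isinstance(rois, ROITimeSeries):
        return rois.data
    return np.atleast_2d(np.asarray(rois, dtype=float))


@dataclass
class FCMatrix:
    """Pairwise Pearson r, Fisher z, and p-values for one subject/run."""

    r: np.ndarray
    z: np.ndarray            # atanh(r), diagonal zeroed
    p: np.ndarray
    n_volumes: int
    threshold_mask: np.ndarray | None = None   # p < threshold, off-diagonal


def nuisance_design_24(motion: pd.DataFrame, wm: np.ndarray | pd.Series,
                       ventricles: np.ndarray | pd.Series) -> pd.DataFrame:
    """Expand 6 motion parameters into the 24-parameter model plus tissue.

    Columns: the 6 parameters, their backward-difference temporal derivatives
    (zero-padded at the first volume), the squares of those 12, then the
    white-matter and ventricle signals.
    """
    if motion.shape[1] != 6:
        raise ValueError(f"expected exactly 6 motion columns, got {motion.shape[1]}")
    out = {}
    for name in motion.columns:
        out[str(name)] = motion[name].to_numpy(dtype=float)
    for name in motion.columns:
        x = motion[name].to_numpy(dtype=float)
        out[f"{name}_derivative"] = np.concatenate([[0.0], np.diff(x)])
    for name in list(out):
        out[f"{name}_sq"] = out[name] ** 2
    out["white_matter"] = np.asarray(wm, dtype=float)
    out["ventricles"] = np.asarray(ventricles, dtype=float)
    return pd.DataFrame(out)


def residualize_series(rois: np.ndarray, nuisance: pd.DataFrame | np.ndarray,
                       task_design: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of each ROI series on [nuisance | task regressors].

    An intercept is always included.  Duplicate regressor columns are dropped
    before the rank check; remaining rank deficiency raises.
    """
    Y = _as_matrix(rois)
    blocks = [np.ones((Y.shape[1], 1))]
    if nuisance is not None:
        blocks.append(np.asarray(nuisance, dtype=float))
    if task_design is not None:
        blocks.append(np.atleast_2d(np.asarray(task_design, dtype=float).T).T)
    X = np.column_stack(blocks)
    X = np.unique(X, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("nuisance/task regressor matrix is rank "
                                    "deficient after deduplication")
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ coef).T


def fc_matrix(rois: np.ndarray, threshold_p: float = 0.01) -> FCMatrix:
    """Pairwise Pearson correlation with Fisher z and a per-subject threshold.

    p-values use the t transform with T-2 degrees of freedom; the threshold
    mask marks off-diagonal cells with p below ``threshold_p`` (the
    per-subject gate applied to seed maps before the group stage).
    """
    Y = _as_matrix(rois)
    n_roi, T = Y.shape
    if T < 3:
        raise ValueError("need at least 3 volumes")
    sds = Y.std(axis=1)
    degenerate = sds <= 1e-12 * np.maximum(np.abs(Y.mean(axis=1)), 1.0)
    if degenerate.any():
        names = np.flatnonzero(degenerate).tolist()
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(Y)
    r = np.clip(r, -1.0, 1.0)
    off = ~np.eye(n_roi, dtype=bool)
    z = np.zeros_like(r)
    z[off] = np.arctanh(np.clip(r[off], -1 + 1e-15, 1 - 1e-15))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((T - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), T - 2)
    np.fill_diagonal(p, 0.0)
    return FCMatrix(r=r, z=z, p=p, n_volumes=T,
                    threshold_mask=off & (p < threshold_p))


def group_fc_test(z_matrices: np.ndarray | list[np.ndarray]):
    """Elementwise one-sample t-test on subject Fisher-z matrices.

    Returns t and two-sided p matrices plus masks at the reporting
    thresholds p < 0.001 (seed maps) and p < 0.05 (node-by-node).
    """
    Z = np.asarray(z_matrices, dtype=float)
    if Z.shape[0] < 3:
        raise ValueError("group test requires at least 3 subjects")
    tval, pval = stats.ttest_1samp(Z, 0.0, axis=0)
    zero_var = ~np.isfinite(tval)
    tval = np.where(zero_var, 0.0, tval)
    pval = np.where(zero_var, 1.0, pval)
    return {"t": tval, "p": pval, "mask_p001": pval < 0.001,
            "mask_p05": pval < 0.05, "n": Z.shape[0]}


def tsnr(series: np.ndarray, cutoff: float = TSNR_CUTOFF):
    """Temporal SNR (mean over SD) per ROI with a quality flag.

    Zero-SD series give infinite tSNR and are flagged separately.
    """
    Y = _as_matrix(series)
    if Y.shape[1] < 2:
        raise ValueError("tSNR needs at least 2 volumes")
    mean = Y.mean(axis=1)
    sd = Y.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(sd > 0, mean / sd, np.inf * np.sign(mean))
    return {"tsnr": val, "passes": (val > cutoff) & np.isfinite(val),
            "infinite": ~np.isfinite(val) | (sd == 0)}
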