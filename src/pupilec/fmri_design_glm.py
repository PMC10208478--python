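"""EEG-informed fMRI design construction and ROI-wise GLM fitting.

The single-trial-variability (STV) analysis turns the per-trial EEG
discriminant components at a window center tau into parametric BOLD
regressors: besides unmodulated oddball/standard event regressors and a
reaction-time regressor, two short (100 ms) boxcars at onset+tau are height-
modulated by the demeaned discriminant component, each orthogonalized against
its event regressor (the oddball STV regressor additionally against RT).  All
regressors are built on a 10 ms grid, convolved with a canonical double-gamma
HRF, and sampled at the scanner TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "GLMResult",
    "double_gamma_hrf",
    "build_design",
    "fit_glm",
    "group_level_test",
]

HIRES_DT = 0.01  # seconds; resolution of boxcar construction


@dataclass
class HRFSpec:
    """Canonical double-gamma hemodynamic response (SPM-style parameters)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0


@dataclass
class DesignMatrix:
    """Volumes x regressors design with named columns and provenance.

    ``orthogonalized_against`` records, per column, which other columns it
    was residualized against (in order); the recorded provenance is
    verifiable as zero inner products.
    """

    matrix: pd.DataFrame
    roles: dict[str, str]
    orthogonalized_against: dict[str, list[str]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


@dataclass
class GLMResult:
    betas: pd.DataFrame     # rois x regressors
    tvals: pd.DataFrame
    zvals: pd.DataFrame
    dof: int
    resid_var: np.ndarray   # per ROI


def double_gamma_hrf(spec: HRFSpec = HRFSpec(), dt: float = HIRES_DT) -> np.ndarray:
    """Sampled difference-of-gammas kernel, normalized to unit peak."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.duration, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.undershoot_ratio * under
    return h / h.max()


def _hires_boxcar(onsets, durations, heights, n_hires, dt=HIRES_DT):
    x = np.zeros(n_hires)
    for onset, dur, height in zip(onsets, durations, heights):
        i0 = int(np.round(onset / dt))
        i1 = max(int(np.round((onset + dur) / dt)), i0 + 1)
        x[i0:min(i1, n_hires)] += height
    return x


def _residualize(x: np.ndarray, against: np.ndarray) -> np.ndarray:
    """OLS residual of x on the columns of ``against`` (plain projection)."""
    coef, *_ = np.linalg.lstsq(against, x, rcond=None)
    return x - against @ coef


def build_design(events: pd.DataFrame, stv: np.ndarray,
                 confounds: pd.DataFrame | None, tr: float, n_vols: int,
                 hrf: HRFSpec = HRFSpec(), tau: float = 0.375,
                 stv_duration: float = 0.1,
                 include_derivatives: bool = True) -> DesignMatrix:
    """Build the five-regressor STV design for one run and window center tau.

    Regressors of interest (all HRF-convolved, sampled at TR):
      1. ``event_oddball`` / ``event_standard``: unit boxcars over each
         stimulus presentation;
      2. ``rt``: unit boxcar from stimulus onset for the trial's response
         time (oddball trials), residualized against ``event_oddball``;
      3. ``stv_oddball`` / ``stv_standard``: boxcars at onset+tau of
         ``stv_duration``, height = demeaned per-trial discriminant value,
         residualized against the matching event regressor; ``stv_oddball``
         additionally against ``rt``.

    Temporal derivatives of the regressors of interest (first differences of
    the convolved series) and confound columns are appended unconvolved.
    """
    stv = np.asarray(stv, dtype=float)
    if len(stv) != len(events):
        raise ValueError("need one STV value per trial")
    if abs(stv.mean()) > 1e-8 * (np.abs(stv).max() + 1e-30):
        stv = stv - stv.mean()
    kernel = double_gamma_hrf(hrf, HIRES_DT)
    n_hires = int(np.ceil(n_vols * tr / HIRES_DT)) + kernel.size
    vol_idx = np.round(np.arange(n_vols) * tr / HIRES_DT).astype(int)

    is_odd = (events["trial_type"] == "oddball").to_numpy()
    odd, std = events[is_odd], events[~is_odd]
    if odd["response_time"].isna().any():
        raise ValueError("missing response times for oddball trials")

    hires = {
        "event_oddball": _hires_boxcar(odd["onset"], odd["duration"],
                                       np.ones(len(odd)), n_hires),
        "event_standard": _hires_boxcar(std["onset"], std["duration"],
                                        np.ones(len(std)), n_hires),
        "rt": _hires_boxcar(odd["onset"], odd["response_time"],
                            np.ones(len(odd)), n_hires),
        "stv_oddball": _hires_boxcar(odd["onset"] + tau,
                                     np.full(len(odd), stv_duration),
                                     stv[is_odd], n_hires),
        "stv_standard": _hires_boxcar(std["onset"] + tau,
                                      np.full(len(std), stv_duration),
                                      stv[~is_odd], n_hires),
    }
    cols: dict[str, np.ndarray] = {}
    for name, x in hires.items():
        conv = np.convolve(x, kernel)[:n_hires]
        cols[name] = conv[vol_idx]

    roles = {"event_oddball": "event", "event_standard": "event", "rt": "RT",
             "stv_oddball": "STV", "stv_standard": "STV"}
    provenance: dict[str, list[str]] = {}

    def ortho(name: str, against: list[str]) -> None:
        A = np.column_stack([cols[a] for a in against])
        cols[name] = _residualize(cols[name], A)
        provenance[name] = list(against)

    ortho("rt", ["event_oddball"])
    for name, chain in (("stv_oddball", ["event_oddball", "rt"]),
                        ("stv_standard", ["event_standard"])):
        if np.allclose(cols[name], 0.0):
            warnings.warn(f"regressor {name!r} is identically zero "
                          "(degenerate STV modulation); dropped", stacklevel=2)
            del cols[name]
            del roles[name]
            continue
        # sequential residualization in the stated order
        acc: list[str] = []
        for target in chain:
            cols[name] = _residualize(cols[name], cols[target][:, None])
            acc.append(target)
        provenance[name] = acc

    if include_derivatives:
        for name in list(cols):
            d = np.diff(cols[name], prepend=cols[name][0])
            cols[f"{name}_derivative"] = d
            roles[f"{name}_derivative"] = "derivative"
    if confounds is not None:
        for name in confounds.columns:
            cols[str(name)] = confounds[name].to_numpy()
            roles[str(name)] = "confound"
    matrix = pd.DataFrame(cols)
    zero = [c for c in matrix.columns if np.allclose(matrix[c], 0.0)]
    if zero:
        warnings.warn(f"dropping all-zero regressors: {zero}", stacklevel=2)
        matrix = matrix.drop(columns=zero)
        for c in zero:
            roles.pop(c, None)
    return DesignMatrix(matrix=matrix, roles=roles,
                        orthogonalized_against=provenance)


def fit_glm(rois: np.ndarray, design: DesignMatrix,
            add_intercept: bool = True) -> GLMResult:
    """Ordinary-least-squares GLM per ROI with t and z statistics.

    z is the standard-normal quantile matching the t CDF value (sign-safe).
    Raises on rank deficiency, naming the collinear columns.
    """
    Y = np.atleast_2d(np.asarray(rois, dtype=float))
    X = design.values()
    names = design.names
    if add_intercept:
        X = np.column_stack([X, np.ones(X.shape[0])])
        names = names + ["intercept"]
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify offending columns by incremental rank
        bad, cur = [], np.empty((n, 0))
        for j, name in enumerate(names):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {bad}")
    dof = n - k
    XtX_inv = np.linalg.inv(X.T @ X)
    betas = Y @ X @ XtX_inv.T
    resid = Y - betas @ X.T
    sigma2 = (resid * resid).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, betas / se, 0.0)
    # sign-symmetric normal quantile of the t CDF
    z = np.sign(tvals) * stats.norm.isf(
        np.clip(stats.t.sf(np.abs(tvals), dof), 1e-300, 1.0))
    idx = [f"roi_{i}" for i in range(Y.shape[0])]
    return GLMResult(
        betas=pd.DataFrame(betas, columns=names, index=idx),
        tvals=pd.DataFrame(tvals, columns=names, index=idx),
        zvals=pd.DataFrame(z, columns=names, index=idx),
        dof=dof, resid_var=sigma2)


def group_level_test(subject_betas: np.ndarray):
    """One-sample t-test across subjects per ROI/regressor cell.

    ``subject_betas`` has subjects on axis 0.  Cells with zero variance give
    t = 0 and are flagged rather than propagating NaN.
    """
    b = np.asarray(subject_betas, dtype=float)
    if b.shape[0] < 3:
        raise ValueError("group test requires at least 3 subjects")
    tval, pval = stats.ttest_1samp(b, 0.0, axis=0)
    zero_var = ~np.isfinite(tval)
    tval = np.where(zero_var, 0.0, tval)
    pval = np.where(zero_var, 1.0, pval)
    return {"t": tval, "p": pval, "zero_variance": zero_var, "n": b.shape[0]}
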