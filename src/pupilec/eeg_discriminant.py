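"""Sliding-window single-trial EEG discrimination of oddball vs standard.

For each 50 ms window centered at tau (0 to 1000 ms post-stimulus in 25 ms
steps), the channel signals are window-averaged and a ridge-stabilized
logistic regression learns projection weights w(tau) separating oddball from
standard trials.  The projections d_i(tau) = w(tau)^T ybar_i are the
single-trial variability (STV) components; their demeaned values feed the
EEG-informed fMRI design.  Discrimination quality per window is the
leave-one-out cross-validated AUC, calibrated against a label-permutation
null pooled over windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._logistic import fit_logistic, loo_auc

__all__ = [
    "EEGEpochs",
    "WindowGrid",
    "DiscriminantResult",
    "epoch_continuous",
    "fit_window_discriminant",
    "loo_auc_curve",
    "permutation_threshold",
    "erp_average",
]


@dataclass
class EEGEpochs:
    """Stimulus-locked EEG epochs: (trials, channels, samples)."""

    data: np.ndarray
    fs: float
    tmin: float                      # epoch start relative to onset, seconds
    labels: np.ndarray               # "oddball" / "standard" per trial
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epochs must be (trials, channels, samples)")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.channel_names is None:
            self.channel_names = [f"ch{c}" for c in range(self.data.shape[1])]

    @property
    def y_signed(self) -> np.ndarray:
        """+1 for oddball, -1 for standard."""
        return np.where(self.labels == "oddball", 1.0, -1.0)

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs


@dataclass
class WindowGrid:
    """Sliding-window layout: 50 ms windows, centers 0-1000 ms step 25 ms."""

    width_ms: float = 50.0
    start_ms: float = 0.0
    stop_ms: float = 1000.0
    step_ms: float = 25.0

    @property
    def centers_ms(self) -> np.ndarray:
        return np.arange(self.start_ms, self.stop_ms + 0.5 * self.step_ms,
                         self.step_ms)

    def __len__(self) -> int:
        return self.centers_ms.size


@dataclass
class DiscriminantResult:
    """Per-window weights, components, and (optionally) AUC calibration."""

    grid: WindowGrid
    weights: np.ndarray              # (windows, channels), raw-feature scale
    intercepts: np.ndarray           # (windows,)
    components: np.ndarray           # (windows, trials) d_i(tau)
    demeaned: np.ndarray             # (windows, trials) d~_i(tau)
    labels: np.ndarray
    auc: np.ndarray | None = None
    null_aucs: np.ndarray | None = None
    threshold: float | None = None

    def stv(self, tau_ms: float) -> np.ndarray:
        """Demeaned component vector for the window centered at tau_ms."""
        idx = int(np.argmin(np.abs(self.grid.centers_ms - tau_ms)))
        return self.demeaned[idx]


def epoch_continuous(eeg: np.ndarray, fs: float, events,
                     tmin: float = -0.5, tmax: float = 2.0,
                     channel_names: list[str] | None = None) -> EEGEpochs:
    """Cut stimulus-locked epochs from continuous EEG (samples, channels).

    Trials whose window exceeds the recording are dropped.
    """
    eeg = np.asarray(eeg, dtype=float)
    n_pre = int(round(-tmin * fs))
    n_post = int(round(tmax * fs))
    segs, labels = [], []
    for onset, ttype in zip(events["onset"], events["trial_type"]):
        c = int(round(onset * fs))
        lo, hi = c - n_pre, c + n_post
        if lo < 0 or hi > eeg.shape[0]:
            continue
        segs.append(eeg[lo:hi].T)
        labels.append(ttype)
    return EEGEpochs(data=np.asarray(segs), fs=fs, tmin=tmin,
                     labels=np.asarray(labels), channel_names=channel_names)


def _window_features(epochs: EEGEpochs, grid: WindowGrid) -> np.ndarray:
    """Window-averaged channel features, shape (windows, trials, channels).

    Averaging the channel samples over [tau - N/2, tau + N/2] before the
    projection is identical to averaging the projected samples.
    """
    t_ms = epochs.times * 1000.0
    half = grid.width_ms / 2.0
    feats = []
    for c in grid.centers_ms:
        sel = (t_ms >= c - half - 1e-9) & (t_ms <= c + half + 1e-9)
        if not sel.any():
            raise ValueError(f"window at {c} ms lies outside the epoch")
        feats.append(epochs.data[:, :, sel].mean(axis=2))
    return np.stack(feats)


def _standardize(F: np.ndarray):
    mu = F.mean(axis=1, keepdims=True)
    sd = F.std(axis=1, keepdims=True)
    if (sd <= 0).any():
        bad = np.argwhere(sd[:, 0, :] <= 0)
        raise ValueError(
            "constant (degenerate) features in window(s) "
            f"{sorted(set(int(b[0]) for b in bad))}")
    return (F - mu) / sd, mu, sd


def fit_window_discriminant(epochs: EEGEpochs, grid: WindowGrid = WindowGrid(),
                            ridge: float = 1.0) -> DiscriminantResult:
    """Fit per-window logistic weights and compute STV components.

    Weights are learned on standardized features (ridge on weights only,
    intercept free) and mapped back to the raw channel scale, so
    d_i(tau) = w(tau)^T ybar_i + b equals the classifier decision value.
    """
    y = epochs.y_signed
    if min((y > 0).sum(), (y < 0).sum()) < 2:
        raise ValueError("need at least 2 trials per class")
    F = _window_features(epochs, grid)
    Fz, mu, sd = _standardize(F)
    n_win, n_tr, n_ch = F.shape
    weights = np.empty((n_win, n_ch))
    intercepts = np.empty(n_win)
    comps = np.empty((n_win, n_tr))
    for w in range(n_win):
        beta = fit_logistic(Fz[w], y, ridge=ridge)
        w_raw = beta[:n_ch] / sd[w, 0]
        b_raw = beta[n_ch] - float(mu[w, 0] @ w_raw)
        weights[w] = w_raw
        intercepts[w] = b_raw
        comps[w] = F[w] @ w_raw + b_raw
    demeaned = comps - comps.mean(axis=1, keepdims=True)
    return DiscriminantResult(grid=grid, weights=weights, intercepts=intercepts,
                              components=comps, demeaned=demeaned,
                              labels=epochs.labels.copy())


def loo_auc_curve(epochs: EEGEpochs, grid: WindowGrid = WindowGrid(),
                  ridge: float = 1.0) -> np.ndarray:
    """Leave-one-out AUC per window.

    Each trial is scored by a classifier trained on all other trials; the
    AUC is the Mann-Whitney rank statistic of oddball vs standard scores
    with ties counted 1/2.
    """
    y = epochs.y_signed
    Fz, _, _ = _standardize(_window_features(epochs, grid))
    return loo_auc(Fz, y, ridge=ridge)


def permutation_threshold(epochs: EEGEpochs, grid: WindowGrid = WindowGrid(),
                          n_perm: int = 100, alpha: float = 0.01,
                          ridge: float = 1.0,
                          rng: np.random.Generator | None = None):
    """AUC significance threshold from permuted labels.

    Labels are permuted ``n_perm`` times, the per-window LOO AUC recomputed,
    and the null values pooled across windows and permutations; the
    threshold is the (1 - alpha) quantile of the pooled null.

    Returns (threshold, null_aucs) with null_aucs of shape (n_perm, windows).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_perm < 1.0 / alpha:
        warnings.warn(f"{n_perm} permutations resolve p-values only down to "
                      f"{1.0 / n_perm:.3g} > alpha={alpha}", stacklevel=2)
    y = epochs.y_signed
    Fz, _, _ = _standardize(_window_features(epochs, grid))
    null = np.empty((n_perm, len(grid)))
    for b in range(n_perm):
        null[b] = loo_auc(Fz, rng.permutation(y), ridge=ridge)
    return float(np.quantile(null, 1.0 - alpha)), null


def erp_average(epochs: EEGEpochs, channel: int | str):
    """Per-condition stimulus-locked mean and standard error for one channel."""
    if isinstance(channel, str):
        if channel not in epochs.channel_names:
            raise KeyError(f"unknown channel {channel!r}")
        channel = epochs.channel_names.index(channel)
    out = {}
    for cond in ("oddball", "standard"):
        sel = epochs.labels == cond
        seg = epochs.data[sel, channel, :]
        n = max(int(sel.sum()), 1)
        out[cond] = {
            "mean": seg.mean(axis=0) if sel.any() else np.zeros(epochs.data.shape[2]),
            "sem": (seg.std(axis=0, ddof=1) / np.sqrt(n)
                    if sel.sum() > 1 else np.zeros(epochs.data.shape[2])),
        }
    out["times"] = epochs.times
    return out
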