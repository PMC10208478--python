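"""Pupillometry: blink cleaning, stimulus-locked epoching, and TEPR.

The task-evoked pupillary response (TEPR) is the maximum percent change of
pupil diameter within a trial relative to the pre-stimulus baseline; the mean
TEPR over oddball trials is the per-subject index of the phasic, pupil-linked
arousal response used in the brain-pupil correlation analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PupilTrace",
    "PupilEpochs",
    "TEPRTable",
    "preprocess_pupil",
    "epoch_pupil",
    "compute_tepr",
    "grand_average_pupil",
]

EPOCH_WINDOW = (-0.5, 2.0)  # seconds relative to stimulus onset


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter stream (eye-tracker units)."""

    diameter: np.ndarray
    fs: float = 1000.0
    blink_mask: np.ndarray | None = None
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.blink_mask is None:
            self.blink_mask = np.zeros(self.diameter.shape, dtype=bool)
        else:
            self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if self.blink_mask.shape != self.diameter.shape:
            raise ValueError("blink mask shape does not match diameter")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.diameter.size) / self.fs

    @property
    def duration(self) -> float:
        return self.diameter.size / self.fs


@dataclass
class PupilEpochs:
    """Stimulus-locked epochs over a fixed peri-stimulus window."""

    data: np.ndarray            # (trials, samples)
    labels: np.ndarray          # trial_type per retained trial
    baselines: np.ndarray       # mean diameter over the pre-stimulus interval
    fs: float
    window: tuple[float, float] = EPOCH_WINDOW
    dropped: list[int] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.window[0] + np.arange(n) / self.fs


@dataclass
class TEPRTable:
    """Per-trial TEPR (percent) and the per-subject oddball mean."""

    trials: pd.DataFrame        # columns: trial, trial_type, tepr
    subject_mean: float         # mean TEPR over oddball trials

    @property
    def oddball_teprs(self) -> np.ndarray:
        sel = self.trials["trial_type"] == "oddball"
        return self.trials.loc[sel, "tepr"].to_numpy()


def preprocess_pupil(trace: PupilTrace, blink_pad: float = 0.1,
                     lowpass_hz: float = 4.0) -> PupilTrace:
    """Interpolate blinks and low-pass filter a pupil trace.

    Blinks are taken as flagged or non-positive samples; the blink mask is
    padded by ``blink_pad`` seconds on both sides and the gap is linearly
    interpolated from the flanking valid samples before a zero-phase
    Butterworth low-pass (default 4 Hz) is applied.  A trace with more than
    half of its samples blinked is returned flagged as low quality.
    """
    if trace.fs <= 2.0 * lowpass_hz:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    d = trace.diameter.copy()
    bad = trace.blink_mask | (d <= 0) | ~np.isfinite(d)
    if bad.any():
        pad = int(round(blink_pad * trace.fs))
        if pad > 0:
            kernel = np.ones(2 * pad + 1)
            bad = np.convolve(bad.astype(float), kernel, mode="same") > 0
    low_quality = trace.low_quality
    if bad.mean() > 0.5:
        warnings.warn("more than 50% of pupil samples are blinked; "
                      "trace flagged as low quality", stacklevel=2)
        low_quality = True
    if bad.all():
        raise ValueError("no valid pupil samples to interpolate from")
    if bad.any():
        idx = np.arange(d.size)
        d[bad] = np.interp(idx[bad], idx[~bad], d[~bad])
    sos = signal.butter(4, lowpass_hz, btype="low", fs=trace.fs, output="sos")
    d = signal.sosfiltfilt(sos, d)
    return PupilTrace(diameter=d, fs=trace.fs, low_quality=low_quality)


def epoch_pupil(trace: PupilTrace, events: pd.DataFrame,
                window: tuple[float, float] = EPOCH_WINDOW) -> PupilEpochs:
    """Cut one epoch per trial; trials exceeding the trace are dropped.

    The per-trial baseline is the mean diameter over the pre-stimulus part of
    the window, [window[0], 0).
    """
    fs = trace.fs
    n_pre = int(round(-window[0] * fs))
    n_post = int(round(window[1] * fs))
    n_samp = n_pre + n_post        # half-open window [window[0], window[1])
    rows, labels, baselines, dropped = [], [], [], []
    for i, (onset, ttype) in enumerate(zip(events["onset"], events["trial_type"])):
        c = int(round(onset * fs))
        lo, hi = c - n_pre, c + n_post
        if lo < 0 or hi > trace.diameter.size:
            logger.info("trial %d dropped: epoch [%d, %d) outside trace", i, lo, hi)
            dropped.append(i)
            continue
        seg = trace.diameter[lo:hi]
        rows.append(seg)
        labels.append(ttype)
        baselines.append(seg[:n_pre].mean())
    data = np.asarray(rows).reshape(len(rows), n_samp)
    return PupilEpochs(data=data, labels=np.asarray(labels),
                       baselines=np.asarray(baselines), fs=fs,
                       window=window, dropped=dropped)


def compute_tepr(epochs: PupilEpochs) -> TEPRTable:
    """Maximum percent diameter change within each trial.

    TEPR = 100 * max over (0, window_end] of (diameter - baseline)/baseline.
    Trials with a non-positive baseline are excluded (logged).  The subject
    summary is the mean TEPR over oddball trials.
    """
    t = epochs.times
    post = t > 0
    rows = []
    for i, (seg, base, lab) in enumerate(
            zip(epochs.data, epochs.baselines, epochs.labels)):
        if base <= 0:
            logger.warning("trial %d excluded: non-positive baseline %.3g", i, base)
            continue
        tepr = 100.0 * np.max((seg[post] - base) / base)
        rows.append({"trial": i, "trial_type": lab, "tepr": tepr})
    trials = pd.DataFrame(rows, columns=["trial", "trial_type", "tepr"])
    odd = trials.loc[trials["trial_type"] == "oddball", "tepr"]
    subject_mean = float(odd.mean()) if len(odd) else float("nan")
    return TEPRTable(trials=trials, subject_mean=subject_mean)


def grand_average_pupil(epochs_per_subject: list[PupilEpochs],
                        alpha: float = 0.001):
    """Across-subject grand-average pupil curves with a pointwise contrast.

    Each subject's epochs are z-scored (single mean/SD over all samples of
    that subject), averaged within condition, then averaged across subjects.
    A per-sample two-sided paired t-test contrasts oddball vs standard, with
    samples flagged at ``p < alpha``.

    Returns a dict with condition means, standard errors, t, p, and flags.
    """
    if len(epochs_per_subject) < 2:
        raise ValueError("grand average requires at least 2 subjects")
    conds = ("oddball", "standard")
    per_subject = {c: [] for c in conds}
    for ep in epochs_per_subject:
        mu, sd = ep.data.mean(), ep.data.std()
        z = (ep.data - mu) / sd if sd > 0 else ep.data - mu
        for c in conds:
            sel = ep.labels == c
            if not sel.any():
                raise ValueError(f"subject missing condition {c!r}")
            per_subject[c].append(z[sel].mean(axis=0))
    curves = {c: np.asarray(v) for c, v in per_subject.items()}  # (subj, samp)
    n = len(epochs_per_subject)
    mean = {c: v.mean(axis=0) for c, v in curves.items()}
    sem = {c: v.std(axis=0, ddof=1) / np.sqrt(n) for c, v in curves.items()}
    diff = curves["oddball"] - curves["standard"]
    tval, pval = stats.ttest_1samp(diff, 0.0, axis=0)
    # constant-zero difference columns give nan; they carry no evidence
    pval = np.where(np.isnan(pval), 1.0, pval)
    tval = np.where(np.isnan(tval), 0.0, tval)
    return {
        "times": epochs_per_subject[0].times,
        "mean": mean,
        "sem": sem,
        "t": tval,
        "p": pval,
        "flags": pval < alpha,
    }
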