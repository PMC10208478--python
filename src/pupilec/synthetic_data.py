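"""Synthetic multimodal cohorts with known ground truth.

Generates everything the downstream stages consume — oddball event schedules,
continuous multichannel EEG driven by bilinear MVAR latent dynamics, pupil
traces with trial-locked dilations, and HRF-convolved ROI BOLD with nuisance
structure — so the full pipeline is testable without any recorded data.  The
defaults mirror an auditory oddball design: 80% standard / 20% oddball trials,
2-3 s uniform inter-trial intervals, 200 ms stimuli, the first five trials
standard and no two oddballs in a row, and pupil dilations peaking ~1.4 s
after the stimulus.

A cohort additionally plants a controlled across-subject correlation between
each subject's modulatory coupling gain (scaling B) and pupil response
amplitude, giving downstream brain-pupil correlation analyses a known target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .pupillometry import PupilTrace
from .ec_statespace import InputSet, build_inputs

__all__ = [
    "ParadigmSpec",
    "GroundTruthModel",
    "SyntheticRun",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_event_schedule",
    "validate_event_schedule",
    "simulate_latent_eeg",
    "simulate_pupil",
    "pupil_kernel",
    "simulate_bold_rois",
    "generate_cohort",
    "default_ground_truth",
    "recovery_ground_truth",
]


class InfeasibleScheduleError(ValueError):
    """The schedule constraints cannot be satisfied."""


# ---------------------------------------------------------------------------
# paradigm / ground-truth specifications
# ---------------------------------------------------------------------------

@dataclass
class ParadigmSpec:
    """Oddball paradigm layout (defaults follow the study design)."""

    n_trials_per_run: int = 105
    n_runs: int = 5
    n_subjects: int = 19
    oddball_fraction: float = 0.2
    iti_range: tuple[float, float] = (2.0, 3.0)
    stim_duration: float = 0.2
    first_k_standard: int = 5
    forbid_consecutive_oddballs: bool = True
    rng_seed: int = 0
    rt_mean: float = 0.4035
    rt_sd: float = 0.0669

    def __post_init__(self) -> None:
        if not 0.0 < self.oddball_fraction < 1.0:
            raise ValueError("oddball_fraction must be in (0, 1)")
        if self.iti_range[0] >= self.iti_range[1]:
            raise ValueError("iti_range must be (low, high) with low < high")

    @property
    def n_oddballs(self) -> int:
        return int(round(self.oddball_fraction * self.n_trials_per_run))


@dataclass
class GroundTruthModel:
    """Generating parameters for latent dynamics, EEG, pupil, and the cohort.

    ``A_true``/``B_true``/``D_true`` follow the bilinear MVAR state equation;
    ``leadfield_L`` and ``indicator_G`` define the EEG observation model.
    The generator draws source-level noise (precision ``source_noise_prec``)
    and channel noise (``obs_noise_prec``) separately, so estimators that
    absorb both into one observation noise are stress-tested.
    """

    n_nodes: int
    A_true: np.ndarray
    B_true: np.ndarray                # (K, n, n)
    D_true: np.ndarray                # (n,) diagonal input gains
    leadfield_L: np.ndarray           # channels x sources
    indicator_G: np.ndarray           # sources x nodes, binary
    state_noise_prec: float = 1.0
    obs_noise_prec: float = 25.0
    source_noise_prec: float = 400.0
    fs_state: float = 100.0
    eeg_fs_multiple: int = 1
    pupil_kernel_peak: float = 1.4
    pupil_amp_mean: float = 8.0       # percent, oddball trials
    pupil_amp_sd: float = 2.5
    coupling_gain_mean: float = 1.0
    coupling_gain_sd: float = 0.3
    planted_rho: float = 0.65
    pupil_noise_sd: float = 2.0       # a.u. at baseline 1000
    pupil_amp_by_subject: np.ndarray | None = None
    coupling_gain_by_subject: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A_true = np.asarray(self.A_true, dtype=float)
        self.B_true = np.asarray(self.B_true, dtype=float).reshape(
            -1, self.n_nodes, self.n_nodes)
        self.D_true = np.asarray(self.D_true, dtype=float).reshape(self.n_nodes)
        if not np.isin(self.indicator_G, (0, 1)).all():
            raise ValueError("indicator_G must be binary")
        if (np.asarray(self.indicator_G).sum(axis=0) < 1).any():
            raise ValueError("every node must map to at least one source")

    @property
    def n_modulatory(self) -> int:
        return self.B_true.shape[0]

    def spectral_radii(self, gain: float = 1.0):
        rad = lambda M: float(np.max(np.abs(np.linalg.eigvals(M))))
        return rad(self.A_true), rad(self.A_true + gain * self.B_true.sum(axis=0))

    def check_stable(self, gain: float = 1.0) -> None:
        r_a, r_ab = self.spectral_radii(gain)
        if r_a >= 1.0 or r_ab >= 1.0:
            raise ValueError(
                f"unstable ground truth: spectral radius A={r_a:.3f}, "
                f"A+sum(B)={r_ab:.3f} (gain {gain:.3f})")


@dataclass
class SyntheticRun:
    events: pd.DataFrame
    eeg: np.ndarray               # (T_eeg, channels)
    eeg_fs: float
    latent_states: np.ndarray     # (T_state, nodes)
    inputs: InputSet
    pupil: PupilTrace
    bold: np.ndarray              # (rois, volumes)
    nuisance: pd.DataFrame
    seed: int


@dataclass
class SyntheticSubject:
    subject_id: str
    coupling_gain: float
    pupil_amp: float
    runs: list[SyntheticRun]


@dataclass
class SyntheticCohort:
    paradigm: ParadigmSpec
    truth: GroundTruthModel
    subjects: list[SyntheticSubject]
    seed: int

    @property
    def coupling_gains(self) -> np.ndarray:
        return np.array([s.coupling_gain for s in self.subjects])

    @property
    def pupil_amps(self) -> np.ndarray:
        return np.array([s.pupil_amp for s in self.subjects])


# ---------------------------------------------------------------------------
# event schedules
# ---------------------------------------------------------------------------

def generate_event_schedule(spec: ParadigmSpec,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one run's event table under the paradigm constraints.

    Oddball count is round(fraction * n_trials); the first ``first_k_standard``
    trials are standard; optionally no two oddballs are adjacent; successive
    onsets are separated by stimulus duration plus a Uniform(iti_range) ITI.
    Oddball positions are drawn uniformly over all feasible position sets.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_trials_per_run
    n_odd = spec.n_oddballs
    free = n - spec.first_k_standard
    max_odd = (free + 1) // 2 if spec.forbid_consecutive_oddballs else free
    if n_odd > max_odd or free < 0:
        raise InfeasibleScheduleError(
            f"infeasible schedule: {n_odd} oddballs do not fit in {free} "
            f"free slots (consecutive oddballs "
            f"{'forbidden' if spec.forbid_consecutive_oddballs else 'allowed'})")
    if spec.forbid_consecutive_oddballs:
        # uniform non-adjacent subset via the gap bijection
        picks = np.sort(rng.choice(free - n_odd + 1, size=n_odd, replace=False))
        positions = spec.first_k_standard + picks + np.arange(n_odd)
    else:
        positions = spec.first_k_standard + np.sort(
            rng.choice(free, size=n_odd, replace=False))
    types = np.array(["standard"] * n, dtype=object)
    types[positions] = "oddball"

    itis = rng.uniform(*spec.iti_range, size=n)
    onsets = np.cumsum(itis + spec.stim_duration) - spec.stim_duration
    rts = np.full(n, np.nan)
    is_odd = types == "oddball"
    rts[is_odd] = np.clip(
        rng.normal(spec.rt_mean, spec.rt_sd, size=int(is_odd.sum())), 0.15, None)
    return pd.DataFrame({
        "onset": onsets,
        "duration": np.full(n, spec.stim_duration),
        "trial_type": types,
        "response_time": rts,
    })


def validate_event_schedule(events: pd.DataFrame, spec: ParadigmSpec) -> list[str]:
    """Independent constraint scan; returns a list of violation messages."""
    violations = []
    types = events["trial_type"].to_numpy()
    onsets = events["onset"].to_numpy()
    if len(events) != spec.n_trials_per_run:
        violations.append(f"trial count {len(events)} != {spec.n_trials_per_run}")
    n_odd = int((types == "oddball").sum())
    if n_odd != spec.n_oddballs:
        violations.append(f"oddball count {n_odd} != {spec.n_oddballs}")
    if (types[:spec.first_k_standard] != "standard").any():
        violations.append("oddball within the first constrained trials")
    if spec.forbid_consecutive_oddballs:
        adjacent = (types[:-1] == "oddball") & (types[1:] == "oddball")
        if adjacent.any():
            violations.append("consecutive oddballs at positions "
                              f"{np.flatnonzero(adjacent).tolist()}")
    if (np.diff(onsets) <= 0).any():
        violations.append("onsets not strictly increasing")
    gaps = np.diff(onsets) - spec.stim_duration
    lo, hi = spec.iti_range
    if ((gaps < lo - 1e-9) | (gaps > hi + 1e-9)).any():
        violations.append("inter-trial interval outside range")
    return violations


# ---------------------------------------------------------------------------
# latent dynamics and EEG
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simulate_states(A_pat, pat_idx, Du, noise):  # pragma: no cover
    T, n = noise.shape
    s = np.zeros((T, n))
    prev = np.zeros(n)
    for t in range(T):
        cur = A_pat[pat_idx[t]] @ prev + Du[t] + noise[t]
        s[t] = cur
        prev = cur
    return s


def simulate_latent_eeg(truth: GroundTruthModel, events: pd.DataFrame,
                        duration: float, rng: np.random.Generator | None = None,
                        coupling_gain: float = 1.0):
    """Simulate latent node states and continuous EEG for one run.

    States follow ``s_t = A s_{t-1} + sum_k gain*B^k m^k_t s_{t-1} + D u_t + w_t``
    at ``fs_state``; EEG is emitted at ``fs_state * eeg_fs_multiple`` by
    zero-order hold as ``L (G s_t + eps_t) + e_t`` with source noise ``eps``
    and channel noise ``e`` drawn per EEG sample.

    Returns (states, eeg, inputs).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    truth.check_stable(coupling_gain)
    if len(events) and float((events["onset"] + events["duration"]).max()) > duration:
        raise ValueError("duration does not cover all events")
    fs = truth.fs_state
    inputs = build_inputs(events, fs, duration=duration)
    T = inputs.exogenous.size
    n = truth.n_nodes
    K = truth.n_modulatory
    B = coupling_gain * truth.B_true

    m = inputs.modulatory
    codes = (m.T.astype(int) * (1 << np.arange(K))).sum(axis=1)
    pats = np.unique(codes)
    pat_idx = np.searchsorted(pats, codes)
    A_pat = np.stack([
        truth.A_true + sum(B[k] for k in range(K) if (int(c) >> k) & 1)
        if int(c) else truth.A_true.copy()
        for c in pats])
    Du = inputs.exogenous[:, None] * truth.D_true[None, :]
    state_sd = truth.state_noise_prec ** -0.5
    noise = rng.normal(0.0, state_sd, size=(T, n)) if state_sd > 0 else np.zeros((T, n))
    states = _simulate_states(A_pat, pat_idx.astype(np.int64), Du, noise)

    mult = int(truth.eeg_fs_multiple)
    held = np.repeat(states, mult, axis=0)
    L, G = truth.leadfield_L, np.asarray(truth.indicator_G, dtype=float)
    src = held @ G.T
    if np.isfinite(truth.source_noise_prec):
        src = src + rng.normal(0.0, truth.source_noise_prec ** -0.5, size=src.shape)
    eeg = src @ L.T
    if np.isfinite(truth.obs_noise_prec):
        eeg = eeg + rng.normal(0.0, truth.obs_noise_prec ** -0.5, size=eeg.shape)
    return states, eeg, inputs


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

def pupil_kernel(t: np.ndarray, peak: float = 1.4,
                 shape: float = 10.1) -> np.ndarray:
    """Unimodal gamma-family dilation kernel with unit peak at ``t = peak``.

    k(t) = (t/peak)^shape * exp(shape * (1 - t/peak)) for t >= 0, else 0.
    The unit-peak normalization makes a planted amplitude equal the TEPR of a
    noiseless isolated trial.  The shape default gives a physiologically
    plausible dilation width of a few hundred milliseconds at half maximum.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / peak
    out[pos] = r ** shape * np.exp(shape * (1.0 - r))
    return out


def simulate_pupil(events: pd.DataFrame, subject_amp: float,
                   kernel_peak: float = 1.4, baseline: float = 1000.0,
                   noise_sd: float = 0.0, fs: float = 1000.0,
                   duration: float | None = None,
                   standard_amp_fraction: float = 0.25,
                   rng: np.random.Generator | None = None,
                   blink_events: int = 0) -> PupilTrace:
    """Trial-locked pupil trace: baseline + per-trial dilations + noise.

    Oddball trials dilate by ``subject_amp`` percent of baseline; standard
    trials by ``standard_amp_fraction`` of that.  Optional blink gaps zero
    out short segments for preprocessing tests.
    """
    if fs <= 0 or kernel_peak <= 0:
        raise ValueError("fs and kernel_peak must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    if duration is None:
        duration = float(events["onset"].max()) + 4.0 if len(events) else 4.0
    t = np.arange(int(round(duration * fs))) / fs
    trace = np.full(t.size, float(baseline))
    for onset, ttype in zip(events["onset"], events["trial_type"]):
        amp_pct = subject_amp if ttype == "oddball" else \
            subject_amp * standard_amp_fraction
        trace += (amp_pct / 100.0 * baseline) * pupil_kernel(
            t - onset, peak=kernel_peak)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=trace.size)
    if blink_events > 0:
        blink_len = int(0.15 * fs)
        for start in rng.integers(0, max(trace.size - blink_len, 1),
                                  size=blink_events):
            trace[start:start + blink_len] = 0.0
    return PupilTrace(diameter=trace, fs=fs)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def simulate_nuisance(n_vols: int, rng: np.random.Generator,
                      motion_sd: float = 0.05,
                      tissue_sd: float = 1.0) -> pd.DataFrame:
    """Slow random-walk motion parameters plus WM/ventricle signals."""
    cols = {}
    for name in ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"):
        steps = rng.normal(0.0, motion_sd, size=n_vols)
        cols[name] = np.cumsum(steps)
    for name in ("white_matter", "ventricles"):
        cols[name] = rng.normal(0.0, tissue_sd, size=n_vols)
    return pd.DataFrame(cols)


def simulate_bold_rois(events: pd.DataFrame, stv: np.ndarray,
                       betas: pd.DataFrame, tr: float = 2.1,
                       n_vols: int = 150, noise_sd: float = 0.0,
                       nuisance: pd.DataFrame | None = None,
                       nuisance_betas: np.ndarray | None = None,
                       tau: float = 0.375,
                       rng: np.random.Generator | None = None):
    """ROI BOLD series from the task design plus nuisance and white noise.

    The design is built by the fMRI design module at high temporal resolution,
    HRF-convolved and sampled at TR; each ROI's series is design @ betas for
    the named regressors (rows of ``betas`` are ROIs, columns regressor
    names), plus optional nuisance contributions and Gaussian noise.

    Returns (bold, nuisance) with bold of shape (rois, volumes).
    """
    from .fmri_design_glm import HRFSpec, build_design
    if tr <= 0:
        raise ValueError("tr must be positive")
    if len(events) and n_vols * tr < float(events["onset"].max()):
        raise ValueError("n_vols * tr does not cover the events")
    if rng is None:
        rng = np.random.default_rng(0)
    design = build_design(events, stv=stv, confounds=None, tr=tr,
                          n_vols=n_vols, hrf=HRFSpec(), tau=tau,
                          include_derivatives=False)
    X = design.matrix
    bold = np.zeros((len(betas), n_vols))
    for name in betas.columns:
        if name not in X.columns:
            raise KeyError(f"beta refers to unknown regressor {name!r}")
        bold += np.outer(betas[name].to_numpy(), X[name].to_numpy())
    if nuisance is None:
        nuisance = simulate_nuisance(n_vols, rng)
    if nuisance_betas is not None:
        bold += np.asarray(nuisance_betas) @ nuisance.to_numpy().T
    if noise_sd > 0:
        bold += rng.normal(0.0, noise_sd, size=bold.shape)
    return bold, nuisance


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def default_ground_truth(n_nodes: int = 4, n_channels: int = 8,
                         seed: int = 0, planted_rho: float = 0.65,
                         late_nodes: tuple[int, ...] | None = None,
                         **overrides) -> GroundTruthModel:
    """A stable ground-truth model with a positive late-to-early oddball block.

    Nodes are split into an early half and a late half (mirroring early-time
    vs late-time salience networks); the oddball modulatory matrix carries
    positive couplings from late to early nodes, so cohort-level analyses
    have a known late-to-early network strength to recover.
    """
    rng = np.random.default_rng(seed)
    n = n_nodes
    if late_nodes is None:
        late_nodes = tuple(range(n // 2, n))
    early = [i for i in range(n) if i not in late_nodes]
    A = 0.5 * np.eye(n) + rng.uniform(-0.08, 0.08, size=(n, n))
    B_odd = np.zeros((n, n))
    for i in early:
        for j in late_nodes:
            B_odd[i, j] = rng.uniform(0.15, 0.3)
    B_odd[np.arange(n), np.arange(n)] += rng.uniform(-0.1, 0.0, size=n)
    B_std = np.zeros((n, n))
    B_std[np.arange(n), np.arange(n)] = rng.uniform(-0.05, 0.05, size=n)
    D = rng.uniform(0.3, 0.6, size=n)
    L = rng.normal(0.0, 1.0, size=(n_channels, n))
    G = np.eye(n)
    truth = GroundTruthModel(
        n_nodes=n, A_true=A, B_true=np.stack([B_odd, B_std]), D_true=D,
        leadfield_L=L, indicator_G=G, planted_rho=planted_rho, **overrides)
    # leave stability margin for the largest plausible subject gain
    max_gain = truth.coupling_gain_mean + 3.5 * truth.coupling_gain_sd
    for _ in range(100):
        _, r_ab = truth.spectral_radii(max_gain)
        if r_ab < 0.98 and truth.spectral_radii()[0] < 0.98:
            break
        truth.A_true *= 0.97
        truth.B_true *= 0.97
    truth.check_stable(max_gain)
    return truth


def recovery_ground_truth(n_nodes: int = 5, n_channels: int = 10,
                          seed: int = 0, snr: float = 5.0,
                          all_null: bool = False,
                          **overrides) -> GroundTruthModel:
    """Ground truth for parameter-recovery simulations.

    Couplings are sparse with clearly nonzero magnitudes (>= 0.1), so sign
    agreement is well defined.  The observation noise precision is calibrated
    so the per-channel signal-to-noise ratio of the noise-driven latent
    signal equals ``snr`` (via the stationary state covariance from the
    discrete Lyapunov equation).  ``all_null`` zeroes every coupling for
    false-positive calibration.
    """
    from scipy.linalg import solve_discrete_lyapunov
    rng = np.random.default_rng(seed)
    n = n_nodes
    if all_null:
        A = np.zeros((n, n))
        B = np.zeros((2, n, n))
        D = np.zeros(n)
    else:
        A = 0.5 * np.eye(n)
        off = [(i, j) for i in range(n) for j in range(n) if i != j]
        rng.shuffle(off)
        for i, j in off[:max(n, len(off) // 3)]:
            A[i, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 0.2)
        B_odd = np.zeros((n, n))
        picks = [(i, j) for i in range(n) for j in range(n)]
        rng.shuffle(picks)
        for i, j in picks[:n]:
            B_odd[i, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.15, 0.3)
        B_std = np.zeros((n, n))
        B_std[np.arange(n), np.arange(n)] = -rng.uniform(0.1, 0.15, size=n)
        B = np.stack([B_odd, B_std])
        for _ in range(100):
            r = max(np.max(np.abs(np.linalg.eigvals(A))),
                    np.max(np.abs(np.linalg.eigvals(A + B.sum(axis=0)))))
            if r < 0.93:
                break
            A *= 0.95
            B *= 0.95
        D = rng.uniform(0.3, 0.6, size=n)
    L = rng.normal(0.0, 1.0, size=(n_channels, n))
    G = np.eye(n)
    state_var = 1.0
    base = A if not all_null else np.zeros((n, n))
    Sigma = solve_discrete_lyapunov(base, state_var * np.eye(n))
    H = L @ G
    signal_power = float(np.mean(np.diag(H @ Sigma @ H.T)))
    obs_prec = snr ** 2 / signal_power
    return GroundTruthModel(
        n_nodes=n, A_true=A, B_true=B, D_true=D, leadfield_L=L,
        indicator_G=G, state_noise_prec=1.0 / state_var,
        obs_noise_prec=obs_prec, source_noise_prec=np.inf, **overrides)


def draw_subject_effects(truth: GroundTruthModel, n_subjects: int,
                         rng: np.random.Generator):
    """Bivariate-Gaussian (coupling gain, pupil amplitude) with planted rho.

    Gains are clipped to +-3.5 SD to preserve simulation stability; the clip
    is essentially never active at the default SDs.
    """
    rho = truth.planted_rho
    if not -1.0 < rho < 1.0:
        raise ValueError("planted_rho must be in (-1, 1)")
    cov = np.array([[1.0, rho], [rho, 1.0]])
    zs = rng.multivariate_normal(np.zeros(2), cov, size=n_subjects,
                                 method="cholesky")
    zs = np.clip(zs, -3.5, 3.5)
    gains = truth.coupling_gain_mean + truth.coupling_gain_sd * zs[:, 0]
    amps = np.maximum(truth.pupil_amp_mean + truth.pupil_amp_sd * zs[:, 1], 0.5)
    return gains, amps


def generate_cohort(spec: ParadigmSpec, truth: GroundTruthModel,
                    seed: int | None = None,
                    with_bold: bool = True) -> SyntheticCohort:
    """Generate a full multimodal cohort with planted brain-pupil coupling.

    Per subject, a (coupling gain, pupil amplitude) pair is drawn from a
    bivariate Gaussian with correlation ``truth.planted_rho``; the subject's
    modulatory matrices are scaled by the gain and every modality is
    generated per run.  Deterministic given the seed.
    """
    if spec.n_subjects < 3:
        raise ValueError("need at least 3 subjects for downstream correlation")
    if seed is None:
        seed = spec.rng_seed
    root = np.random.default_rng(seed)
    gains, amps = draw_subject_effects(truth, spec.n_subjects, root)
    if truth.coupling_gain_by_subject is not None:
        gains = np.asarray(truth.coupling_gain_by_subject, dtype=float)
    if truth.pupil_amp_by_subject is not None:
        amps = np.asarray(truth.pupil_amp_by_subject, dtype=float)
    truth = replace(truth, coupling_gain_by_subject=gains,
                    pupil_amp_by_subject=amps)
    tr, n_vols = 2.1, 150
    subjects = []
    for s in range(spec.n_subjects):
        runs = []
        for r in range(spec.n_runs):
            run_seed = int(root.integers(2 ** 31))
            rng = np.random.default_rng(run_seed)
            events = generate_event_schedule(spec, rng=rng)
            duration = float(events["onset"].iloc[-1]) + 3.5
            states, eeg, inputs = simulate_latent_eeg(
                truth, events, duration, rng=rng, coupling_gain=gains[s])
            pupil = simulate_pupil(
                events, subject_amp=amps[s], kernel_peak=truth.pupil_kernel_peak,
                noise_sd=truth.pupil_noise_sd, duration=duration, rng=rng)
            if with_bold:
                nv = max(n_vols, int(np.ceil(duration / tr)) + 2)
                stv = rng.normal(size=len(events))
                stv -= stv.mean()
                betas = pd.DataFrame(
                    {"event_oddball": np.full(truth.n_nodes, 1.0),
                     "event_standard": np.full(truth.n_nodes, 0.3)})
                bold, nuis = simulate_bold_rois(
                    events, stv=stv, betas=betas, tr=tr, n_vols=nv,
                    noise_sd=1.0, rng=rng)
            else:
                bold = np.zeros((truth.n_nodes, 0))
                nuis = pd.DataFrame()
            runs.append(SyntheticRun(
                events=events, eeg=eeg,
                eeg_fs=truth.fs_state * truth.eeg_fs_multiple,
                latent_states=states, inputs=inputs, pupil=pupil,
                bold=bold, nuisance=nuis, seed=run_seed))
        subjects.append(SyntheticSubject(
            subject_id=f"sub-{s + 1:02d}", coupling_gain=float(gains[s]),
            pupil_amp=float(amps[s]), runs=runs))
    return SyntheticCohort(paradigm=spec, truth=truth, subjects=subjects,
                           seed=seed)
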