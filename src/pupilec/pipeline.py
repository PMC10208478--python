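"""End-to-end drivers: in-memory cohort analysis and the disk pipeline.

``analyze_cohort`` runs the claim-bearing chain on a synthetic cohort held in
memory: pupil preprocessing -> TEPR, per-run variational-Bayes effective
connectivity -> per-subject Bayesian parameter averaging -> network coupling
strength -> across-subject Pearson correlation with TEPR.  ``run_pipeline``
executes every stage (including the EEG discriminant, the STV-informed GLM
and functional connectivity) over serialized run bundles and writes a results
tree with the effective configuration, seeds, and exclusions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (ec_statespace, eeg_discriminant, fmri_connectivity,
               fmri_design_glm, group_inference, pupillometry, synthetic_data)
from .config import Config
from .io import RunBundle, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["analyze_cohort", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


def _subject_tepr(runs, blink_pad=0.1, lowpass_hz=4.0):
    """Pool TEPR trials over a subject's runs; returns (mean TEPR, median RT)."""
    teprs, rts = [], []
    for run in runs:
        clean = pupillometry.preprocess_pupil(run.pupil, blink_pad=blink_pad,
                                              lowpass_hz=lowpass_hz)
        epochs = pupillometry.epoch_pupil(clean, run.events)
        table = pupillometry.compute_tepr(epochs)
        teprs.append(table.oddball_teprs)
        rts.append(run.events["response_time"].dropna().to_numpy())
    return float(np.mean(np.concatenate(teprs))), float(
        np.median(np.concatenate(rts)))


def _ec_spec_for(truth, cfg_kwargs=None) -> ec_statespace.ECModelSpec:
    kwargs = dict(fit_fs=truth.fs_state)
    if cfg_kwargs:
        kwargs.update(cfg_kwargs)
    return ec_statespace.ECModelSpec(
        node_names=[f"node{i}" for i in range(truth.n_nodes)],
        leadfield=truth.leadfield_L, indicator=truth.indicator_G, **kwargs)


def analyze_cohort(cohort: synthetic_data.SyntheticCohort,
                   from_nodes=None, to_nodes=None, sign: str = "+",
                   modulatory_index: int = 0, ec_kwargs: dict | None = None,
                   alternative: str = "two-sided") -> dict:
    """Recover the planted brain-pupil association from a synthetic cohort.

    Per subject: mean oddball TEPR; per run: VB effective-connectivity fit
    (non-converged runs excluded, as in the run-exclusion rule); per subject:
    BPA over converged runs, then the oddball-modulatory network strength of
    the ``from_nodes -> to_nodes`` block.  Returns the across-subject
    correlation, its RT/ELBO-controlled variant, and the pooled between-run
    variant, with all intermediate quantities.
    """
    truth = cohort.truth
    n = truth.n_nodes
    if to_nodes is None:
        to_nodes = [i for i in range(n) if i < n // 2]     # early half
    if from_nodes is None:
        from_nodes = [i for i in range(n) if i >= n // 2]  # late half
    spec = _ec_spec_for(truth, ec_kwargs)
    strengths, teprs, rt_medians, elbo_means = [], [], [], []
    run_points = []
    excluded = []
    for subject in cohort.subjects:
        tepr, rt_med = _subject_tepr(subject.runs)
        posts = []
        for r, run in enumerate(subject.runs):
            post = ec_statespace.vb_fit(run.eeg, run.inputs, spec)
            if not post.converged:
                excluded.append((subject.subject_id, r, post.failure_reason))
                logger.warning("%s run %d excluded: %s", subject.subject_id,
                               r, post.failure_reason)
                continue
            posts.append(post)
            run_points.append((group_inference.network_strength(
                post.B_mean[modulatory_index], from_nodes, to_nodes, sign),
                tepr))
        if not posts:
            continue
        combined = group_inference.bpa_ec(posts)
        strengths.append(group_inference.network_strength(
            combined.B_mean[modulatory_index], from_nodes, to_nodes, sign))
        teprs.append(tepr)
        rt_medians.append(rt_med)
        elbo_means.append(float(np.mean([p.mean_elbo for p in posts])))
    strengths = np.asarray(strengths)
    teprs = np.asarray(teprs)
    corr = group_inference.brain_pupil_correlation(
        strengths, teprs, alternative=alternative)
    corr_ctrl = group_inference.brain_pupil_correlation(
        strengths, teprs,
        controls={"rt_median": np.asarray(rt_medians),
                  "elbo_mean": np.asarray(elbo_means)},
        alternative=alternative)
    rp = np.asarray(run_points)
    corr_runs = group_inference.brain_pupil_correlation(
        rp[:, 0], rp[:, 1], level="between-run", alternative=alternative) \
        if len(rp) >= 3 else None
    return {
        "correlation": corr,
        "correlation_controlled": corr_ctrl,
        "correlation_between_run": corr_runs,
        "strengths": strengths,
        "teprs": teprs,
        "excluded_runs": excluded,
        "true_gains": cohort.coupling_gains,
        "true_amps": cohort.pupil_amps,
    }


# ---------------------------------------------------------------------------
# disk pipeline
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(f"[{name}] {err}") from err
        return wrapped
    return deco


@_stage("pupil")
def _pupil_stage(data, cfg: Config):
    clean = pupillometry.preprocess_pupil(
        pupillometry.PupilTrace(diameter=data["pupil"], fs=data["pupil_fs"]),
        blink_pad=cfg.pupil.blink_pad, lowpass_hz=cfg.pupil.lowpass_hz)
    epochs = pupillometry.epoch_pupil(clean, data["events"],
                                      window=cfg.pupil.epoch_window)
    return pupillometry.compute_tepr(epochs)


@_stage("discriminant")
def _discriminant_stage(data, cfg: Config, rng):
    d = cfg.discriminant
    grid = eeg_discriminant.WindowGrid(
        width_ms=d.window_width_ms, start_ms=d.window_start_ms,
        stop_ms=d.window_stop_ms, step_ms=d.window_step_ms)
    epochs = eeg_discriminant.epoch_continuous(
        data["eeg"], data["eeg_fs"], data["events"])
    result = eeg_discriminant.fit_window_discriminant(epochs, grid,
                                                      ridge=d.ridge)
    result.auc = eeg_discriminant.loo_auc_curve(epochs, grid, ridge=d.ridge)
    result.threshold, result.null_aucs = eeg_discriminant.permutation_threshold(
        epochs, grid, n_perm=d.n_permutations, alpha=d.alpha, ridge=d.ridge,
        rng=rng)
    return result


@_stage("glm")
def _glm_stage(data, stv, cfg: Config):
    n_vols = data["bold"].shape[1]
    design = fmri_design_glm.build_design(
        data["events"], stv=stv, confounds=data["nuisance"], tr=cfg.glm.tr,
        n_vols=n_vols, tau=cfg.glm.tau, stv_duration=cfg.glm.stv_duration)
    return design, fmri_design_glm.fit_glm(data["bold"], design)


@_stage("fc")
def _fc_stage(data, design, cfg: Config):
    nuis = data["nuisance"]
    nuisance24 = fmri_connectivity.nuisance_design_24(
        nuis.iloc[:, :6], nuis["white_matter"], nuis["ventricles"])
    task = design.matrix[["event_oddball", "event_standard"]].to_numpy()
    resid = fmri_connectivity.residualize_series(data["bold"], nuisance24, task)
    return (fmri_connectivity.fc_matrix(resid),
            fmri_connectivity.tsnr(data["bold"]))


@_stage("ec")
def _ec_stage(data, truth, cfg: Config):
    spec = _ec_spec_for(truth, dict(
        fit_fs=cfg.ec.fit_fs,
        coupling_prior_precision=cfg.ec.coupling_prior_precision,
        noise_prior_shape=cfg.ec.noise_prior_shape,
        noise_prior_rate=cfg.ec.noise_prior_rate,
        obs_prior_shape=cfg.ec.obs_prior_shape,
        obs_prior_rate=cfg.ec.obs_prior_rate,
        max_iter=cfg.ec.max_iter, elbo_tol=cfg.ec.elbo_tol))
    return ec_statespace.vb_fit(data["eeg"], data["events"], spec)


def run_pipeline(config: Config, bundles: list[RunBundle] | None,
                 outdir: str | Path,
                 truth: synthetic_data.GroundTruthModel | None = None) -> dict:
    """Run every stage over the given bundles and write a results tree.

    With ``config.simulate`` and no bundles, a synthetic cohort is generated
    first and serialized under ``outdir/data``.  Stage outputs land under
    ``outdir`` as TSV/JSON with the effective config, seeds, and excluded
    runs recorded; any stage failure aborts with a stage-tagged error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    rng = np.random.default_rng(config.seed)
    if bundles is None:
        if not config.simulate:
            raise PipelineError("[setup] no bundles given and simulate=False")
        p = config.paradigm
        spec = synthetic_data.ParadigmSpec(
            n_trials_per_run=p.n_trials_per_run, n_runs=p.n_runs,
            n_subjects=p.n_subjects, oddball_fraction=p.oddball_fraction,
            iti_range=p.iti_range, stim_duration=p.stim_duration,
            first_k_standard=p.first_k_standard,
            forbid_consecutive_oddballs=p.forbid_consecutive_oddballs,
            rng_seed=config.seed)
        truth = truth or synthetic_data.default_ground_truth(
            n_nodes=config.n_nodes, seed=config.seed)
        cohort = synthetic_data.generate_cohort(spec, truth, seed=config.seed)
        bundles = write_cohort(cohort, outdir / "data")
    if truth is None:
        raise PipelineError("[setup] a ground-truth model (for node/leadfield "
                            "definitions) is required with external bundles")
    if not bundles:
        raise PipelineError("[setup] empty bundle list")

    by_subject: dict[str, list] = {}
    records = []
    excluded = []
    for bundle in bundles:
        data = bundle.load()
        tepr = _pupil_stage(data, config)
        disc = _discriminant_stage(data, config, rng)
        stv = disc.stv(config.glm.tau * 1000.0)
        design, glm = _glm_stage(data, stv, config)
        fc, ts = _fc_stage(data, design, config)
        ec = _ec_stage(data, truth, config)
        if not ec.converged:
            excluded.append({"subject": bundle.subject_id, "run": bundle.run_id,
                             "reason": ec.failure_reason})
        rec = {
            "subject": bundle.subject_id, "run": bundle.run_id,
            "seed": bundle.seed,
            "tepr_mean": tepr.subject_mean,
            "rt_median": float(data["events"]["response_time"].median()),
            "auc_max": float(np.max(disc.auc)),
            "auc_threshold": disc.threshold,
            "glm_stv_oddball_beta": float(
                glm.betas["stv_oddball"].mean())
            if "stv_oddball" in glm.betas else float("nan"),
            "tsnr_min": float(np.min(ts["tsnr"])),
            "ec_converged": bool(ec.converged),
            "ec_elbo_final": float(ec.elbo_trace[-1]),
        }
        records.append(rec)
        by_subject.setdefault(bundle.subject_id, []).append((bundle, ec, tepr, fc))

    # group stage: BPA per subject, network strengths, brain-pupil correlation
    n = truth.n_nodes
    early = list(range(n // 2))
    late = list(range(n // 2, n))
    strengths, teprs = [], []
    z_stack = []
    for sid, items in by_subject.items():
        posts = [ec for _, ec, _, _ in items if ec.converged]
        if not posts:
            continue
        combined = group_inference.bpa_ec(posts)
        strengths.append(group_inference.network_strength(
            combined.B_mean[0], late, early, "+"))
        teprs.append(float(np.mean([t.subject_mean for _, _, t, _ in items])))
        z_stack.append(np.mean([fc.z for _, _, _, fc in items], axis=0))
    results = {"runs": records, "excluded_runs": excluded,
               "n_subjects": len(strengths)}
    if len(strengths) >= 3:
        corr = group_inference.brain_pupil_correlation(
            np.asarray(strengths), np.asarray(teprs))
        results["correlation"] = {"r": corr.r, "p": corr.p, "n": corr.n}
        fc_group = fmri_connectivity.group_fc_test(np.asarray(z_stack))
        results["fc_group_mean_t"] = float(np.mean(np.abs(fc_group["t"])))

    pd.DataFrame(records).to_csv(outdir / "run_summary.tsv", sep="\t",
                                 index=False)
    (outdir / "results.json").write_text(json.dumps(results, indent=2))
    return results
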