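# Methods

`pupilec` reimplements, as a tested pipeline on synthetic data, the analysis
chain of a simultaneous pupillometry–EEG–fMRI auditory-oddball experiment:
single-trial EEG discrimination, EEG-informed fMRI GLMs, ROI functional
connectivity, state-space effective connectivity with group-level Bayesian
parameter averaging, and the correlation of network coupling strength with
the task-evoked pupillary response (TEPR). This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic benchmarks do and do not establish about real recordings.

## Paradigm and synthetic data

The generator emulates an auditory oddball design: runs of 105 trials (80%
standard, 20% oddball, so 21 oddballs per run), 200 ms stimuli, inter-trial
intervals drawn from Uniform(2, 3) s, the first five trials constrained to be
standard, and no two consecutive oddballs. Oddball positions are sampled
uniformly over all feasible position sets via the gap bijection for
non-adjacent subsets, so the scheduler has no positional bias beyond the
constraints. Response times for oddballs are drawn from N(403.5, 66.9²) ms,
truncated below at 150 ms, matching the behavioral summary of the design
being emulated. An infeasible constraint set (e.g., more oddballs than
non-adjacent slots) raises rather than silently truncating.

### Latent dynamics and EEG

Node activity follows a bilinear (input-modulated) first-order MVAR process:

    s_t = A s_{t-1} + Σ_k B^k m^k_t s_{t-1} + D u_t + ω_t

with K = 2 modulatory inputs — unit-height boxcars over oddball and standard
stimuli — a shared exogenous stimulus boxcar u_t with diagonal gain D, and
Gaussian state noise ω_t. EEG is generated through a linear forward model
y_t = L(G s_t + ε_t) + e_t, where G is a binary source-to-node indicator and
L a lead field. The generator draws source noise ε and channel noise e
separately even though the estimator absorbs both into a single observation
noise, deliberately stress-testing that approximation. States are simulated
at `fs_state` = 100 Hz; EEG can be emitted at any integer multiple by
zero-order hold (the default 1× keeps benchmarks desk-scale; the estimator
resamples to 100 Hz regardless, since slow couplings carry no information at
kHz rates).

### Pupil

Each trial adds a dilation kernel k(t) = (t/p)^s · exp(s(1 − t/p)) with mode
p = 1.4 s (the empirical post-stimulus peak latency for oddball dilations)
and shape s = 10.1, a standard pupillary-response shape parameter. The
kernel is normalized to unit peak so that a planted amplitude of a% of
baseline yields a TEPR of exactly a% on a noiseless isolated trial — this is
what makes the TEPR exactness benchmark meaningful. Standard trials dilate
at 25% of the oddball amplitude (configurable); baseline is 1000 a.u. with
additive Gaussian noise of 2 a.u. by default.

### BOLD

ROI BOLD series are built from the same design-matrix code used by the
analysis (high-resolution boxcars convolved with the canonical double-gamma
HRF, sampled at TR = 2.1 s, 150 volumes ≈ 315 s), multiplied by planted
betas, plus random-walk motion parameters, white-matter/ventricle signals,
and white noise.

### Cohorts and the planted brain–pupil coupling

Per subject, a (coupling gain, pupil amplitude) pair is drawn from a
bivariate Gaussian with correlation `planted_rho` (default 0.65, the
magnitude of the strongest between-subject brain–pupil correlation in the
study being emulated). The gain scales the subject's modulatory matrices
B^k; the amplitude sets the subject's oddball TEPR. Gains are clipped at
±3.5 SD because extreme tails would destabilize the bilinear dynamics; the
clip is essentially never active at the default SD of 0.3. The default
4-node ground truth places positive oddball-modulated couplings from the
"late" node set to the "early" node set, mirroring the late-to-early
(salience-to-attention) feedback structure the network-strength analysis is
designed to detect.

What the generator does **not** emulate: MR gradient and ballistocardiogram
artifacts in EEG, head-motion coupling between modalities, blink/saccade
dynamics beyond simple gap insertion, spatially extended sources,
physiological (cardiac/respiratory) BOLD structure, or scanner drift.
Passing benchmarks therefore establish correctness of the estimators under
the model class, not robustness to those real-world artifacts.

## Pupillometry

Blinks are defined as flagged or non-positive samples, padded by ±100 ms and
linearly interpolated from flanking valid samples; a zero-phase 4th-order
Butterworth low-pass at 4 Hz follows. These are field-standard defaults;
the upstream description leaves them open, and all are configurable. A
trace with more than half of its samples blinked is flagged low-quality
rather than rejected. Epochs span [−0.5, 2.0) s around stimulus onset
(half-open, so a 1 kHz epoch has exactly 2500 samples); the baseline is the
mean over [−0.5, 0) s. TEPR is the maximum percent change relative to
baseline over the post-stimulus part of the window; with ITIs ≥ 2 s the
window cannot overlap the next trial's response peak. The subject-level
value is the mean TEPR over oddball trials.

## Sliding-window EEG discriminant

For each 50 ms window centered at τ ∈ {0, 25, …, 1000} ms, channel samples
are window-averaged (mathematically identical to averaging the projected
samples, and cheaper) and a logistic regression learns weights w(τ)
separating oddball from standard trials. The fit uses a small ridge penalty
(1.0 on standardized features, intercept unpenalized) purely for stability
on separable data; weights are mapped back to the raw channel scale. The
per-trial components d_i(τ) = w(τ)ᵀ·ȳ_i are demeaned to d̃_i(τ) before use
as fMRI modulators. No class reweighting is applied despite the 80/20
imbalance (the upstream analysis is silent on it; AUC is rank-based and
prevalence-free).

Window quality is the leave-one-out cross-validated AUC (Mann–Whitney with
ties counted ½). The significance threshold pools 100 label permutations
across all 41 windows and takes the 0.99 quantile. A caveat documented by
the tests: LOO scoring is pessimistically biased under the null (each
left-out trial is scored by a model trained slightly against it), so
individual null-window AUCs can fall well below 0.5; the permutation null
shares exactly this bias, which is what keeps the threshold calibrated
(measured exceedance ≈ 1% at α = 0.01).

## EEG-informed fMRI design and GLM

Regressors are built on a 10 ms grid, convolved with the canonical
double-gamma HRF (delays 6/16 s, dispersions 1/1 s, undershoot ratio 1/6,
32 s support, peak-normalized) and sampled at TR: unit-height oddball and
standard event boxcars; an RT regressor (unit height, duration = per-trial
response time) residualized against the oddball event regressor; and
oddball/standard STV regressors (onset τ, duration 100 ms, height d̃_i(τ)),
each residualized against its event regressor, the oddball one additionally
against RT. Orthogonalization is sequential OLS projection in that printed
order; the recorded provenance is verifiable as zero inner products.
Temporal derivatives are first differences of the convolved regressors;
confounds enter as given. Identically zero STV regressors (d̃ ≡ 0) are
dropped with a warning rather than passed to a singular fit.

ROI-wise fitting is ordinary least squares with exact t statistics and
normal-quantile z values; no prewhitening is applied (white noise is exact
for the generator, and the benchmarks verify the analytic SEs to within
10%). Group inference is a one-sample t-test across subjects — a deliberate
ROI-scale replacement for voxelwise mixed-effects modeling with
random-field cluster correction, which is out of scope.

## Functional connectivity

BOLD nuisance removal uses the 24-parameter motion model (6 parameters,
their backward-difference derivatives, and the squares of those 12) plus
white-matter and ventricle signals; task-evoked variance (both event
regressors) is regressed out before correlation so FC reflects background
coupling. Pearson correlations are Fisher z-transformed; per-subject maps
are gated at p < 0.01 (t transform with T−2 dof — the upstream method is
unstated, this is the standard choice) before elementwise one-sample
t-tests at the group level, reported at p < 0.001 (seed maps) and p < 0.05
(node-by-node). tSNR is mean over SD with a quality cutoff of 30.

## State-space effective connectivity

The estimator is the core of the package. The latent model is the same
bilinear MVAR state equation; sources are collapsed into an effective
observation matrix H = L·G with one combined observation-noise precision
(absorbing e and L·ε — the source-noise precision is therefore not
separately identified, by design). One latent state per node, MVAR order 1.

Inference is mean-field variational Bayes with factorization
q(s_{1:T}) · Π_i q(w_i) · Π_i q(λ_i) · q(λ_y), where w_i is row i of
[A | B¹…B^K | D], λ_i its state-noise precision, λ_y the observation-noise
precision. All updates are conjugate and closed-form:

- **State update.** The exact mean-field update of q(s) is a Gaussian
  Markov chain whose natural parameters include the parameter-covariance
  correction E[WᵀΛW] = Σ_i E[λ_i](w̄_iw̄_iᵀ + Σ_{w_i}). The chain is solved
  in information form: block-tridiagonal forward elimination, back-
  substitution, and the Takahashi recursions for marginal and lag-one
  covariances, plus the log-determinant needed for the chain entropy
  (numba-compiled; O(T·n³)). The public fixed-parameter smoother is the
  same backbone without the covariance correction and is verified against
  brute-force conditioning of the full joint Gaussian.
- **Coupling rows.** Gaussian with precision αI + E[λ_i]·ΣE[z_tz_tᵀ], where
  z_t stacks [s_{t−1}; m¹_t s_{t−1}; …; u_t] and the moments use the exact
  smoothed second and lag-one moments. The prior is zero-mean Gaussian
  with precision α (default 1.0 — weakly informative at desk-scale run
  lengths).
- **Precisions.** Gamma updates with priors Gamma(0.01, 0.01) (mean 1,
  vague).

Because every sweep is exact coordinate ascent, the evidence lower bound is
non-decreasing; this is asserted to 1e−8 relative tolerance in the tests,
and on a single-step conjugate toy the converged ELBO equals the exact log
marginal likelihood. Initialization: A = 0.9·I, B = D = 0, precisions at
prior means, parameter covariance at the prior — stable and unbiased toward
modulation. Convergence: relative ΔELBO < 1e−6, max 200 iterations. A run
fails (and is excluded downstream, mirroring the run-exclusion rule of the
emulated study) on a non-finite ELBO, an ELBO decrease beyond 1e−6 relative
on three consecutive iterations, or non-convergence.

Known limitation: on very short runs the mean-field posterior is mildly
overconfident (the q(s)·q(W) factorization ignores their correlation). At
20 s runs the 95% null z-quantile is ≈ 2.04 rather than 1.96 and the
Bonferroni family-wise error measures ≈ 0.09; at 80 s it is ≈ 0.02, and the
study-scale regime (~280 s runs) is comfortably calibrated. The null
calibration benchmark therefore uses 80 s runs.

## Group inference and brain–pupil correlation

Run posteriors are combined per row by Bayesian parameter averaging: the
product of Gaussians divided by the (K−1)-times over-counted prior,
Λ = ΣΛ_i − (K−1)Λ₀, μ = Λ⁻¹(ΣΛ_iμ_i − (K−1)Λ₀μ₀). BPA is exact (verified
against a grid density-product oracle), associative, and order-invariant.
Per-subject parameters are the BPA of that subject's converged runs — the
same operator as the group stage, chosen for consistency since the upstream
description does not state the per-subject aggregation.

Significance: a coupling is flagged when the posterior probability of the
opposite sign is below (α/m)/2 with α = 0.05 and m defaulting to all A and
B entries (n²(K+1)). Strengths: a node's total connection strength sums the
unsigned afferent, efferent, and self couplings (self counted once);
network strength sums the positive (or negative) entries of the
from-set → to-set block of a coupling matrix, with entry (i, j) the
influence of node j on node i. Strengths sum all estimated entries by
default (the literal reading of the method being emulated); a
significant-only variant is available behind a flag.

The brain–pupil analysis correlates the oddball-modulatory (B¹) network
strength with the mean oddball TEPR across subjects (Pearson), with a
controlled variant that residualizes TEPR on median RT and strength on mean
ELBO first, and a between-run variant pooling run-level points.

## Benchmark sizes

All benchmark problem sizes are desk-scale choices: smoother oracle at
T = 6, n = 2 (50 instances); ELBO monotonicity over 20 random fits at
T = 400; parameter recovery on one 5-node, T = 20 000, SNR-5 run; null FWE
over 100 replicates of 80 s runs; discriminant calibration over 200 seeds of
24-trial, 4-channel epochs with 100 permutations each; GLM recovery over
1000 noise replicates; schedule validation over 1000 seeds; and the
end-to-end check over 20 cohorts of 19 subjects × 2 runs of 25 trials
(~70 s, a 4× shortening of the study's runs) at 4 nodes, testing the
directional (one-sided) hypothesis of a positive strength–TEPR correlation.
Two statistical caveats are inherent to these designs. First, the
permutation-threshold calibration is slightly conservative: with 5 oddball
× 19 standard trials the AUC lives on a 95-point grid, the pooled-null 0.99
quantile sits on an atom, and strict-inequality exceedance skips that atom's
mass — the standard behavior of permutation tests with ties. Second, the
end-to-end check operates at its statistical ceiling: with 19 subjects per
cohort drawn at ρ = 0.65, the realized sample correlation varies with
SD ≈ 0.25 on the Fisher scale, so the one-sided power per cohort is at most
≈ 0.93 even under perfect recovery — cohorts whose realized draw falls near
or below the critical value r = 0.389 cannot reach significance regardless
of pipeline quality. The scaled runs keep estimation noise well below the
between-subject spread (strength–gain correlation ≈ 0.9 per cohort), so the
measured fraction of significant cohorts reflects that sampling ceiling,
not estimator failure.
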