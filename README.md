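# pupilec

Multimodal analysis of the auditory oddball paradigm: single-trial EEG
discrimination, EEG-informed fMRI GLMs, ROI functional connectivity,
state-space effective connectivity, and brain–pupil correlation — exercised
end-to-end on a synthetic-data generator with known ground truth.

## Who this is for

Researchers working with simultaneous pupillometry–EEG–fMRI (or any subset)
in event-related designs who need a tested, reusable implementation of the
analysis chain linking task-evoked pupillary responses (TEPR, an index of
phasic arousal tied to the locus coeruleus–norepinephrine system) to the
directed coupling between cortical networks during salience processing.
Every stage is driven by plain-text containers (BIDS-style events TSV,
TSV/HDF5 arrays with JSON sidecars), so the pipeline runs without any
proprietary acquisition format.

## The models at the core

**Sliding-window discriminant.** For windows of width N = 50 ms centered at
τ = 0…1000 ms (step 25 ms), logistic regression learns weights w(τ)
separating oddball from standard EEG epochs; the single-trial components
d_i(τ) = (1/N) Σ_t w(τ)ᵀ y_i(t), demeaned, become parametric fMRI
regressors. Window quality is the leave-one-out AUC, thresholded against a
100-permutation null pooled over windows (p < 0.01).

**Effective connectivity.** Latent node activity follows a bilinear MVAR
state-space model

    y_t = L x_t + e_t,   x_t = G s_t + ε_t,
    s_t = A s_{t−1} + Σ_k B^k m^k_t s_{t−1} + D u_t + ω_t

where A holds intrinsic couplings, B^k the modulation of couplings by the
k-th stimulus class (unit-height boxcar inputs m^k), and D the exogenous
input gain. Inference is mean-field variational Bayes with an exact
Gaussian-chain state update and conjugate Gaussian/Gamma parameter updates;
the evidence lower bound (ELBO) is monotone and serves as the
model-fit covariate downstream. Run posteriors are combined per subject and
per group by Bayesian parameter averaging (precision-weighted product of
Gaussians with prior correction), thresholded by posterior sign probability
(α = 0.05, Bonferroni). Network coupling strength sums the positive or
negative entries of a from-network → to-network block of the oddball
modulatory matrix; its across-subject Pearson correlation with the mean
oddball TEPR is the claim-bearing statistic.

## Worked example

```python
import numpy as np
from pupilec.synthetic_data import (ParadigmSpec, default_ground_truth,
                                    generate_cohort)
from pupilec.pipeline import analyze_cohort

spec = ParadigmSpec(n_trials_per_run=15, n_runs=2, n_subjects=19, rng_seed=1)
truth = default_ground_truth(n_nodes=4, n_channels=8, seed=2,
                             planted_rho=0.65)
cohort = generate_cohort(spec, truth, seed=123, with_bold=False)
res = analyze_cohort(cohort, alternative="greater",
                     ec_kwargs={"elbo_tol": 1e-5, "max_iter": 60})
c = res["correlation"]
print(f"r = {c.r:.4f}, one-sided p = {c.p:.4f}, n = {c.n}")
print(f"strength-gain corr = "
      f"{np.corrcoef(res['strengths'], res['true_gains'])[0, 1]:.3f}")
```

Output:

```
r = 0.5785, one-sided p = 0.0047, n = 19
strength-gain corr = 0.951
```

The cohort plants a correlation of 0.65 between each subject's modulatory
coupling gain and pupil dilation amplitude. The pipeline preprocesses the
pupil traces and computes each subject's mean oddball TEPR, fits the
state-space model to every run, averages run posteriors per subject (BPA),
sums the late-to-early oddball-modulated network strength, and correlates it
with TEPR: here it recovers r = 0.58 (the planted 0.65 attenuated by finite
runs), significant at p < 0.05, and the estimated strengths track the true
per-subject gains at r = 0.95.

A disk-based driver with the same stages (plus the discriminant, GLM, FC and
tSNR stages) is available as `pupilec.pipeline.run_pipeline` or from the
shell:

```bash
pupilec --demo --out results/demo --seed 1
```

which prints, for the 5-subject demo cohort:

```
pipeline complete: 5 subjects, 0 excluded runs
brain-pupil correlation: r=-0.2595 p=0.6733 (n=5)
```

(five subjects are far too few for a significant brain-pupil correlation;
the demo only exercises every stage end-to-end).

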