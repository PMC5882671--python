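# dust-ddm

Drift-diffusion modelling of perceptual decisions under social information
and social norms, built around the DUST task (dots under social
influence): participants judge the motion direction of a random-dot
display while two arrows show other players' alleged decisions, and a
per-trial prompt (NONE / SAME / ONLY) tells them to ignore, follow or
oppose that social information — with monetary consequences for the
*other* players only, and two experiment variants (benefit-others vs
harm-others) differing in whether compliance earns or non-compliance
costs the others money.

The package is for computational cognitive modellers who want a tested,
end-to-end reference pipeline for this class of analysis: it generates
synthetic cohorts with the task's exact design constraints, fits six
competing diffusion-model parametrizations per subject, compares them by
WAIC, and reports model-averaged condition effects, together with
parameter-recovery studies and posterior predictive checks.

## The model

Evidence accumulates as a Wiener process with drift *v* (diffusion
coefficient *s* = 1) from starting point *z* = *w·a* toward absorbing
boundaries at 0 (LEFT) and *a* (RIGHT); response time is the first-passage
time plus a non-decision time *t₀*, and drift may vary across trials as
N(*v*, *sv*²). The first-passage density uses the standard small-/
large-time series expansions with closed-form Gaussian drift mixing. Six
parametrizations differ in whether congruent social cues shift the
starting point (toward the cued side), change the drift rate, both, or
neither, and whether those effects vary by norm condition — from the
5-parameter `reduced` model to the 14-parameter `spdr`. Subject-level
posteriors come from differential-evolution MCMC (3 chains per parameter,
proposals built from scaled chain differences), gated on split-chain
R̂ < 1.1. Per-subject WAIC weights, w_m ∝ exp(−ΔWAIC_m/2), average the
condition effects across the whole model set:

* `sp_bias` — starting-point shift toward the cued side, corrected for
  the incongruent baseline and averaged over left/right cues;
* `drift_delta` — congruent-trial drift minus the dots-only drift.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on synthetic
cohorts (6 subjects per experiment by default; `--full` for study-sized
cohorts):

```
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_behavioural_summaries.py
python analysis/03_fit_models.py --seed 1
python analysis/04_model_comparison.py
python analysis/05_validation.py
```

Step 02 prints, for the harm-others cohort:

```
HO: accuracy by norm x validity
validity  incongruent  invalid  valid
norm
NONE            0.735    0.676  0.777
ONLY            0.731    0.664  0.619
SAME            0.727    0.551  0.811
HO: mean conformity delta ONLY: -0.085, SAME: +0.072
```

Dots-only (incongruent) accuracy sits at the calibrated ~0.70 in every
norm condition; valid cues help and invalid cues hurt, the SAME prompt
amplifies the cue effect, and the ONLY prompt suppresses it (valid-cue
accuracy even drops below the invalid-cue level because the planted
harm-others effects push the starting point away from the cue and slow
congruent-trial accumulation). Conformity — the change in choosing the
cued side relative to NONE — is positive under SAME and negative under
ONLY.

Step 04 then fits and averages the six models; for the same cohort:

```
HO: cohort-mean averaged parameters
           sp_bias  drift_delta
condition
NONE        0.0563       0.0114
ONLY       -0.0448      -0.1917
SAME        0.1267      -0.0615
HO: sp_bias ordering SAME > NONE > ONLY: True
```

The model-averaged starting-point bias recovers the planted ordering
(generating values +0.12 / +0.06 / −0.04) and the ONLY-condition drift
suppression (planted −0.35, attenuated by averaging over models without a
drift effect). Step 05 reports recovery correlations of 0.996 (*a*) and
0.915 (drift magnitude) for the reduced model at 10 subjects × 360
trials.

The same stages are exposed as a CLI (`dust simulate|fit|compare|recover|
ppc|report --config cfg.yaml`) and as plain library calls
(`dust_ddm.pipeline`).

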