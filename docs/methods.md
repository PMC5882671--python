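# Methods

## The task being modelled

The DUST task (dots under social influence) is a two-alternative
motion-discrimination task. On every trial the participant judges whether a
random-dot kinematogram moves left or right, with up to 2.5 s to respond.
Two arrows overlaid on the stimulus display the alleged decisions of two
other players: incongruent arrows (pointing apart) carry no directional
information — the dots-only condition — while congruent arrows are *valid*
when they point with the true motion and *invalid* otherwise. A prompt at
trial onset establishes the social norm for that trial: NONE (no rule),
SAME (decide with the others) or ONLY (decide against them). Norm
(non-)compliance changes the other players' payoffs only; the participant
is always paid 1 cent per correct answer. The two experiment variants
differ only in the others-payoff matrix: in benefit-others (BO) compliance
can earn the others a cent, in harm-others (HO) non-compliance can cost
them one.

Phase-2 schedules hold the design exactly: 360 trials, 120 per norm
prompt, cue types at 40% valid / 30% invalid / 30% incongruent, and never
more than three identical prompts in a row. We stratify the cue
proportions within each norm condition (48/36/36) and balance motion
direction left/right within every norm × cue cell; the stratification is a
design choice of this package (only the overall proportions are fixed by
the task description), made so that condition contrasts are estimated from
balanced cells.

## Diffusion model

Choices and RTs are modelled jointly by a Wiener diffusion process:
evidence accumulates at drift rate *v* (plus white noise, diffusion
coefficient *s* = 1 — all parameter values in this package are on the
*s* = 1 scale) from starting point *z* = *w·a* until it hits 0 (LEFT) or
*a* (RIGHT); RT is the hitting time plus a non-decision time *t0*. Across
trials the drift may vary as Normal(*v*, *sv²*). The stimulus sets the
drift's sign (positive toward the correct boundary for rightward motion);
parameters are drift *magnitudes*. Congruent cues act on the relative
starting point *w*: a right-pointing cue shifts it up, a left-pointing cue
down, symmetrically.

The first-passage density uses the classical small-time / large-time
series expansions, choosing per evaluation whichever needs fewer terms for
a target absolute error of 1e-7 (capped at 64 terms; the branches agree to
better than 1e-6 across the crossover). Drift variability is integrated
out in closed form (Gaussian drift mixing multiplies the zero-drift kernel
by an analytic factor), so no quadrature appears in the likelihood. The
density at or below zero decision time is zero; a candidate parameter
vector placing *t0* at or above any observed RT receives a log-likelihood
of −∞ and is rejected by the sampler rather than raising.

Trials that pass the deadline without a response (rare by design, < 2%
under the defaults) are emitted by the simulator but excluded from the
likelihood; the model does not describe them.

## Six parametrizations

All models share *a*, *t0*, *sv* and a baseline starting point and drift
magnitude; they differ in which parameters respond to the social cue and
norm prompt:

| model          | starting points                    | drifts                    | p  |
|----------------|------------------------------------|---------------------------|----|
| reduced        | one                                | one                       | 5  |
| sp_reduced     | + cong-left, cong-right (shared)   | one                       | 7  |
| sp             | + cong-left/right × norm           | one                       | 11 |
| drift_reduced  | one                                | + one congruent drift     | 6  |
| drift          | one                                | + congruent drift × norm  | 8  |
| spdr           | sp's set                           | drift's set               | 14 |

The per-norm structure (two extra starting points per condition in `sp`;
one congruent drift per condition in `drift`; single incongruent
baselines) is reconstructed from the models' verbal descriptions and their
parameter-count arithmetic; where the description is ambiguous (one
incongruent baseline or three) we keep the single-baseline reading, which
matches the stated counts. Nesting is exact: equating a richer model's
extra parameters reproduces the nested model's likelihood identically,
which the test suite verifies.

## Priors and sampling

Priors are independent truncated normals, weakly informative over typical
two-alternative forced-choice fits: *a* ~ N(1.5, 1) on (0.1, 5), *w*-type
~ N(0.5, 0.25) on (0.02, 0.98), drift magnitudes ~ N(1, 2) on (0, 7),
*t0* ~ N(0.3, 0.2) on (0.05, 1), *sv* ~ N(0.5, 0.5) on (0, 3). All are
overridable per kind or per parameter.

Fitting is differential-evolution MCMC: 3 chains per parameter, proposals
γ·(θ_i − θ_j) + U(−0.001, 0.001) with γ = 2.38/√(2p) and a 5% chance of
γ = 1 for mode jumping. During burn-in, chains migrate (random cyclic
swap) every 20 iterations, and every 50 iterations chains whose log
posterior falls more than twice the interquartile range below the first
quartile are teleported onto a randomly chosen healthy chain — the
standard remedy for the stuck-outlier-chain pathology of DE-MC. Default
budgets are 500 burn-in + 1000 retained iterations per chain; the analysis
scripts and tests run 600 + 500 with thinning 2, which the convergence
diagnostics accept for all six models at 360 trials. A fit enters model
comparison only if every parameter's split-chain R̂ < 1.1; one retry with
doubled iterations is attempted, after which the fit fails loudly. Zero
within-chain variance yields R̂ = +∞ with a warning.

Every retained draw stores its per-trial log-likelihoods; the row sums are
consistent with fresh likelihood evaluations to 1e-8 (tested), which is
what WAIC consumes.

## Model comparison and averaging

WAIC is computed on the deviance scale with the variance-based penalty,
using the *population* (denominator-n) variance over draws so that
duplicating draws leaves the criterion unchanged. Weights are Akaike-style,
exp(−Δ/2) renormalized within the subject's model set.

Condition-level effects are averaged over **all six** models with these
weights, each model contributing its posterior-mean value and models
lacking a parameter contributing the nested value (zero bias / zero drift
difference). The two reported effects per norm condition are

* `sp_bias` = mean(w_congR − w_incong, w_incong − w_congL) — the
  toward-the-cue starting-point shift, corrected for any incongruent
  baseline bias and averaged over left/right cues (positive = toward the
  cued side);
* `drift_delta` = v_cong − v_incong — the congruent-trial drift change.

The posterior mean is used as the point estimate entering the average
because it is linear under the weighting.

## Synthetic cohorts

There is no deposited behavioural data, so cohorts are simulated from an
explicit ground truth. Base parameters default to *a* = 1.2, *w* = 0.5,
*v* = 0.706, *t0* = 0.3 s, *sv* = 0 — calibrated so dots-only accuracy is
1/(1+exp(−v·a)) ≈ 0.70, the level the task's phase-1 staircase targets.
Coherence is not a separate channel; it is absorbed into the base drift.

Preset condition effects reproduce the qualitative pattern the analysis is
designed to detect — starting-point shifts Δw of +0.06 (NONE), +0.12
(SAME), +0.02 (BO) / −0.04 (HO) in ONLY, and a congruent-drift change
Δv_ONLY of −0.15 (BO) / −0.35 (HO). These are this package's choices made
to plant a SAME > NONE > ONLY ordering with stronger ONLY suppression
under harm-others; they are not estimates of any real cohort. Per-subject
heterogeneity is truncated-normal jitter with SD equal to 25% of each
value.

The primary simulator samples (choice, RT) by inverting the analytic
defective CDFs on a 4096-point grid per parameter context — exact in
distribution up to quadrature, and fast because a subject's 360 trials
share at most a handful of contexts. An independent Euler–Maruyama path
simulator (step 1e-4 s) exists solely to cross-validate the analytic
machinery in tests; the documented bias check keeps its choice fractions
within Monte-Carlo error of the closed-form absorption probability at that
step size.

What the generator does *not* emulate: post-error slowing, attention
lapses and fast guesses (no contaminant mixture), starting-point or
non-decision-time variability across trials, learning or fatigue over the
session, and any true social inference by the participant. Passing tests
therefore show that the pipeline recovers what this generative family
plants — not that real cohorts satisfy the model.

## Validation

Parameter recovery simulates subjects from preset-jittered truths, refits,
and scores truth-vs-estimate correlations and central-95%-interval
coverage per parameter. Parameters the presets hold constant (the
incongruent starting point at 0.5, *sv* at 0) have undefined correlation
and are reported as missing; *sv* sits on its domain boundary, where
interval coverage is expectedly poor and posterior means are pulled up by
the prior — a known boundary effect, visible in the recovery tables and
left uncorrected. The desk-scale gate (10 subjects × 360 trials, reduced
model) requires correlation > 0.8 for *a* and the drift magnitude; the
observed values are ≈ 0.99 and ≈ 0.89.

Posterior predictive checks draw ≥ 20 parameter vectors from a fit,
simulate the subject's schedule under each, and compare observed accuracy
and RT quantiles (0.1/0.5/0.9) per norm × information condition
(dots-only / valid / invalid) against the central 95% predictive interval.
Cells are grouped by cue *validity* rather than raw arrow direction
because left/right cue cells mix valid and invalid trials and would dilute
exactly the misfit (cue-induced accuracy splits) the check exists to
expose.

## Problem sizes and numerical choices

The shipped analyses and tests use 6-subject cohorts, 600 + 500 sampler
iterations with thinning 2, 10-subject recovery studies and 80–100 PPC
replicates — sizes chosen so the full suite runs on a single CPU in
minutes while every qualitative conclusion (model ranking, planted-effect
ordering, recovery quality) is already stable; `analysis/01` exposes
`--full` for study-sized cohorts. Density normalization is verified to
1e-4 by quadrature; WAIC oracles to 1e-12; weight normalization to 1e-10.
Ties in schedule generation are broken by the seeded generator;
infeasible norm-sequence constraints fail after 1000 bounded attempts.
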