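# Methods

This note documents the statistical machinery in `distillrct`: the models
each stage fits, the simulation laws behind the synthetic data, the defaults
and why they were chosen, and what the package's tests do and do not
establish about real trials.

## Stage one: the participation model

Enrollment (ever/never) is modelled within the randomized intervention arm
only, by gradient-boosted classification trees. Defaults mirror standard
practice for uptake/propensity modelling with a few hundred subjects:
10-fold cross-validation, a budget of 10,000 trees with the count chosen at
the minimum of the pooled out-of-fold binomial deviance, interaction depth
2, minimum leaf size 8, learning rate 0.001. All five are pass-through
hyperparameters (`StageOneSettings`); the test suite uses a faster
configuration (fewer trees, larger learning rate), which changes runtime,
not behavior.

Two AUCs are reported and labelled: the **cross-validated AUC** (pooled
out-of-fold predictions at the selected tree count) is the headline metric;
the in-sample AUC of the refit model is optimistic by construction and
reported only for transparency. AUC is computed by the Mann–Whitney
formulation — the probability that a random enrollee outscores a random
non-enrollee, ties counting 1/2 — which equals the trapezoidal area under
the empirical ROC curve (property-tested against scikit-learn's
implementation).

Covariate handling is designed so that *scoring can never fail*: real
covariates are median-imputed with a missing-indicator column; categorical
covariates are one-hot encoded over the training levels plus an
always-present `(missing)` level, to which both missing values and levels
unseen at training time are mapped. Per-covariate **relative influence** is
the impurity importance summed over a covariate's encoded columns, rescaled
to sum to 100.

By default every subject in both arms is scored with the final model refit
on all intervention-arm data (symmetry between arms). Setting
`StageOneSettings(oof_scores=True)` substitutes out-of-fold scores for the
training subjects, guarding against in-sample optimism leaking into the
trimming stage.

## Stage two: distillation

A retention level `f` keeps exactly `round(f · N)` subjects (half-away-from-
zero rounding, so counts are portable across platforms) with the highest
scores over the **pooled** sample. The threshold is deliberately a pooled
quantile, never per-arm: per-arm quantiles would trim the arms differently
whenever their score distributions differ by chance, breaking the symmetry
that preserves randomization. Ties are broken by (score descending,
subject id ascending), so the retained set is deterministic for any tie
structure, and a ladder built from one shared ordering is nested by
construction. The default ladder is [1.00, 0.80, 0.60, 0.40, 0.25]; the
0.25 endpoint anchors the "quarter of the original sample" scenario studied
in the power simulation, and the ladder is fully configurable.

## Stage three: difference-in-differences mixed models

Each grid cell fits two periods (baseline and one follow-up year — follow-up
years are analyzed separately rather than pooled, to expose delayed benefit
or decay) with a subject-level random intercept shared across the subject's
two rows:

    ln λ_it = β_0i + β_t·I(post) + β_int·I(intervention) + τ·I(post)·I(intervention),
    β_0i ~ N(β_0, σ²),  offset = ln(exposure months)

Poisson for counts; gamma with log link for costs. `τ` is the
difference-in-differences effect on the log scale; `exp(τ) − 1` is its
percent-change reading. Under randomization `β_int` has expectation zero
(verified by simulation in the test suite).

**Estimation.** The marginal likelihood integrates the random intercept by
Gauss–Hermite quadrature (30 nodes; one-dimensional integrals with
two-observation clusters are far inside its accuracy range) and is
maximized by L-BFGS-B over (β, log σ) — plus log shape for the gamma
family, estimated jointly by maximum likelihood rather than from residual
moments so that all parameters share one objective and one information
matrix. Standard errors are the inverse observed information (numerical
Hessian). On fixtures the Poisson fit matches `lme4::glmer` (adaptive
quadrature) and the gamma fit matches `glmmTMB` to three decimals in
coefficients and standard errors; the lme4 comparison is kept as an
oracle test.

**Degenerate cells and fallback.** When the optimizer fails, the Hessian is
not positive definite, or σ̂² is pinned at (essentially) zero — common in
small distilled subsets — the cell is refit as a fixed-effects GLM with
subject-clustered sandwich standard errors and flagged `fallback_used`.
On well-behaved data the two routes agree within sampling error
(tested). Cells that fail both routes are reported `converged=False`;
a grid run never crashes on one bad cell. Other conventions: subject-periods
with zero exposure months are dropped with a logged warning; gamma-family
costs of exactly zero (outside the gamma support) are floored at a
configurable positive constant (default 1 currency unit) and the floored
count is reported per cell. Inference is Wald throughout (±1.96·SE on the
log scale); no multiplicity adjustment is applied across the grid, because
the retention levels are nested and prespecified.

## The synthetic-trial generator

The generator emulates the structure of a two-arm complex-care pilot:
404 intervention / 401 control subjects and a 64.6% marginal enrollment
rate in the intervention arm by default. Covariates are a mix of standard
normals, Bernoulli(0.3) binaries and one three-level site factor,
identically distributed in both arms. Enrollment propensity is the inverse
logit of a linear covariate score with geometrically decaying weights
(`x1` strongest — used by planted-signal recovery tests), scaled so the
logit-score standard deviation equals `covariate_enrollment_signal`
(default 2.0, which yields cross-validated stage-one AUCs in the low 0.8s)
and with the intercept solved numerically so the mean propensity over the
intervention arm equals the target rate. Responder status is a rank
threshold (top 40% by default) on a latent correlated 0.3 with the
standardized enrollment score — the correlation that gives distillation
something to find. Counts are Poisson and costs gamma, with subject-level
log-normal frailties (sd 0.5 on the log scale) shared across periods to
induce the within-person correlation the random intercept targets; annual
baseline rates default to a high-utilization profile (1.2 admissions, 6
inpatient days, 2.5 ED visits, 20 ambulatory visits, mean cost 30,000,
gamma shape 1.2). The multiplicative treatment effect
`exp(effect_size_log_scale)` applies only to enrolled intervention-arm
responders in follow-up periods; the default effect is 0 (a null trial).

What the generator does **not** emulate: real covariate distributions and
their correlation structure (the motivating application's covariates are
proprietary risk scores and EHR-derived measures), informative missingness,
time-varying engagement intensity, or outcome-dependent censoring. Tests
passing on this generator establish the *internal* correctness of the
pipeline and the operating characteristics of the design under its stated
assumptions — not performance on any particular real dataset.

## The power simulation

Each replicate draws, per subject, three correlated standard normals —
treatment-effect, participation, and prediction-of-participation latents —
from the Cholesky transform, plus independent N(0,1) outcome noise. Default
correlations are 0.30 (effect–participation), 0.80 (effect–prediction) and
0.80 (participation–prediction); this matrix sits close to the
positive-definite boundary (determinant ≈ 0.014), which is what makes the
favorable regime favorable. Responders are the top 40% of the
treatment-effect latent and enrollees the top 40% of the participation
latent intersected with the intervention arm (both sample-rank thresholds,
so the fractions are exact); the outcome adds `taumax` (≤ 0) only for
enrolled intervention-arm responders, corresponding to a log-scale
utilization or cost model where only treated responders benefit.
Distillation inside the simulator ranks on the prediction latent directly —
refitting a stage-one learner on every replicate would only recover a
monotone transform of that latent — and a `distill_by="refit_classifier"`
mode is provided to validate exactly that equivalence. Arms are compared
with a two-sided Welch t-test at α = 0.05.

One genuinely ambiguous point in the design is which three variables are
jointly normal: the narrative names "the outcome, the treatment effect and
the prediction of participation", but the correlation list pairs
*participation* (not the outcome) with the other two. The correlation list
is taken as authoritative — the triple is (effect, participation,
prediction) with independent outcome noise — and the alternative reading
(outcome in the triple, enrollment thresholded on the prediction latent) is
implemented behind `latent_mode="outcome-triple"`.

Replicate seeds are spawned from the scenario seed via NumPy
`SeedSequence`, so any cell is reproducible in isolation. The default 2000
replicates give a Monte-Carlo SE of ≈ 0.005 near a rate of 0.05 and ≈ 0.011
near 0.5. `calibrate_sample_size` bisects `n_per_arm` until the
full-sample rejection rate hits a target (each evaluation ≥ 1000
replicates, seeds derived deterministically from (seed, n)); the bracket is
seeded by the analytic two-sample normal power formula with the diluted
effect `|taumax| · P(responder ∧ enrollee)`, where the orthant probability
comes from the Monte-Carlo oracle `joint_top_fraction_probability`. Under
the defaults the calibrated size for full-data power 0.30 at
taumax = −0.1 is ≈ 9,300 per arm, and power at 25% retention reaches
≈ 0.69 — the distillation gain the method exists to deliver — while the
taumax = 0 row stays at the nominal 0.05 across the whole ladder. With the
prediction correlations zeroed, distillation provides no gain: the retained-
subset effect is flat in retention and power can only fall as the sample
shrinks (both verified in the acceptance tests; note that literal flatness
of *power* across retention is impossible for a fixed nonzero effect,
because the sample size falls mechanically with retention).

## Numerical and design choices

* Rounding of retained counts is half-away-from-zero; `round(f·N) = 0` is
  allowed (an empty level downstream raises "arm exhausted" rather than
  silently keeping a subject).
* GLMM quadrature uses 30 nodes (20 in the heaviest simulation tests);
  σ is optimized on the log scale with a floor at e⁻⁸, and hitting the
  floor triggers the GLM fallback.
* The Welch test, rather than a pooled-variance t-test, guards against the
  mild variance inflation the treatment effect induces in the intervention
  arm.
* Acceptance-style simulations use 2000 replicates and n_per_arm = 2000
  for the null grid; the calibrated power study runs at the ≈ 9,300/arm the
  calibration itself selects. The 200-replicate, 2,000-subject parameter-
  recovery study keeps the full suite in the minutes range.

## Known limitations

* The gamma zero-cost floor is a pragmatic convention; with many exact
  zeros a hurdle or Tweedie model would be more faithful (not implemented).
* Only one-sided (bottom) trimming is supported; excluding *both* extremes
  of the predicted-uptake distribution is a plausible extension the data
  model already supports.
* The stage-one contract fixes a single boosted-tree learner; alternative
  learners would slot behind `ParticipationClassifier`'s interface but are
  not provided.
* Wald inference on small distilled subsets (tens of subjects) can be
  anti-conservative; the CI-coverage test operates at moderate sizes.
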