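# distillrct

Distillation analysis and power simulation for randomized trials diluted by
low intervention uptake.

## The problem

Randomized evaluations of care-delivery interventions are routinely
*diluted*: a large share of subjects randomized to the intervention arm
never enroll, or barely engage, so the intent-to-treat (ITT) contrast
averages a real effect over many untreated people and comes out null.
"As-treated" analyses that compare actual participants to the full control
group reintroduce exactly the self-selection bias randomization was meant to
remove.

The **distillation** approach threads this needle in three stages:

1. **Predict participation.** Within the randomized intervention arm, fit a
   gradient-boosted classification-tree model of enrollment (ever/never) on
   baseline covariates only, and score *every* randomized subject — both
   arms — with a predicted probability of participation.
2. **Distill.** Trim both arms to nested subsets retaining the top
   `round(f * N)` subjects of the *pooled* sample by that score, for a
   prespecified ladder of retention fractions (default 100%, 80%, 60%, 40%,
   25%). Because the threshold never looks at arm or outcomes,
   randomization is preserved within each retained subpopulation — the
   estimand simply shifts to the average treatment effect in a
   higher-uptake subpopulation.
3. **Re-estimate.** On each subset, fit two-period difference-in-differences
   generalized linear mixed models, per outcome and follow-up year:

   ```
   ln λ_it = β_0i + β_t I(t = post) + β_int I(intervention)
             + τ I(t = post) I(intervention),      β_0i ~ N(β_0, σ²)
   ```

   with a log exposure-months offset; Poisson for encounter counts, gamma
   (log link) for costs. `τ` is the treatment effect on the log scale, with
   the percent-change reading `exp(τ) − 1`.

If the probability of uptake is positively correlated with the benefit of
treatment, the distilled subsets concentrate treated responders and the
method buys power; if not, it merely shrinks the sample. The bundled
Monte-Carlo framework (`distillrct.power_sim`) quantifies exactly that
trade-off, including type-I-error control across the nested tests.

## Worked example

```python
import distillrct as d

cfg = d.SyntheticTrialConfig(seed=7, effect_size_log_scale=-0.5)
trial = d.generate_synthetic_trial(cfg)

fit = d.fit_participation_model(
    trial, d.StageOneSettings(folds=10, max_trees=2000, learning_rate=0.01, seed=7)
)
scores = d.score_subjects(fit, trial)
ladder = d.nested_distillation(trial, scores)

spec = d.DiDModelSpec("ed_visits", "poisson", "fu1")
for f in (1.0, 0.25):
    est = d.fit_did_model(trial, spec, level=ladder.level(f))
    print(f, est.tau, est.ci95, est.p_value)
```

prints

```
arms: {'intervention': 404, 'control': 401}
uptake model: 586 trees, cross-validated AUC 0.813
retained per level: {1.0: 805, 0.8: 644, 0.6: 483, 0.4: 322, 0.25: 201}
retention  1.0: tau = -0.052 (95% CI -0.178 to +0.075), pct change -5.1%, p = 0.4217
retention 0.25: tau = -0.225 (95% CI -0.476 to +0.026), pct change -20.2%, p = 0.0785
```

The synthetic trial (805 subjects, 64.6% uptake in the intervention arm,
a 40% log-scale reduction in utilization for treated enrolled responders)
is diluted enough that the full-sample ITT estimate is a null −5%; the
same model on the quarter of subjects most likely to participate recovers
a −20% point estimate — the dilution-versus-concentration trade the method
is built around.

The same workflows are scriptable from the shell:

```bash
distillrct simulate-trial --out trial.csv --effect -0.5 --seed 7
distillrct analyze --input trial.csv --outdir run --seed 7
distillrct power --preset figure3 --outdir power_run
```

`analyze` writes `scores.csv`, `ladder.csv`, `effects.csv` (one row per
outcome x follow-up x retention level), a metrics summary and the echoed
run configuration; `power` writes the rejection-rate grid and a power
curve plot.

## Layout

| module | contents |
| --- | --- |
| `distillrct.trial_data` | subject-level data model, CSV I/O (wide + long), validation, synthetic-trial generator |
| `distillrct.participation` | stage one: `ParticipationClassifier` (scikit-learn estimator), AUC, relative influence, scoring |
| `distillrct.distill` | stage two: exact-count pooled-quantile trimming, nested ladders |
| `distillrct.glmm` / `distillrct.outcome_models` | stage three: random-intercept Poisson/gamma DiD models, cluster-robust GLM fallback, outcome grids |
| `distillrct.power_sim` | correlated-latent trial simulator, power/type-I grids, sample-size calibration |
| `distillrct.pipeline` / `distillrct.cli` | configuration, orchestration, `distillrct` console command |

See `docs/methods.md` for the statistical details, defaults and
limitations.
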