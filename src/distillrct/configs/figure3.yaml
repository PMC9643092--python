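# Illustrative power-study scenario: six treatment values crossed with the
# default five-level retention grid under the favorable correlation regime
# (effect-participation 0.30, effect-prediction 0.80,
# participation-prediction 0.80; responder and enrollment fractions 0.40).
# n_per_arm was calibrated so full-sample power is ~0.30 at taumax = -0.1;
# reps is kept at 200 here so the preset runs in minutes — raise it (e.g.
# to 2000) for publication-quality Monte-Carlo error.
outdir: power_run
taumax: [0.0, -0.1, -0.2, -0.3, -0.4, -0.5]
n_per_arm: 9700
reps: 200
seed: 20220719
alpha: 0.05
responder_fraction: 0.40
enroll_fraction: 0.40
rho_te_part: 0.30
rho_te_pred: 0.80
rho_part_pred: 0.80
retention_grid: [1.00, 0.80, 0.60, 0.40, 0.25]
plot: true
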