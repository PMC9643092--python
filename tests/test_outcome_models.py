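import subprocess

import numpy as np
import pandas as pd
import pytest

from distillrct import (
    DiDModelSpec,
    EstimationError,
    TrialDataset,
    fit_did_model,
    nested_distillation,
    percent_change,
    run_outcome_grid,
)
from distillrct.glmm import RandomInterceptGLMM

from conftest import make_minimal_frame, saturated_toy


def simulate_poisson_did(
    n_per_arm, tau, sigma=0.5, beta0=np.log(2.5 / 12), beta_t=0.1, seed=0
):
    """Draw directly from the two-period Poisson DiD law (long format)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    b = rng.normal(0.0, sigma, n)
    interv = (np.arange(n) < n_per_arm).astype(float)
    off = np.log(12.0)
    ys, posts = [], []
    for post in (0, 1):
        eta = beta0 + beta_t * post + tau * post * interv + b + off
        ys.append(rng.poisson(np.exp(eta)))
        posts.append(np.full(n, post))
    y = np.concatenate(ys).astype(float)
    post = np.concatenate(posts)
    iv = np.concatenate([interv, interv])
    X = np.column_stack([np.ones(2 * n), post, iv, post * iv])
    groups = np.concatenate([np.arange(n), np.arange(n)])
    return y, X, np.full(2 * n, off), groups


class TestClosedFormAndPercentChange:
    def test_saturated_poisson_did_closed_form(self):
        """Cell means (2,1) vs (2,2) with equal offsets give tau = ln(1/2)."""
        est = fit_did_model(
            saturated_toy(), DiDModelSpec("admissions", "poisson", "fu1")
        )
        assert est.tau == pytest.approx(np.log(0.5), abs=1e-4)
        assert est.converged

    def test_offset_scale_invariance_in_saturated_fit(self):
        """Halving every exposure shifts the intercept, never tau."""
        ds = saturated_toy()
        halved = ds.subjects.copy()
        for p in ("baseline", "fu1", "fu2"):
            halved[f"exposure_{p}"] = 6.0
        est_full = fit_did_model(ds, DiDModelSpec("admissions", "poisson", "fu1"))
        est_half = fit_did_model(
            TrialDataset(halved, []), DiDModelSpec("admissions", "poisson", "fu1")
        )
        assert est_half.tau == pytest.approx(est_full.tau, abs=1e-6)
        assert est_half.beta0 == pytest.approx(est_full.beta0 + np.log(2), abs=1e-4)

    @pytest.mark.parametrize(
        "tau, expected",
        [(0.0, 0.0), (-0.1, -0.0952), (-0.5, -0.3935), (0.2, 0.2214)],
    )
    def test_percent_change(self, tau, expected):
        assert percent_change(tau) == pytest.approx(expected, abs=1e-4)

    def test_ci_contains_tau_and_is_wald(self):
        est = fit_did_model(
            saturated_toy(), DiDModelSpec("admissions", "poisson", "fu1")
        )
        lo, hi = est.ci95
        assert lo <= est.tau <= hi
        assert hi - est.tau == pytest.approx(1.96 * est.se, rel=1e-9)


class TestMixedModel:
    def test_poisson_glmm_matches_lme4(self, tmp_path):
        """Independent oracle: R lme4's adaptive-quadrature glmer fit."""
        y, X, off, groups = simulate_poisson_did(150, -0.35, sigma=0.6, seed=42)
        res = RandomInterceptGLMM("poisson").fit(y, X, off, groups)
        df = pd.DataFrame(
            {
                "y": y,
                "post": X[:, 1],
                "interv": X[:, 2],
                "id": groups,
                "off": off,
            }
        )
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        rscript = f"""
        suppressMessages(library(lme4))
        df <- read.csv("{csv}")
        m <- glmer(y ~ post*interv + (1|id), data=df, family=poisson,
                   offset=df$off, nAGQ=25)
        co <- summary(m)$coefficients
        cat(co["post:interv","Estimate"], co["post:interv","Std. Error"],
            unlist(VarCorr(m)), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=rscript, capture_output=True, text=True,
            check=True,
        )
        r_tau, r_se, r_sigma2 = map(float, out.stdout.split())
        assert res.params[3] == pytest.approx(r_tau, abs=5e-3)
        assert res.bse[3] == pytest.approx(r_se, abs=5e-3)
        assert res.sigma2 == pytest.approx(r_sigma2, abs=0.03)

    def test_parameter_recovery_poisson(self):
        y, X, off, groups = simulate_poisson_did(1500, -0.25, sigma=0.5, seed=7)
        res = RandomInterceptGLMM("poisson").fit(y, X, off, groups)
        assert res.params[3] == pytest.approx(-0.25, abs=3 * res.bse[3])
        assert res.sigma2 == pytest.approx(0.25, abs=0.05)

    def test_parameter_recovery_gamma(self):
        rng = np.random.default_rng(3)
        n = 800
        b = rng.normal(0, 0.5, n)
        interv = (np.arange(n) < n // 2).astype(float)
        ys, posts = [], []
        for post in (0, 1):
            mu = np.exp(np.log(1000) + 0.1 * post - 0.3 * post * interv + b)
            ys.append(rng.gamma(2.0, mu / 2.0))
            posts.append(np.full(n, post))
        y = np.concatenate(ys)
        post = np.concatenate(posts)
        iv = np.concatenate([interv, interv])
        X = np.column_stack([np.ones(2 * n), post, iv, post * iv])
        groups = np.concatenate([np.arange(n), np.arange(n)])
        res = RandomInterceptGLMM("gamma").fit(y, X, np.zeros(2 * n), groups)
        assert res.params[3] == pytest.approx(-0.3, abs=3 * res.bse[3])
        assert res.shape == pytest.approx(2.0, rel=0.25)
        assert res.sigma2 == pytest.approx(0.25, abs=0.07)

    def test_fallback_agrees_with_mixed_fit(self):
        """On well-behaved data the cluster-robust GLM and the GLMM agree."""
        import statsmodels.api as sm

        y, X, off, groups = simulate_poisson_did(1200, -0.3, sigma=0.4, seed=11)
        mixed = RandomInterceptGLMM("poisson").fit(y, X, off, groups)
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        assert abs(mixed.params[3] - glm.params[3]) < 2 * mixed.bse[3]


class TestFitDiDModel:
    def test_arm_exhausted_raises(self):
        df = make_minimal_frame(4, 4)
        ds = TrialDataset(df, [])
        interv_ids = df.loc[df["arm"] == "intervention", "subject_id"]
        with pytest.raises(EstimationError, match="arm exhausted"):
            fit_did_model(
                ds,
                DiDModelSpec("admissions", "poisson", "fu1"),
                level=list(interv_ids) + ["S004"],
            )

    def test_zero_exposure_rows_dropped(self):
        df = make_minimal_frame(6, 6)
        df.loc[0, "exposure_fu1"] = 0.0
        est = fit_did_model(
            TrialDataset(df, []), DiDModelSpec("admissions", "poisson", "fu1")
        )
        assert est.n_obs == 23

    def test_zero_costs_floored_and_counted(self):
        df = make_minimal_frame(6, 6)
        df["cost_baseline"] = 150.0
        df.loc[[0, 4], "cost_baseline"] = 0.0
        est = fit_did_model(
            TrialDataset(df, []),
            DiDModelSpec("cost", "gamma", "fu1", zero_cost_floor=1.0),
        )
        assert est.n_cost_floored == 2

    def test_degenerate_cell_reports_nonconverged_without_crash(self):
        df = make_minimal_frame(6, 6)
        for p in ("baseline", "fu1", "fu2"):
            df[f"admissions_{p}"] = 0
        est = fit_did_model(
            TrialDataset(df, []), DiDModelSpec("admissions", "poisson", "fu1")
        )
        assert not est.converged or not np.isfinite(est.se) or est.se >= 0


class TestOutcomeGrid:
    @pytest.fixture(scope="class")
    def grid_setup(self, small_trial, small_trial_scored):
        _, scores = small_trial_scored
        ladder = nested_distillation(small_trial, scores)
        return small_trial, ladder

    def test_grid_shape_and_columns(self, grid_setup):
        ds, ladder = grid_setup
        grid = run_outcome_grid(
            ds, ladder, outcomes=[("admissions", "poisson"), ("cost", "gamma")]
        )
        assert len(grid) == 2 * 2 * 5
        assert {
            "outcome", "period", "retention_fraction", "family", "tau", "se",
            "ci_low", "ci_high", "p_value", "pct_change", "n_subjects",
            "converged", "fallback_used",
        } <= set(grid.columns)

    def test_full_retention_equals_direct_itt_fit(self, grid_setup):
        ds, ladder = grid_setup
        spec = DiDModelSpec("ed_visits", "poisson", "fu1")
        direct = fit_did_model(ds, spec)
        via_level = fit_did_model(ds, spec, level=ladder.level(1.0))
        assert via_level.tau == pytest.approx(direct.tau, abs=1e-8)
        assert via_level.se == pytest.approx(direct.se, abs=1e-8)

    def test_ci_width_grows_as_retention_shrinks(self, grid_setup):
        """Trimming the sample inflates the confidence band, as expected."""
        ds, ladder = grid_setup
        grid = run_outcome_grid(
            ds, ladder, outcomes=[("ambulatory_visits", "poisson")],
            periods=("fu1",),
        )
        width = (grid["ci_high"] - grid["ci_low"]).to_numpy()
        # grid rows are ordered by decreasing retention
        assert width[-1] > width[0]
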