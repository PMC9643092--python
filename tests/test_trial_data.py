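import io

import numpy as np
import pandas as pd
import pytest

from distillrct import (
    ConfigurationError,
    ParseError,
    SyntheticTrialConfig,
    TrialDataset,
    generate_synthetic_trial,
    read_trial_table,
    validate_trial,
    write_trial_table,
)
from distillrct.trial_data import COUNT_OUTCOMES, PERIODS, required_columns

from conftest import make_minimal_frame


class TestGenerator:
    def test_default_arm_sizes(self):
        ds = generate_synthetic_trial(SyntheticTrialConfig(seed=0))
        assert ds.arm_counts() == {"intervention": 404, "control": 401}

    def test_enrollment_rate_calibration(self):
        """Mean intervention-arm enrollment over seed replicates hits the target."""
        fracs = []
        for seed in range(200):
            ds = generate_synthetic_trial(
                SyntheticTrialConfig(n_covariates=4, seed=seed)
            )
            enr = ds.subjects.loc[ds.arm_mask("intervention"), "enrolled"]
            fracs.append((enr == "yes").mean())
        # binomial MC error of the mean over 200 x 404 Bernoulli draws
        se = np.sqrt(0.646 * 0.354 / (404 * 200))
        assert abs(np.mean(fracs) - 0.646) < 4 * se

    def test_reproducible_given_seed(self):
        cfg = SyntheticTrialConfig(seed=42)
        a = generate_synthetic_trial(cfg)
        b = generate_synthetic_trial(cfg)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_generated_dataset_is_valid(self):
        ds = generate_synthetic_trial(SyntheticTrialConfig(seed=5))
        assert validate_trial(ds) == []

    def test_null_effect_arm_exchangeability(self):
        """With no treatment effect, outcomes are identically distributed by arm."""
        from scipy.stats import ks_2samp, mannwhitneyu

        ds = generate_synthetic_trial(
            SyntheticTrialConfig(
                n_intervention=3000,
                n_control=3000,
                effect_size_log_scale=0.0,
                seed=77,
            )
        )
        interv = ds.arm_mask("intervention")
        cost = ds.subjects["cost_fu1"].to_numpy()
        assert ks_2samp(cost[interv], cost[~interv]).pvalue > 0.01
        adm = ds.subjects["admissions_fu1"].to_numpy()
        assert mannwhitneyu(adm[interv], adm[~interv]).pvalue > 0.01

    def test_effect_scales_treated_responder_outcomes(self):
        ds0 = generate_synthetic_trial(
            SyntheticTrialConfig(seed=3, effect_size_log_scale=0.0)
        )
        ds1 = generate_synthetic_trial(
            SyntheticTrialConfig(seed=3, effect_size_log_scale=-1.5)
        )
        interv0 = ds0.subjects.loc[ds0.arm_mask("intervention")]
        interv1 = ds1.subjects.loc[ds1.arm_mask("intervention")]
        # follow-up utilization drops in the intervention arm; draws made
        # before any effect-dependent draw are untouched
        assert (
            interv1["admissions_fu1"].mean() < interv0["admissions_fu1"].mean()
        )
        assert (
            interv1["admissions_baseline"].sum()
            == interv0["admissions_baseline"].sum()
        )

    @pytest.mark.parametrize(
        "field, value",
        [
            ("enrollment_rate", 1.5),
            ("responder_fraction", 0.0),
            ("n_intervention", 0),
            ("covariate_enrollment_signal", -1.0),
            ("frailty_sd", -0.1),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SyntheticTrialConfig(**{field: value})
        with pytest.raises(ConfigurationError):
            generate_synthetic_trial(cfg)


class TestValidation:
    def test_valid_minimal_frame(self, minimal_dataset):
        assert validate_trial(minimal_dataset) == []

    def test_control_with_enrollment_status(self):
        df = make_minimal_frame()
        df.loc[df["arm"] == "control", "enrolled"] = "yes"
        report = validate_trial(TrialDataset(df, []))
        assert any("enrolled defined for control arm" in v for v in report)

    def test_exposure_out_of_range(self):
        df = make_minimal_frame()
        df.loc[0, "exposure_fu1"] = 13.0
        report = validate_trial(TrialDataset(df, []))
        assert any("exposure_fu1" in v and "S000" in v for v in report)

    def test_negative_and_fractional_counts(self):
        df = make_minimal_frame().astype({"ed_visits_baseline": float})
        df.loc[1, "admissions_fu2"] = -1
        df.loc[2, "ed_visits_baseline"] = 1.5
        report = validate_trial(TrialDataset(df, []))
        assert any("admissions_fu2" in v for v in report)
        assert any("ed_visits_baseline" in v for v in report)

    def test_duplicate_subject_ids_reported(self):
        df = make_minimal_frame()
        df.loc[1, "subject_id"] = "S000"
        report = validate_trial(TrialDataset(df, []))
        assert any("duplicate" in v for v in report)


class TestTabularIO:
    def test_write_then_read_round_trip(self):
        ds = generate_synthetic_trial(SyntheticTrialConfig(seed=8))
        buf = io.StringIO()
        write_trial_table(ds, buf)
        buf.seek(0)
        back = read_trial_table(buf)
        pd.testing.assert_frame_equal(
            ds.subjects[back.subjects.columns], back.subjects
        )
        assert [(s.name, s.kind) for s in back.covariate_schema] == [
            (s.name, s.kind) for s in ds.covariate_schema
        ]

    def test_round_trip_is_byte_stable(self):
        ds = generate_synthetic_trial(SyntheticTrialConfig(seed=8))
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_trial_table(ds, buf1)
        buf1.seek(0)
        write_trial_table(read_trial_table(buf1), buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_small_file_parses(self):
        df = make_minimal_frame(2, 1)
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        ds = read_trial_table(buf)
        assert ds.n_subjects == 3

    def test_duplicate_id_raises_naming_id(self):
        df = make_minimal_frame()
        df.loc[1, "subject_id"] = "S000"
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(ParseError, match="S000"):
            read_trial_table(buf)

    def test_missing_required_column_named(self):
        df = make_minimal_frame().drop(columns=["exposure_fu1"])
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(ParseError, match="exposure_fu1"):
            read_trial_table(buf)

    def test_non_numeric_count_reports_row(self):
        df = make_minimal_frame().astype({"admissions_fu1": object})
        df.loc[2, "admissions_fu1"] = "two"
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(ParseError, match="admissions_fu1.*row 2"):
            read_trial_table(buf)

    def test_categorical_value_with_comma_is_quoted(self):
        df = make_minimal_frame()
        df["clinic"] = "Smith, Jones & Co"
        ds = TrialDataset(df, [])
        buf = io.StringIO()
        write_trial_table(read_trial_table(io.StringIO(df.to_csv(index=False))), buf)
        buf.seek(0)
        back = read_trial_table(buf)
        assert (back.subjects["clinic"] == "Smith, Jones & Co").all()

    def test_empty_covariate_dataset_writes_required_columns_only(
        self, minimal_dataset
    ):
        buf = io.StringIO()
        write_trial_table(minimal_dataset, buf)
        buf.seek(0)
        header = buf.getvalue().splitlines()[0].split(",")
        assert header == required_columns()

    def test_long_layout_round_trip(self):
        ds = generate_synthetic_trial(
            SyntheticTrialConfig(n_intervention=20, n_control=20, seed=1)
        )
        long_rows = []
        for p in PERIODS:
            part = ds.subjects[
                ["subject_id", "arm", "enrolled"] + ds.covariate_names
            ].copy()
            part["period"] = p
            part["exposure_months"] = ds.subjects[f"exposure_{p}"]
            for o in COUNT_OUTCOMES:
                part[o] = ds.subjects[f"{o}_{p}"]
            part["cost"] = ds.subjects[f"cost_{p}"]
            long_rows.append(part)
        buf = io.StringIO()
        pd.concat(long_rows, ignore_index=True).to_csv(buf, index=False)
        buf.seek(0)
        back = read_trial_table(buf, layout="long")
        merged = back.subjects.set_index("subject_id").loc[
            ds.subjects["subject_id"]
        ]
        for col in ["admissions_fu1", "cost_fu2", "exposure_baseline"]:
            np.testing.assert_allclose(
                merged[col].to_numpy(float), ds.subjects[col].to_numpy(float)
            )

    def test_missing_covariate_round_trips_as_nan(self):
        ds = generate_synthetic_trial(
            SyntheticTrialConfig(seed=2, missing_rate=0.2)
        )
        assert ds.subjects["x1"].isna().any()
        buf = io.StringIO()
        write_trial_table(ds, buf)
        buf.seek(0)
        back = read_trial_table(buf)
        assert (
            back.subjects["x1"].isna().to_numpy()
            == ds.subjects["x1"].isna().to_numpy()
        ).all()
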