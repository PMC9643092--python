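import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from distillrct import (
    StageOneSettings,
    SyntheticTrialConfig,
    TrialDataset,
    fit_participation_model,
    generate_synthetic_trial,
    score_subjects,
)
from distillrct.trial_data import COUNT_OUTCOMES, PERIODS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: small stage-one settings used throughout the tests; the production
#: defaults (10 folds, 10,000 trees, learning rate 0.001) are exercised for
#: their values, not their runtime
FAST_STAGE_ONE = StageOneSettings(
    folds=5, max_trees=250, learning_rate=0.05, seed=0
)


def make_minimal_frame(n_interv=4, n_control=4):
    """A valid all-zero wide table to mutate in invariant tests."""
    n = n_interv + n_control
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "arm": ["intervention"] * n_interv + ["control"] * n_control,
            "enrolled": ["yes", "no"] * (n_interv // 2)
            + ["yes"] * (n_interv % 2)
            + [np.nan] * n_control,
        }
    )
    for p in PERIODS:
        df[f"exposure_{p}"] = 12.0
    for o in COUNT_OUTCOMES:
        for p in PERIODS:
            df[f"{o}_{p}"] = 1
    for p in PERIODS:
        df[f"cost_{p}"] = 100.0
    return df


@pytest.fixture
def minimal_dataset():
    return TrialDataset(make_minimal_frame(), [])


@pytest.fixture(scope="session")
def small_trial():
    """A modest synthetic trial with a strong uptake signal."""
    return generate_synthetic_trial(
        SyntheticTrialConfig(
            n_intervention=150,
            n_control=150,
            n_covariates=6,
            covariate_enrollment_signal=2.5,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_trial_scored(small_trial):
    fit = fit_participation_model(small_trial, FAST_STAGE_ONE)
    return fit, score_subjects(fit, small_trial)


def saturated_toy():
    """4+4 subjects whose cell means admit a closed-form Poisson DiD fit:

    intervention baseline mean 2, post mean 1; control 2 and 2; equal
    offsets, no frailty, so tau-hat = ln((1/2)/(2/2)) = ln(1/2).
    """
    df = make_minimal_frame(4, 4)
    df["admissions_baseline"] = 2
    df["admissions_fu1"] = [1, 1, 1, 1, 2, 2, 2, 2]
    return TrialDataset(df, [])
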