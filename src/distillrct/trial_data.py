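"""Subject-level trial data model, tabular I/O and the synthetic-trial generator.

The in-memory container is a wide :class:`pandas.DataFrame` (one row per
subject) wrapped by :class:`TrialDataset`, which carries the covariate schema
alongside the table.  Column contract for the wide layout:

``subject_id, arm, enrolled, <covariates...>,
exposure_baseline, exposure_fu1, exposure_fu2,
<outcome>_<period> for each count outcome and period,
cost_baseline, cost_fu1, cost_fu2``

``arm`` is ``intervention``/``control``; ``enrolled`` is ``yes``/``no`` for
intervention-arm subjects and empty (missing) for controls, where enrollment
is undefined.  A long layout (one row per subject x period) is also accepted,
see :func:`read_trial_table`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigurationError, ParseError

PERIODS: tuple[str, ...] = ("baseline", "fu1", "fu2")
COUNT_OUTCOMES: tuple[str, ...] = (
    "admissions",
    "inpatient_days",
    "ed_visits",
    "ambulatory_visits",
)
COST_OUTCOME = "cost"
OUTCOMES: tuple[str, ...] = COUNT_OUTCOMES + (COST_OUTCOME,)
ARMS: tuple[str, str] = ("intervention", "control")
MAX_EXPOSURE_MONTHS = 12.0


def required_columns() -> list[str]:
    """Non-covariate columns every wide-format trial table must carry."""
    cols = ["subject_id", "arm", "enrolled"]
    cols += [f"exposure_{p}" for p in PERIODS]
    for outcome in OUTCOMES:
        cols += [f"{outcome}_{p}" for p in PERIODS]
    return cols


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: its column name and declared kind."""

    name: str
    kind: str  # "real" | "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("real", "categorical"):
            raise ConfigurationError(
                f"covariate {self.name!r}: kind must be 'real' or 'categorical', "
                f"got {self.kind!r}"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """A single subject, unpacked from the wide table (mainly for inspection)."""

    subject_id: str
    arm: str
    enrolled: str | None  # "yes"/"no", None for control arm
    covariates: Mapping[str, object]
    exposure_months: Mapping[str, float]
    counts: Mapping[str, Mapping[str, int]]  # outcome -> period -> count
    cost: Mapping[str, float]  # period -> cost


@dataclass
class TrialDataset:
    """Wide subject-level table plus its covariate schema."""

    subjects: pd.DataFrame
    covariate_schema: list[CovariateSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in required_columns() if c not in self.subjects.columns]
        if missing:
            raise ParseError(f"missing required column(s): {', '.join(missing)}")
        for spec in self.covariate_schema:
            if spec.name not in self.subjects.columns:
                raise ParseError(f"missing covariate column: {spec.name}")
        self.subjects = self.subjects.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> pd.Series:
        return self.subjects["subject_id"]

    @property
    def covariate_names(self) -> list[str]:
        return [s.name for s in self.covariate_schema]

    def arm_counts(self) -> dict[str, int]:
        vc = self.subjects["arm"].value_counts()
        return {arm: int(vc.get(arm, 0)) for arm in ARMS}

    def covariate_frame(self) -> pd.DataFrame:
        """Covariate columns indexed by subject_id (schema order)."""
        frame = self.subjects.set_index("subject_id")[self.covariate_names]
        return frame

    def arm_mask(self, arm: str) -> np.ndarray:
        return (self.subjects["arm"] == arm).to_numpy()

    def subset(self, subject_ids: Iterable[str]) -> "TrialDataset":
        """Restrict to the given subjects (order of the original table kept)."""
        wanted = set(subject_ids)
        mask = self.subjects["subject_id"].isin(wanted).to_numpy()
        return TrialDataset(
            self.subjects.loc[mask].reset_index(drop=True),
            list(self.covariate_schema),
        )

    def iter_records(self) -> Iterator[SubjectRecord]:
        for _, row in self.subjects.iterrows():
            enrolled = row["enrolled"]
            yield SubjectRecord(
                subject_id=row["subject_id"],
                arm=row["arm"],
                enrolled=None if pd.isna(enrolled) else str(enrolled),
                covariates={n: row[n] for n in self.covariate_names},
                exposure_months={p: float(row[f"exposure_{p}"]) for p in PERIODS},
                counts={
                    o: {p: int(row[f"{o}_{p}"]) for p in PERIODS}
                    for o in COUNT_OUTCOMES
                },
                cost={p: float(row[f"{COST_OUTCOME}_{p}"]) for p in PERIODS},
            )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_trial(dataset: TrialDataset) -> list[str]:
    """Check the dataset invariants; return a list of violation messages.

    An empty list means the dataset is valid.  Violations are data, not
    exceptions: each message names the subject (where applicable) and the
    rule that failed.
    """
    df = dataset.subjects
    violations: list[str] = []

    dup = df["subject_id"][df["subject_id"].duplicated()]
    for sid in dup.unique():
        violations.append(f"subject {sid!r}: duplicate subject_id")

    bad_arm = df.loc[~df["arm"].isin(ARMS), "subject_id"]
    for sid in bad_arm:
        violations.append(f"subject {sid!r}: arm must be one of {ARMS}")

    counts = pd.Series(dataset.arm_counts())
    for arm in ARMS:
        if counts[arm] == 0:
            violations.append(f"dataset: {arm} arm is empty")

    enrolled = df["enrolled"]
    ctrl = df["arm"] == "control"
    for sid in df.loc[ctrl & enrolled.notna(), "subject_id"]:
        violations.append(f"subject {sid!r}: enrolled defined for control arm")
    for sid in df.loc[~ctrl & enrolled.isna(), "subject_id"]:
        violations.append(f"subject {sid!r}: enrolled missing for intervention arm")
    bad_enr = (~ctrl) & enrolled.notna() & ~enrolled.isin(["yes", "no"])
    for sid in df.loc[bad_enr, "subject_id"]:
        violations.append(f"subject {sid!r}: enrolled must be 'yes' or 'no'")

    for p in PERIODS:
        col = df[f"exposure_{p}"]
        bad = col.isna() | (col < 0) | (col > MAX_EXPOSURE_MONTHS)
        for sid in df.loc[bad, "subject_id"]:
            violations.append(
                f"subject {sid!r}: exposure_{p} must lie in [0, {MAX_EXPOSURE_MONTHS:g}]"
            )

    for o in COUNT_OUTCOMES:
        for p in PERIODS:
            col = df[f"{o}_{p}"]
            nonint = col.notna() & (col != np.floor(col))
            bad = col.isna() | (col < 0) | nonint
            for sid in df.loc[bad, "subject_id"]:
                violations.append(
                    f"subject {sid!r}: {o}_{p} must be a nonnegative integer"
                )
    for p in PERIODS:
        col = df[f"{COST_OUTCOME}_{p}"]
        bad = col.isna() | (col < 0)
        for sid in df.loc[bad, "subject_id"]:
            violations.append(f"subject {sid!r}: cost_{p} must be a nonnegative real")

    return violations


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_LONG_VALUE_COLUMNS = ["exposure_months"] + list(COUNT_OUTCOMES) + [COST_OUTCOME]


def _infer_schema(df: pd.DataFrame) -> list[CovariateSpec]:
    req = set(required_columns()) | {"period"} | set(_LONG_VALUE_COLUMNS)
    specs = []
    for col in df.columns:
        if col in req:
            continue
        kind = "real" if pd.api.types.is_numeric_dtype(df[col]) else "categorical"
        specs.append(CovariateSpec(col, kind))
    return specs


def read_trial_table(
    source,
    schema: Sequence[CovariateSpec] | None = None,
    layout: str = "wide",
) -> TrialDataset:
    """Read a delimited-text trial table into a :class:`TrialDataset`.

    Parameters
    ----------
    source
        Path or open text handle of a UTF-8 CSV (RFC-4180 quoting).
    schema
        Covariate schema.  When omitted, every non-required column is taken
        as a covariate and its kind inferred from the parsed dtype.
    layout
        ``"wide"`` (one row per subject, the default) or ``"long"`` (one row
        per subject x period with columns ``subject_id, arm, enrolled,
        <covariates...>, period, exposure_months, admissions, inpatient_days,
        ed_visits, ambulatory_visits, cost``).

    Missing covariates are represented by an empty field and parsed to NaN
    (real) or NA (categorical); no imputation happens here.
    """
    if layout not in ("wide", "long"):
        raise ParseError(f"unknown layout {layout!r}")
    df = pd.read_csv(
        source,
        dtype={"subject_id": str, "enrolled": str},
        float_precision="round_trip",  # values invert write_trial_table exactly
    )
    if layout == "long":
        df = _long_to_wide(df)

    missing = [c for c in required_columns() if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")

    for o in COUNT_OUTCOMES:
        for p in PERIODS:
            col = df[f"{o}_{p}"]
            if not pd.api.types.is_numeric_dtype(col):
                bad = pd.to_numeric(col, errors="coerce").isna() & col.notna()
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(f"non-numeric count in column {o}_{p}, row {row}")

    if schema is None:
        schema = _infer_schema(df)
    dataset = TrialDataset(df, list(schema))

    dup = dataset.subjects["subject_id"][dataset.subjects["subject_id"].duplicated()]
    if len(dup):
        raise ParseError(f"duplicate subject_id {dup.iloc[0]!r}")
    return dataset


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    needed = ["subject_id", "arm", "enrolled", "period"] + _LONG_VALUE_COLUMNS
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(
            f"long layout: missing required column(s): {', '.join(missing)}"
        )
    bad = ~df["period"].isin(PERIODS)
    if bad.any():
        raise ParseError(f"long layout: unknown period {df.loc[bad, 'period'].iloc[0]!r}")
    covs = [c for c in df.columns if c not in needed]
    head = df.drop_duplicates("subject_id")[["subject_id", "arm", "enrolled"] + covs]
    wide = head.set_index("subject_id")
    piv = df.pivot(index="subject_id", columns="period", values=_LONG_VALUE_COLUMNS)
    for o in COUNT_OUTCOMES + (COST_OUTCOME,):
        for p in PERIODS:
            wide[f"{o}_{p}"] = piv[(o, p)]
    for p in PERIODS:
        wide[f"exposure_{p}"] = piv[("exposure_months", p)]
    return wide.reset_index()


def write_trial_table(dataset: TrialDataset, sink) -> None:
    """Write a wide-format CSV with a deterministic column order.

    Column order: required identifier/exposure/outcome columns first (in the
    order of :func:`required_columns`), then covariates in schema order.
    Values round-trip bit-exactly through :func:`read_trial_table`.
    """
    cols = required_columns() + dataset.covariate_names
    out = dataset.subjects[cols]
    out.to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# Synthetic-trial generator
# ---------------------------------------------------------------------------

#: Annual event rates / cost moments for a high-utilization complex-care
#: population: ~1.2 admissions, ~6 inpatient days, ~2.5 ED visits and ~20
#: ambulatory visits per person-year, with a mean total cost of ~30k
#: currency units (gamma, shape 1.2, i.e. heavily right-skewed).
DEFAULT_BASELINE_RATES: dict[str, float] = {
    "admissions": 1.2,
    "inpatient_days": 6.0,
    "ed_visits": 2.5,
    "ambulatory_visits": 20.0,
}
DEFAULT_COST_MEAN = 30_000.0
DEFAULT_COST_SHAPE = 1.2


@dataclass
class SyntheticTrialConfig:
    """Parameters of the synthetic two-arm trial.

    Defaults emulate the motivating complex-care pilot: 404 subjects
    randomized to intervention, 401 to control, and a 64.6% marginal
    enrollment rate in the intervention arm.  ``covariate_enrollment_signal``
    is the standard deviation, on the logit scale, of the linear covariate
    score driving enrollment propensity (0 = enrollment independent of
    covariates).  ``effect_size_log_scale`` multiplies follow-up outcome
    rates/means by ``exp(effect)`` for treated-enrolled responders only;
    the default 0 generates a null trial.
    """

    n_intervention: int = 404
    n_control: int = 401
    enrollment_rate: float = 0.646
    n_covariates: int = 10
    covariate_enrollment_signal: float = 2.0
    responder_fraction: float = 0.40
    responder_enrollment_corr: float = 0.30
    effect_size_log_scale: float = 0.0
    baseline_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES)
    )
    cost_mean: float = DEFAULT_COST_MEAN
    cost_shape: float = DEFAULT_COST_SHAPE
    frailty_sd: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_intervention < 1 or self.n_control < 1:
            raise ConfigurationError("n_intervention and n_control must be >= 1")
        if not 0.0 < self.enrollment_rate < 1.0:
            raise ConfigurationError("enrollment_rate must lie in (0, 1)")
        if self.n_covariates < 1:
            raise ConfigurationError("n_covariates must be >= 1")
        if self.covariate_enrollment_signal < 0:
            raise ConfigurationError("covariate_enrollment_signal must be >= 0")
        if not 0.0 < self.responder_fraction <= 1.0:
            raise ConfigurationError("responder_fraction must lie in (0, 1]")
        if not -1.0 < self.responder_enrollment_corr < 1.0:
            raise ConfigurationError("responder_enrollment_corr must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        for name in COUNT_OUTCOMES:
            if self.baseline_rates.get(name, -1.0) <= 0:
                raise ConfigurationError(f"baseline_rates[{name!r}] must be > 0")
        if self.cost_mean <= 0 or self.cost_shape <= 0:
            raise ConfigurationError("cost_mean and cost_shape must be > 0")
        if self.frailty_sd < 0:
            raise ConfigurationError("frailty_sd must be >= 0")


def _covariate_layout(n_covariates: int) -> list[CovariateSpec]:
    """Mix of kinds: ~60% continuous, one 3-level categorical, rest binary."""
    n_real = max(1, math.ceil(0.6 * n_covariates))
    n_real = min(n_real, n_covariates)
    specs = [CovariateSpec(f"x{j + 1}", "real") for j in range(n_real)]
    rest = n_covariates - n_real
    if rest >= 1:
        specs.append(CovariateSpec("site", "categorical"))
        rest -= 1
    specs += [CovariateSpec(f"b{j + 1}", "categorical") for j in range(rest)]
    return specs


def generate_synthetic_trial(config: SyntheticTrialConfig) -> TrialDataset:
    """Generate a reproducible synthetic two-arm trial.

    Generation law
    --------------
    * Covariates: continuous covariates are standard normal; binary
      covariates are Bernoulli(0.3) ("yes"/"no"); one 3-level "site"
      covariate is uniform over {A, B, C}.  Generated identically in both
      arms.
    * Enrollment: a linear score over standardized covariate effects, with
      geometrically decaying weights (x1 largest), is scaled to standard
      deviation ``covariate_enrollment_signal`` on the logit scale.  The
      intercept is solved numerically so the mean inverse-logit propensity
      over the intervention arm equals ``enrollment_rate``; intervention
      subjects then enroll Bernoulli(propensity).  Controls carry no
      enrollment status.
    * Responder status: a latent with correlation
      ``responder_enrollment_corr`` to the standardized enrollment score;
      the top ``responder_fraction`` of the pooled sample (rank threshold)
      are responders.
    * Outcomes: counts are Poisson with a subject-level log-normal frailty
      (sd ``frailty_sd`` on the log scale, mean 1) shared across periods
      and count outcomes; cost is gamma with its own frailty.  Rates scale
      with exposure months / 12.  Follow-up rates and cost means of
      treated-enrolled responders are multiplied by
      ``exp(effect_size_log_scale)``; apart from that term the generation
      law is identical in both arms.
    * Exposure: 12 months at baseline; each follow-up year is 12 months
      with probability 0.92 and Uniform(1, 12) otherwise (disenrollment).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_intervention + config.n_control
    schema = _covariate_layout(config.n_covariates)

    width = len(str(n))
    ids = np.array([f"S{i + 1:0{width}d}" for i in range(n)])
    arm = np.array(
        ["intervention"] * config.n_intervention + ["control"] * config.n_control
    )

    # covariates + their standardized "effect" encodings for the linear score
    values: dict[str, np.ndarray] = {}
    effects = np.empty((n, len(schema)))
    for j, spec in enumerate(schema):
        if spec.kind == "real":
            v = rng.standard_normal(n)
            values[spec.name] = v
            effects[:, j] = v
        elif spec.name == "site":
            lv = rng.integers(0, 3, size=n)
            values[spec.name] = np.array(["A", "B", "C"])[lv]
            # level effects -1/0/+1, standardized
            e = lv.astype(float) - 1.0
            effects[:, j] = e / np.sqrt(2.0 / 3.0)
        else:
            v = rng.random(n) < 0.3
            values[spec.name] = np.where(v, "yes", "no")
            effects[:, j] = (v - 0.3) / np.sqrt(0.3 * 0.7)

    weights = 0.75 ** np.arange(len(schema))
    raw = effects @ weights
    sd_raw = float(np.sqrt(weights @ weights))  # effects are ~unit-variance, indep.
    score = config.covariate_enrollment_signal * raw / sd_raw
    score_std = raw / sd_raw

    # intercept calibrated so the mean propensity in the intervention arm
    # equals the target marginal enrollment rate
    interv = arm == "intervention"
    s_int = score[interv]

    def gap(c: float) -> float:
        return float(np.mean(expit(c + s_int))) - config.enrollment_rate

    intercept = brentq(gap, -40.0, 40.0)
    propensity = expit(intercept + score)
    enrolled_flag = interv & (rng.random(n) < propensity)
    enrolled = np.where(enrolled_flag, "yes", "no").astype(object)
    enrolled[~interv] = np.nan

    # responder status: latent correlated with the enrollment score
    rho = config.responder_enrollment_corr
    resp_latent = rho * score_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    k_resp = int(np.floor(config.responder_fraction * n + 0.5))
    responder = np.zeros(n, dtype=bool)
    responder[np.argsort(resp_latent)[n - k_resp:]] = True

    treated = interv & enrolled_flag & responder
    effect_mult = float(np.exp(config.effect_size_log_scale))

    exposure = {p: np.full(n, 12.0) for p in PERIODS}
    for p in ("fu1", "fu2"):
        partial = rng.random(n) >= 0.92
        exposure[p] = np.where(partial, rng.uniform(1.0, 12.0, size=n), 12.0)
        exposure[p] = np.round(exposure[p], 2)

    frailty_counts = np.exp(
        rng.normal(0.0, config.frailty_sd, size=n) - config.frailty_sd**2 / 2
    )
    frailty_cost = np.exp(
        rng.normal(0.0, config.frailty_sd, size=n) - config.frailty_sd**2 / 2
    )

    data: dict[str, np.ndarray] = {
        "subject_id": ids,
        "arm": arm,
        "enrolled": enrolled,
    }
    for p in PERIODS:
        data[f"exposure_{p}"] = exposure[p]
    for outcome, rate in ((o, config.baseline_rates[o]) for o in COUNT_OUTCOMES):
        for p in PERIODS:
            mult = np.where(treated & (p != "baseline"), effect_mult, 1.0)
            lam = rate * (exposure[p] / 12.0) * frailty_counts * mult
            data[f"{outcome}_{p}"] = rng.poisson(lam)
    for p in PERIODS:
        mult = np.where(treated & (p != "baseline"), effect_mult, 1.0)
        mean = config.cost_mean * (exposure[p] / 12.0) * frailty_cost * mult
        shape = config.cost_shape
        data[f"{COST_OUTCOME}_{p}"] = np.round(
            rng.gamma(shape, mean / shape), 2
        )
    for spec in schema:
        data[spec.name] = values[spec.name]

    df = pd.DataFrame(data)
    if config.missing_rate > 0:
        for spec in schema:
            if spec.kind == "real":
                hole = rng.random(n) < config.missing_rate
                df.loc[hole, spec.name] = np.nan
    return TrialDataset(df, schema)
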