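"""Stage three: difference-in-differences outcome models on distilled subsets.

For each outcome and each follow-up year, a two-period (baseline vs
follow-up) generalized linear mixed model is fit on the retained subjects:

    ln lambda_it = beta0_i + beta_t I(t = post) + beta_int I(intervention)
                   + tau I(t = post) I(intervention),
    beta0_i ~ Normal(beta0, sigma^2),

with a log exposure-months offset; Poisson for encounter counts, gamma with
log link for costs.  ``tau`` — the post x intervention interaction — is the
difference-in-differences treatment effect on the log scale, with an
approximate percent-change interpretation ``exp(tau) - 1``.  Under
randomization ``beta_int`` is centered at zero.

If the mixed fit does not converge, or the random-intercept variance is
estimated at (essentially) zero, the model is refit as a fixed-effects GLM
with subject-clustered sandwich standard errors and ``fallback_used`` is set.
Structural failures (an arm emptied by distillation) raise
:class:`~distillrct.errors.EstimationError`; numerical failures are reported
in the estimate with ``converged=False`` and never crash a grid run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .distill import DistillationLadder, DistillationLevel
from .errors import EstimationError
from .glmm import RandomInterceptGLMM
from .trial_data import COUNT_OUTCOMES, COST_OUTCOME, TrialDataset

logger = logging.getLogger(__name__)

FOLLOW_UPS = ("fu1", "fu2")

#: outcome -> family for the standard grid
DEFAULT_OUTCOME_FAMILIES: dict[str, str] = {
    **{o: "poisson" for o in COUNT_OUTCOMES},
    COST_OUTCOME: "gamma",
}


@dataclass(frozen=True)
class DiDModelSpec:
    """One grid cell's model: outcome, family and follow-up period.

    Exactly two periods enter each fit: ``baseline`` and ``follow_up``.
    ``zero_cost_floor`` (gamma only) replaces period costs of exactly zero,
    which lie outside the gamma support, by a small positive constant; the
    number of floored observations is reported on the estimate.
    """

    outcome: str
    family: str  # "poisson" | "gamma"
    follow_up: str = "fu1"
    zero_cost_floor: float = 1.0

    def __post_init__(self):
        if self.family not in ("poisson", "gamma"):
            raise EstimationError(f"unsupported family {self.family!r}")
        if self.follow_up not in FOLLOW_UPS:
            raise EstimationError(f"follow_up must be one of {FOLLOW_UPS}")
        if self.zero_cost_floor <= 0:
            raise EstimationError("zero_cost_floor must be > 0")


@dataclass
class EffectEstimate:
    """Difference-in-differences treatment effect for one grid cell."""

    tau: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    beta_t: float
    beta_intervention: float
    beta0: float
    sigma2_re: float
    n_subjects: int
    n_obs: int
    family: str
    converged: bool
    fallback_used: bool
    n_cost_floored: int = 0

    @property
    def pct_change(self) -> float:
        return percent_change(self.tau)


def percent_change(tau: float) -> float:
    """Multiplicative effect ``exp(tau) - 1`` as a signed fraction."""
    return float(np.exp(tau) - 1.0)


def _long_frame(
    dataset: TrialDataset, spec: DiDModelSpec
) -> tuple[pd.DataFrame, int]:
    """Two rows per subject (baseline, follow-up); drops zero-exposure rows."""
    df = dataset.subjects
    rows = []
    for period, post in ((
        "baseline", 0), (spec.follow_up, 1)):
        col = f"{spec.outcome}_{period}"
        if col not in df.columns:
            raise EstimationError(f"unknown outcome column {col!r}")
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": df["subject_id"],
                    "intervention": (df["arm"] == "intervention").astype(int),
                    "post": post,
                    "y": df[col].to_numpy(float),
                    "exposure": df[f"exposure_{period}"].to_numpy(float),
                }
            )
        )
    long = pd.concat(rows, ignore_index=True)
    zero_exp = long["exposure"] <= 0
    if zero_exp.any():
        logger.warning(
            "dropping %d subject-period rows with zero exposure months",
            int(zero_exp.sum()),
        )
        long = long.loc[~zero_exp].reset_index(drop=True)
    n_floored = 0
    if spec.family == "gamma":
        zero_y = long["y"] < spec.zero_cost_floor
        n_floored = int(zero_y.sum())
        long.loc[zero_y, "y"] = spec.zero_cost_floor
    return long, n_floored


def fit_did_model(
    dataset: TrialDataset,
    spec: DiDModelSpec,
    level: DistillationLevel | Iterable[str] | None = None,
    sigma2_fallback_tol: float = 1e-4,
) -> EffectEstimate:
    """Fit the two-period difference-in-differences GLMM for one cell.

    ``level`` restricts the fit to a distilled subset (a
    :class:`DistillationLevel` or any iterable of subject ids); ``None``
    uses the full dataset, i.e. the conventional ITT fit.
    """
    if level is not None:
        ids = level.retained_ids if isinstance(level, DistillationLevel) else level
        dataset = dataset.subset(ids)
    counts = dataset.arm_counts()
    for arm, n in counts.items():
        if n < 2:
            raise EstimationError(
                f"arm exhausted: {arm} arm has {n} subject(s) after distillation"
            )

    long, n_floored = _long_frame(dataset, spec)
    y = long["y"].to_numpy(float)
    X = np.column_stack(
        [
            np.ones(len(long)),
            long["post"].to_numpy(float),
            long["intervention"].to_numpy(float),
            (long["post"] * long["intervention"]).to_numpy(float),
        ]
    )
    offset = np.log(long["exposure"].to_numpy(float))
    groups = long["subject_id"].to_numpy()

    def _wrap(params, bse, sigma2, converged, fallback):
        tau, se = float(params[3]), float(bse[3])
        return EffectEstimate(
            tau=tau,
            se=se,
            ci95=(tau - 1.96 * se, tau + 1.96 * se),
            p_value=float(2.0 * norm.sf(abs(tau) / se)) if se > 0 else float("nan"),
            beta_t=float(params[1]),
            beta_intervention=float(params[2]),
            beta0=float(params[0]),
            sigma2_re=float(sigma2),
            n_subjects=dataset.n_subjects,
            n_obs=len(long),
            family=spec.family,
            converged=converged,
            fallback_used=fallback,
            n_cost_floored=n_floored,
        )

    mixed_exc: Exception | None = None
    try:
        mixed = RandomInterceptGLMM(family=spec.family).fit(y, X, offset, groups)
        if mixed.converged and not mixed.boundary_sigma and (
            mixed.sigma2 > sigma2_fallback_tol
        ):
            return _wrap(mixed.params, mixed.bse, mixed.sigma2, True, False)
    except Exception as exc:  # numerical failure: fall through to GLM
        mixed_exc = exc
        logger.warning("mixed fit failed (%s); using cluster-robust GLM", exc)

    try:
        fam = (
            sm.families.Poisson()
            if spec.family == "poisson"
            else sm.families.Gamma(link=sm.families.links.Log())
        )
        scale = "X2" if spec.family == "gamma" else 1.0
        glm = sm.GLM(y, X, family=fam, offset=offset).fit(
            scale=scale, cov_type="cluster", cov_kwds={"groups": groups}
        )
        return _wrap(glm.params, glm.bse, 0.0, True, True)
    except Exception as exc:
        logger.warning("fallback GLM failed too (%s); cell flagged", exc)
        nan4 = np.full(4, np.nan)
        est = _wrap(nan4, nan4, float("nan"), False, True)
        if mixed_exc is not None:
            logger.debug("original mixed-fit error: %s", mixed_exc)
        return est


def run_outcome_grid(
    dataset: TrialDataset,
    ladder: DistillationLadder,
    outcomes: Sequence[tuple[str, str]] | None = None,
    periods: Sequence[str] = FOLLOW_UPS,
    zero_cost_floor: float = 1.0,
) -> pd.DataFrame:
    """Fit every (outcome, follow-up period, retention level) cell.

    Returns a tidy long table with one row per cell — the tabular analogue
    of the grid-of-forest-plots display (outcomes x periods, effect vs
    retention).  Cells that fail numerically are recorded with
    ``converged=False``; an arm exhausted by distillation is likewise
    recorded, not raised, so one bad cell never aborts the grid.
    """
    if outcomes is None:
        outcomes = list(DEFAULT_OUTCOME_FAMILIES.items())
    records = []
    for outcome, family in outcomes:
        for period in periods:
            spec = DiDModelSpec(
                outcome=outcome,
                family=family,
                follow_up=period,
                zero_cost_floor=zero_cost_floor,
            )
            for lv in ladder:
                try:
                    est = fit_did_model(dataset, spec, level=lv)
                except EstimationError as exc:
                    logger.warning(
                        "cell (%s, %s, %.2f): %s", outcome, period,
                        lv.retention_fraction, exc,
                    )
                    est = None
                records.append(
                    {
                        "outcome": outcome,
                        "period": period,
                        "retention_fraction": lv.retention_fraction,
                        "family": family,
                        "tau": est.tau if est else float("nan"),
                        "se": est.se if est else float("nan"),
                        "ci_low": est.ci95[0] if est else float("nan"),
                        "ci_high": est.ci95[1] if est else float("nan"),
                        "p_value": est.p_value if est else float("nan"),
                        "pct_change": est.pct_change if est else float("nan"),
                        "n_subjects": est.n_subjects if est else lv.n_retained,
                        "converged": bool(est.converged) if est else False,
                        "fallback_used": bool(est.fallback_used) if est else False,
                        "n_cost_floored": est.n_cost_floored if est else 0,
                    }
                )
    return pd.DataFrame.from_records(records)
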