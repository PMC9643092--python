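"""Monte-Carlo power and type-I-error study of the distillation design.

Each simulated trial draws, per subject, a trio of correlated standard
normals — a treatment-effect latent, a participation latent and a
prediction-of-participation latent — plus independent N(0, 1) outcome noise.
Subjects in the top ``responder_fraction`` of the treatment-effect latent
(sample-rank threshold, so the fraction is exact) are responders; the top
``enroll_fraction`` of the participation latent, intersected with the
intervention arm, are enrolled.  The outcome is

    y = eps + taumax * I(responder) * I(enrolled) * I(intervention),

i.e. the treatment value ``taumax`` (log scale, <= 0 for a beneficial
effect) is realized only by enrolled intervention-arm responders.  Arms are
allocated 1:1.  Distillation retains the top fraction of the *pooled* sample
by the prediction latent (no stage-one refit by default; nested within a
replicate exactly as in :mod:`distillrct.distill`) and the arms are compared
with a two-sided Welch t-test at level ``alpha``.

The default scenario uses responder/enrollment fractions of 0.40 and
correlations 0.30 (effect-participation), 0.80 (effect-prediction) and 0.80
(participation-prediction) — a favorable regime chosen to make the
properties of the method visible.  An alternative reading of the generating
law, in which the outcome itself is one of the three correlated normals and
enrollment is thresholded on the prediction latent, is available via
``latent_mode="outcome-triple"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distill import DEFAULT_RETENTION_GRID, round_half_away
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Treatment values shown in the illustrative scenario.
DEFAULT_TAUMAX_GRID: tuple[float, ...] = (0.0, -0.1, -0.2, -0.3, -0.4, -0.5)


def _as_seed_int(*parts: int) -> int:
    """Deterministically fold integers into a sub-2^31 seed."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation design (a taumax value and its settings)."""

    taumax: float = 0.0
    n_per_arm: int = 2000
    responder_fraction: float = 0.40
    enroll_fraction: float = 0.40
    rho_te_part: float = 0.30
    rho_te_pred: float = 0.80
    rho_part_pred: float = 0.80
    alpha: float = 0.05
    retention_grid: tuple[float, ...] = DEFAULT_RETENTION_GRID
    reps: int = 2000
    seed: int = 0
    latent_mode: str = "participation-triple"
    distill_by: str = "pred_latent"  # | "refit_classifier"

    def corr_matrix(self) -> np.ndarray:
        """Correlation of (treatment-effect, participation, prediction)."""
        return np.array(
            [
                [1.0, self.rho_te_part, self.rho_te_pred],
                [self.rho_te_part, 1.0, self.rho_part_pred],
                [self.rho_te_pred, self.rho_part_pred, 1.0],
            ]
        )

    def validate(self) -> None:
        if self.taumax > 0:
            raise ConfigurationError("taumax must be <= 0 (a beneficial effect)")
        if self.n_per_arm < 2:
            raise ConfigurationError("n_per_arm must be >= 2")
        for name in ("responder_fraction", "enroll_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not self.retention_grid:
            raise ConfigurationError("retention_grid must be nonempty")
        for f in self.retention_grid:
            if not 0.0 < f <= 1.0:
                raise ConfigurationError("retention fractions must lie in (0, 1]")
        if len(set(self.retention_grid)) != len(self.retention_grid):
            raise ConfigurationError("retention fractions must be distinct")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if self.latent_mode not in ("participation-triple", "outcome-triple"):
            raise ConfigurationError(f"unknown latent_mode {self.latent_mode!r}")
        if self.distill_by not in ("pred_latent", "refit_classifier"):
            raise ConfigurationError(f"unknown distill_by {self.distill_by!r}")
        _cholesky_or_error(self.corr_matrix())


def _cholesky_or_error(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ConfigurationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ConfigurationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ConfigurationError("correlation matrix must have unit diagonal")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ConfigurationError("correlation matrix not PD") from None


def draw_correlated_latents(n: int, corr, seed) -> np.ndarray:
    """Draw ``n`` rows of standard-normal margins with the target correlation.

    Uses the triangular (Cholesky) factor transform of i.i.d. normals;
    reproducible given ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    """
    L = _cholesky_or_error(np.asarray(corr, dtype=float))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, L.shape[0])) @ L.T


def _top_fraction_mask(values: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask of the top round(fraction * n) values (rank threshold)."""
    n = len(values)
    k = round_half_away(fraction * n)
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        mask[np.argpartition(values, n - k)[n - k:]] = True
    return mask


@dataclass
class SimReplicate:
    """Per-subject arrays of one simulated trial."""

    arm: np.ndarray  # bool, True = intervention (1:1 allocation)
    te_latent: np.ndarray
    part_latent: np.ndarray
    pred_latent: np.ndarray
    responder: np.ndarray  # bool
    enrolled: np.ndarray  # bool, subset of the intervention arm
    outcome: np.ndarray


def simulate_trial_replicate(scenario: SimScenario, seed) -> SimReplicate:
    """Generate one trial under the scenario's law; reproducible given seed."""
    scenario.validate()
    rng = np.random.default_rng(seed)
    n = 2 * scenario.n_per_arm
    z = rng.standard_normal((n, 3)) @ _cholesky_or_error(scenario.corr_matrix()).T
    te, part, pred = z[:, 0], z[:, 1], z[:, 2]
    arm = np.zeros(n, dtype=bool)
    arm[: scenario.n_per_arm] = True  # subjects are i.i.d.; allocation is 1:1

    responder = _top_fraction_mask(te, scenario.responder_fraction)
    if scenario.latent_mode == "participation-triple":
        enrolled = _top_fraction_mask(part, scenario.enroll_fraction) & arm
        noise = rng.standard_normal(n)
    else:
        # outcome-in-triple reading: the second latent is the outcome noise
        # and enrollment is thresholded on the prediction latent itself
        enrolled = _top_fraction_mask(pred, scenario.enroll_fraction) & arm
        noise = part
    outcome = noise + scenario.taumax * (responder & enrolled)
    return SimReplicate(
        arm=arm,
        te_latent=te,
        part_latent=part,
        pred_latent=pred,
        responder=responder,
        enrolled=enrolled,
        outcome=outcome,
    )


def _distillation_scores(rep: SimReplicate, scenario: SimScenario, rng) -> np.ndarray:
    if scenario.distill_by == "pred_latent":
        return rep.pred_latent
    # full-method mode: refit a stage-one classifier per replicate on the
    # intervention arm (logistic on the prediction latent) and score everyone
    from sklearn.linear_model import LogisticRegression

    X = rep.pred_latent[:, None]
    y = rep.enrolled[rep.arm].astype(int)
    if y.min() == y.max():  # degenerate enrollment: fall back to the latent
        return rep.pred_latent
    lr = LogisticRegression().fit(X[rep.arm], y)
    return lr.predict_proba(X)[:, 1]


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


@dataclass
class PowerGrid:
    """Rejection rates over (taumax x retention) cells with MC uncertainty."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rejection_rate(self, taumax: float, retention_fraction: float) -> float:
        t = self.table
        row = t[
            (t["taumax"] == taumax) & (t["retention_fraction"] == retention_fraction)
        ]
        if row.empty:
            raise KeyError((taumax, retention_fraction))
        return float(row["rejection_rate"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_csv(self, sink) -> None:
        self.table.to_csv(sink, index=False)


def estimate_power_grid(
    scenarios: SimScenario | Sequence[SimScenario],
) -> PowerGrid:
    """Estimate rejection rates for every (scenario, retention) cell.

    Within each replicate the distilled subsets are nested (one shared
    ordering of the distillation score); cells where a retained arm has
    fewer than two subjects are skipped and counted in ``n_skipped``.
    ``mc_se = sqrt(r (1 - r) / reps)`` is the binomial Monte-Carlo standard
    error of each rejection rate.
    """
    if isinstance(scenarios, SimScenario):
        scenarios = [scenarios]
    records = []
    for scenario in scenarios:
        scenario.validate()
        fractions = sorted(scenario.retention_grid, reverse=True)
        n = 2 * scenario.n_per_arm
        rej = {f: 0 for f in fractions}
        used = {f: 0 for f in fractions}
        children = np.random.SeedSequence(scenario.seed).spawn(scenario.reps)
        aux_rng = np.random.default_rng(
            _as_seed_int(scenario.seed, 0x5EED)
        )
        for child in children:
            rep = simulate_trial_replicate(scenario, child)
            score = _distillation_scores(rep, scenario, aux_rng)
            order = np.argsort(score, kind="stable")
            for f in fractions:
                k = round_half_away(f * n)
                keep = order[n - k:]
                yi = rep.outcome[keep[rep.arm[keep]]]
                yc = rep.outcome[keep[~rep.arm[keep]]]
                if len(yi) < 2 or len(yc) < 2:
                    logger.warning(
                        "retention %.2f left an arm with <2 subjects; cell skipped",
                        f,
                    )
                    continue
                used[f] += 1
                rej[f] += _welch_p(yi, yc) < scenario.alpha
        for f in fractions:
            reps_f = used[f]
            rate = rej[f] / reps_f if reps_f else float("nan")
            records.append(
                {
                    "taumax": scenario.taumax,
                    "retention_fraction": f,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / reps_f))
                    if reps_f
                    else float("nan"),
                    "reps": reps_f,
                    "n_per_arm": scenario.n_per_arm,
                    "n_skipped": scenario.reps - reps_f,
                }
            )
    return PowerGrid(pd.DataFrame.from_records(records))


def scenario_grid(
    template: SimScenario, taumax_values: Sequence[float]
) -> list[SimScenario]:
    """One scenario per taumax value, with independently derived seeds."""
    if len(taumax_values) == 0:
        raise ConfigurationError("taumax grid must be nonempty")
    return [
        replace(template, taumax=t, seed=_as_seed_int(template.seed, i + 1))
        for i, t in enumerate(taumax_values)
    ]


def joint_top_fraction_probability(
    rho: float, q: float, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo P(X > z_q, Y > z_q) for bivariate standard normals.

    ``z_q`` is the (1 - q) quantile, so each margin exceeds its threshold
    with probability ``q``; at ``rho = 0`` the joint probability is ``q**2``
    and at ``rho = 1`` it is ``q``.  This is the brute-force oracle for the
    enrolled-and-responder overlap that drives the diluted effect size.
    """
    if not -1.0 < rho < 1.0:
        if rho in (-1.0, 1.0):  # comonotone limits have closed forms
            return max(0.0, 2 * q - 1.0) if rho == -1.0 else q
        raise ConfigurationError("rho must lie in [-1, 1]")
    if not 0.0 < q < 1.0:
        raise ConfigurationError("q must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - q)
    rng = np.random.default_rng(seed)
    total = 0
    remaining = int(n_draws)
    while remaining > 0:
        m = min(remaining, 2_000_000)
        x = rng.standard_normal(m)
        y = rho * x + np.sqrt(1.0 - rho**2) * rng.standard_normal(m)
        total += int(np.count_nonzero((x > z) & (y > z)))
        remaining -= m
    return total / n_draws


@dataclass
class CalibrationResult:
    """Outcome of the full-data power calibration."""

    n_per_arm: int
    power: float
    degenerate: bool
    evaluations: list[tuple[int, float]]

    def __int__(self) -> int:
        return self.n_per_arm


def _full_data_power(template: SimScenario, n: int, reps: int, seed: int) -> float:
    scn = replace(
        template,
        n_per_arm=int(n),
        retention_grid=(1.0,),
        reps=reps,
        seed=_as_seed_int(seed, n),
    )
    grid = estimate_power_grid(scn)
    return grid.rejection_rate(scn.taumax, 1.0)


def calibrate_sample_size(
    template: SimScenario,
    target_full_data_power: float,
    tolerance: float = 0.02,
    seed: int = 0,
    eval_reps: int = 1000,
    n_bounds: tuple[int, int] = (100, 2_000_000),
) -> CalibrationResult:
    """Bisect ``n_per_arm`` until full-sample (100% retention) power hits target.

    Each evaluation runs ``eval_reps`` replicates with a seed derived
    deterministically from ``(seed, n)``, so the search is reproducible.
    With ``taumax = 0`` the rejection rate equals ``alpha`` for every n; a
    target at or below ``alpha`` is then degenerate and the lower bound is
    returned with ``degenerate=True``.  An unreachable target raises
    :class:`ConfigurationError` with the bracketing information.
    """
    if not 0.0 < target_full_data_power < 1.0:
        raise ConfigurationError("target power must lie in (0, 1)")
    if eval_reps < 100:
        raise ConfigurationError("eval_reps must be >= 100 for a usable signal")
    lo, hi = n_bounds
    evaluations: list[tuple[int, float]] = []

    if template.taumax == 0.0:
        power = _full_data_power(template, lo, eval_reps, seed)
        return CalibrationResult(lo, power, True, [(lo, power)])

    # analytic pre-estimate from the responder-and-enrolled overlap and the
    # two-sample normal power formula, used only to seed the bracket
    p_joint = _joint_overlap(template)
    delta = abs(template.taumax) * p_joint
    lam = stats.norm.ppf(1 - template.alpha / 2) + stats.norm.ppf(
        target_full_data_power
    )
    n0 = int(np.clip(2 * (lam / max(delta, 1e-12)) ** 2, lo, hi))

    def power_at(n: int) -> float:
        n = int(np.clip(n, lo, hi))
        p = _full_data_power(template, n, eval_reps, seed)
        evaluations.append((n, p))
        return p

    a, b = max(lo, n0 // 4), min(hi, max(n0 * 4, lo + 1))
    pa, pb = power_at(a), power_at(b)
    while pa > target_full_data_power and a > lo:
        a = max(lo, a // 2)
        pa = power_at(a)
    while pb < target_full_data_power and b < hi:
        b = min(hi, b * 2)
        pb = power_at(b)
    if pa > target_full_data_power or pb < target_full_data_power:
        raise ConfigurationError(
            "target power unreachable within n bounds: "
            f"power({a})={pa:.3f}, power({b})={pb:.3f}, target="
            f"{target_full_data_power:.3f}"
        )
    best = min(evaluations, key=lambda e: abs(e[1] - target_full_data_power))
    for _ in range(40):
        if b - a <= 1:
            break
        mid = (a + b) // 2
        pm = power_at(mid)
        if abs(pm - target_full_data_power) < abs(best[1] - target_full_data_power):
            best = (mid, pm)
        if abs(pm - target_full_data_power) <= tolerance:
            return CalibrationResult(mid, pm, False, evaluations)
        if pm < target_full_data_power:
            a = mid
        else:
            b = mid
    return CalibrationResult(best[0], best[1], False, evaluations)


def _joint_overlap(scenario: SimScenario) -> float:
    """MC overlap P(responder and enrolled-eligible) under the scenario."""
    if scenario.responder_fraction == scenario.enroll_fraction:
        return joint_top_fraction_probability(
            scenario.rho_te_part,
            scenario.responder_fraction,
            n_draws=400_000,
            seed=_as_seed_int(scenario.seed, 0x0A11),
        )
    rng = np.random.default_rng(_as_seed_int(scenario.seed, 0x0A12))
    x = rng.standard_normal(400_000)
    y = scenario.rho_te_part * x + np.sqrt(
        1 - scenario.rho_te_part**2
    ) * rng.standard_normal(400_000)
    zr = stats.norm.ppf(1 - scenario.responder_fraction)
    ze = stats.norm.ppf(1 - scenario.enroll_fraction)
    return float(np.mean((x > zr) & (y > ze)))


def plot_power_grid(grid: PowerGrid, path=None):
    """Line chart of power vs retention, one line per taumax value.

    Retention decreases left to right (concentration increases), mirroring
    the usual presentation.  Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    t = grid.table
    for taumax, sub in sorted(t.groupby("taumax"), reverse=True):
        sub = sub.sort_values("retention_fraction", ascending=False)
        x = 100 * sub["retention_fraction"]
        ax.errorbar(
            x,
            sub["rejection_rate"],
            yerr=sub["mc_se"],
            marker="o",
            label=f"taumax = {taumax:g}",
        )
    ax.invert_xaxis()
    ax.set_xlabel("retention (% of randomized sample)")
    ax.set_ylabel("rejection rate")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title("Power / type-I error vs distillation")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
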