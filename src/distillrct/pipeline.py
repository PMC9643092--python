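"""End-to-end orchestration of the two workflows.

``run_analysis`` executes the three-stage distillation analysis on a trial
table (stage one: uptake model; stage two: nested trimming; stage three:
difference-in-differences grid) and writes every artifact to the output
directory with deterministic names.  ``run_simulation`` runs the power /
type-I-error Monte-Carlo study from a scenario configuration.  Both echo
their effective configuration so any run is reproducible from its output
directory plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .distill import DEFAULT_RETENTION_GRID, nested_distillation
from .errors import ConfigurationError, ParseError
from .outcome_models import DEFAULT_OUTCOME_FAMILIES, FOLLOW_UPS, run_outcome_grid
from .participation import (
    StageOneSettings,
    fit_participation_model,
    score_subjects,
    write_score_table,
)
from .power_sim import (
    DEFAULT_TAUMAX_GRID,
    PowerGrid,
    SimScenario,
    estimate_power_grid,
    plot_power_grid,
    scenario_grid,
)
from .trial_data import CovariateSpec, read_trial_table, validate_trial

logger = logging.getLogger(__name__)


def _attach_run_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logging.getLogger("distillrct").addHandler(handler)
    return handler


def _detach_run_log(handler: logging.Handler) -> None:
    logging.getLogger("distillrct").removeHandler(handler)
    handler.close()


@dataclass
class AnalysisConfig:
    """Configuration of a distillation analysis run (YAML-serializable)."""

    input_path: str = ""
    outdir: str = "distill_run"
    seed: int = 0
    retention_fractions: tuple[float, ...] = DEFAULT_RETENTION_GRID
    outcomes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_FAMILIES)
    )
    periods: tuple[str, ...] = FOLLOW_UPS
    zero_cost_floor: float = 1.0
    covariate_schema: list[tuple[str, str]] | None = None  # None: infer
    stage_one: StageOneSettings = field(default_factory=StageOneSettings)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown analysis-config key(s): {', '.join(sorted(unknown))}"
            )
        kwargs = dict(raw)
        if "stage_one" in kwargs and isinstance(kwargs["stage_one"], dict):
            kwargs["stage_one"] = StageOneSettings(**kwargs["stage_one"])
        if "retention_fractions" in kwargs:
            kwargs["retention_fractions"] = tuple(kwargs["retention_fractions"])
        if "periods" in kwargs:
            kwargs["periods"] = tuple(kwargs["periods"])
        if kwargs.get("covariate_schema") is not None:
            kwargs["covariate_schema"] = [
                (str(n), str(k)) for n, k in kwargs["covariate_schema"]
            ]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["retention_fractions"] = list(self.retention_fractions)
        d["periods"] = list(self.periods)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the three stages end to end; returns paths and summary metrics.

    Artifacts written to ``config.outdir``: ``scores.csv`` (subject_id,
    score), ``ladder.csv`` (long-format retained sets), ``effects.csv``
    (one row per outcome x period x retention level), ``metrics.json``,
    ``run_config.yaml`` (the effective configuration) and ``run.log``.
    Per-cell non-convergence is recorded in ``effects.csv``, not raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _attach_run_log(outdir)
    try:
        config.to_yaml(outdir / "run_config.yaml")

        schema = (
            [CovariateSpec(n, k) for n, k in config.covariate_schema]
            if config.covariate_schema is not None
            else None
        )
        dataset = read_trial_table(config.input_path, schema=schema)
        violations = validate_trial(dataset)
        if violations:
            head = "; ".join(violations[:5])
            raise ParseError(
                f"input failed validation ({len(violations)} violation(s)): {head}"
            )
        counts = dataset.arm_counts()
        logger.info(
            "stage 0 read: %d subjects (%d intervention / %d control), "
            "%d covariates",
            dataset.n_subjects,
            counts["intervention"],
            counts["control"],
            len(dataset.covariate_schema),
        )

        settings = dataclasses.replace(config.stage_one, seed=config.seed)
        fit = fit_participation_model(dataset, settings)
        scores = score_subjects(fit, dataset)
        write_score_table(scores, outdir / "scores.csv")
        logger.info(
            "stage 1 uptake model: %d trees, cv AUC %.3f (in-sample %.3f); "
            "scored %d subjects",
            fit.n_trees_selected,
            fit.auc,
            fit.auc_insample,
            len(scores),
        )

        ladder = nested_distillation(dataset, scores, config.retention_fractions)
        ladder.to_csv(outdir / "ladder.csv")
        logger.info(
            "stage 2 distillation: retained counts %s",
            [lv.n_retained for lv in ladder],
        )

        effects = run_outcome_grid(
            dataset,
            ladder,
            outcomes=list(config.outcomes.items()),
            periods=config.periods,
            zero_cost_floor=config.zero_cost_floor,
        )
        effects.to_csv(outdir / "effects.csv", index=False)
        logger.info(
            "stage 3 outcome grid: %d cells, %d converged",
            len(effects),
            int(effects["converged"].sum()),
        )

        metrics = {
            "n_subjects": dataset.n_subjects,
            "arm_counts": counts,
            "stage_one": {
                "n_trees_selected": fit.n_trees_selected,
                "auc_cv": fit.auc,
                "auc_insample": fit.auc_insample,
                "relative_influence": fit.relative_influence,
            },
            "retained_by_level": {
                f"{lv.retention_fraction:g}": lv.n_retained_by_arm for lv in ladder
            },
            "n_cells": int(len(effects)),
            "n_converged": int(effects["converged"].sum()),
            "version": __version__,
        }
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        return {
            "outdir": str(outdir),
            "scores": str(outdir / "scores.csv"),
            "ladder": str(outdir / "ladder.csv"),
            "effects": str(outdir / "effects.csv"),
            "metrics": metrics,
        }
    finally:
        _detach_run_log(handler)


@dataclass
class SimulationConfig:
    """Configuration of a power-simulation run (YAML-serializable)."""

    outdir: str = "power_run"
    taumax: tuple[float, ...] = DEFAULT_TAUMAX_GRID
    n_per_arm: int = 2000
    reps: int = 2000
    seed: int = 0
    alpha: float = 0.05
    responder_fraction: float = 0.40
    enroll_fraction: float = 0.40
    rho_te_part: float = 0.30
    rho_te_pred: float = 0.80
    rho_part_pred: float = 0.80
    retention_grid: tuple[float, ...] = DEFAULT_RETENTION_GRID
    latent_mode: str = "participation-triple"
    distill_by: str = "pred_latent"
    plot: bool = True

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown simulation-config key(s): {', '.join(sorted(unknown))}"
            )
        kwargs = dict(raw)
        for key in ("taumax", "retention_grid"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taumax"] = list(self.taumax)
        d["retention_grid"] = list(self.retention_grid)
        return d

    def template(self) -> SimScenario:
        return SimScenario(
            taumax=0.0,
            n_per_arm=self.n_per_arm,
            responder_fraction=self.responder_fraction,
            enroll_fraction=self.enroll_fraction,
            rho_te_part=self.rho_te_part,
            rho_te_pred=self.rho_te_pred,
            rho_part_pred=self.rho_part_pred,
            alpha=self.alpha,
            retention_grid=self.retention_grid,
            reps=self.reps,
            seed=self.seed,
            latent_mode=self.latent_mode,
            distill_by=self.distill_by,
        )


def load_simulation_preset(name: str) -> SimulationConfig:
    """Load a bundled scenario configuration (e.g. ``"figure3"``)."""
    ref = resources.files("distillrct") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigurationError(f"unknown simulation preset {name!r}")
    with resources.as_file(ref) as path:
        return SimulationConfig.from_yaml(path)


def run_simulation(config: SimulationConfig) -> PowerGrid:
    """Run the (taumax x retention) power study and write its artifacts.

    Writes ``power.csv``, a ``manifest.json`` with the seed, replicate count
    and library versions, the echoed ``sim_config.yaml`` and (optionally)
    ``power.png``.
    """
    if len(config.taumax) == 0:
        raise ConfigurationError("taumax grid must be nonempty")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _attach_run_log(outdir)
    try:
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        scenarios = scenario_grid(config.template(), config.taumax)
        grid = estimate_power_grid(scenarios)
        grid.to_csv(outdir / "power.csv")
        logger.info(
            "simulation: %d scenarios x %d retention levels, %d reps each",
            len(scenarios),
            len(config.retention_grid),
            config.reps,
        )
        import numpy, pandas, scipy  # versions for the manifest

        manifest = {
            "seed": config.seed,
            "reps": config.reps,
            "n_per_arm": config.n_per_arm,
            "versions": {
                "distillrct": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        if config.plot:
            plot_power_grid(grid, outdir / "power.png")
        return grid
    finally:
        _detach_run_log(handler)
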