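"""Stage two: trim both randomized arms to nested high-uptake subsets.

Given a score table (predicted probability of participation for every
randomized subject), a distillation level retains exactly
``round(f * N_total)`` subjects with the highest scores over the *pooled*
sample.  The threshold is a pooled quantile — never computed per arm — so
both arms are trimmed in an equivalent manner and randomization is preserved
within the retained subpopulation.  Levels built from the same score ordering
are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DistillationError
from .trial_data import ARMS, TrialDataset

#: Default ladder: full sample plus four increasingly concentrated subsets,
#: ending at a quarter of the randomized population.
DEFAULT_RETENTION_GRID: tuple[float, ...] = (1.00, 0.80, 0.60, 0.40, 0.25)


def round_half_away(x: float) -> int:
    """round() with half-away-from-zero ties, portable across platforms."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class DistillationLevel:
    """One retention level: the fraction, its score cut and retained subjects."""

    retention_fraction: float
    threshold: float
    retained_ids: frozenset[str]
    n_retained_by_arm: dict[str, int]

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


@dataclass
class DistillationLadder:
    """Distillation levels ordered by decreasing retention fraction (nested)."""

    levels: list[DistillationLevel]

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)

    def level(self, fraction: float) -> DistillationLevel:
        for lv in self.levels:
            if lv.retention_fraction == fraction:
                return lv
        raise KeyError(fraction)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (retention_fraction, subject_id)."""
        rows = []
        for lv in self.levels:
            for sid in sorted(lv.retained_ids):
                rows.append((lv.retention_fraction, lv.threshold, sid))
        return pd.DataFrame(
            rows, columns=["retention_fraction", "threshold", "subject_id"]
        )

    def to_csv(self, sink) -> None:
        self.to_frame().to_csv(sink, index=False)


def _ordered_ids(dataset: TrialDataset, scores: pd.Series) -> pd.DataFrame:
    """Subjects sorted by (score desc, subject_id asc); errors on gaps."""
    ids = dataset.subject_ids
    missing = ids[~ids.isin(scores.index)]
    if len(missing):
        raise DistillationError(f"no score for subject {missing.iloc[0]!r}")
    tbl = pd.DataFrame(
        {"subject_id": ids.to_numpy(), "arm": dataset.subjects["arm"].to_numpy()}
    )
    tbl["score"] = scores.loc[tbl["subject_id"]].to_numpy(float)
    if tbl["score"].isna().any():
        sid = tbl.loc[tbl["score"].isna(), "subject_id"].iloc[0]
        raise DistillationError(f"no score for subject {sid!r}")
    return tbl.sort_values(
        ["score", "subject_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _level_from_ordered(ordered: pd.DataFrame, fraction: float) -> DistillationLevel:
    n = len(ordered)
    k = round_half_away(fraction * n)  # exact, even when ties straddle the cut
    kept = ordered.iloc[:k]
    by_arm = kept["arm"].value_counts()
    return DistillationLevel(
        retention_fraction=fraction,
        threshold=float(kept["score"].iloc[-1]) if k else float("nan"),
        retained_ids=frozenset(kept["subject_id"]),
        n_retained_by_arm={arm: int(by_arm.get(arm, 0)) for arm in ARMS},
    )


def distill_subset(
    dataset: TrialDataset, scores: pd.Series, retention_fraction: float
) -> DistillationLevel:
    """Retain the top ``round(f * N)`` subjects of the pooled sample by score.

    Ties are broken deterministically by (score descending, subject_id
    ascending), so the retained count is exact for any tie structure.  The
    recorded ``threshold`` is the lowest retained score.
    """
    if not 0.0 < retention_fraction <= 1.0:
        raise DistillationError(
            f"retention_fraction must lie in (0, 1], got {retention_fraction!r}"
        )
    return _level_from_ordered(_ordered_ids(dataset, scores), retention_fraction)


def nested_distillation(
    dataset: TrialDataset,
    scores: pd.Series,
    fractions: tuple[float, ...] = DEFAULT_RETENTION_GRID,
) -> DistillationLadder:
    """Build a ladder of nested levels from one shared score ordering.

    Fractions must be distinct, each in (0, 1]; the ladder is sorted by
    decreasing retention, and every smaller level is a subset of every
    larger one by construction.
    """
    fracs = list(fractions)
    if len(set(fracs)) != len(fracs):
        raise DistillationError("retention fractions must be distinct")
    for f in fracs:
        if not 0.0 < f <= 1.0:
            raise DistillationError(
                f"retention_fraction must lie in (0, 1], got {f!r}"
            )
    ordered = _ordered_ids(dataset, scores)
    levels = [
        _level_from_ordered(ordered, f) for f in sorted(fracs, reverse=True)
    ]
    return DistillationLadder(levels)
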