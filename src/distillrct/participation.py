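"""Stage one: predict intervention uptake from baseline covariates.

A gradient-boosted classification-tree model is trained on the randomized
intervention arm only, with enrollment (ever/never) as the outcome, and then
scores *every* randomized subject — both arms — with a predicted probability
of participation.  The boosting configuration mirrors common practice for
uptake/propensity modelling: shallow trees (interaction depth 2), a small
learning rate (0.001), a large tree budget (10,000) and the tree count chosen
by k-fold cross-validated deviance.

:class:`ParticipationClassifier` is a scikit-learn estimator (usable in
sklearn pipelines / model selection); :func:`fit_participation_model` and
:func:`score_subjects` are the trial-level wrappers that handle covariate
encoding, missing data and unseen categorical levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ConfigurationError, FitError
from .trial_data import TrialDataset

MISSING_LEVEL = "(missing)"


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney formulation.

    The probability that a uniformly random positive case outscores a
    uniformly random negative case, with ties counting 1/2.  Equals the
    trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ConfigurationError("scores and labels must be 1-d of equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise FitError("AUC undefined: one outcome class is absent")
    ranks = rankdata(s)  # average ranks -> ties count 1/2
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


class ParticipationClassifier(ClassifierMixin, BaseEstimator):
    """Gradient-boosted classifier with cross-validated tree-count selection.

    Parameters
    ----------
    folds : int, default=10
        Cross-validation folds for selecting the number of trees.
    max_trees : int, default=10000
        Tree budget; the selected count never exceeds it.
    interaction_depth : int, default=2
        Maximum depth of each tree.
    min_leaf : int, default=8
        Minimum samples per terminal leaf.
    learning_rate : float, default=0.001
        Boosting shrinkage.
    random_state : int or None
        Seeds both the fold split and the tree fits.

    Attributes
    ----------
    n_trees_ : int
        Tree count minimizing the pooled out-of-fold binomial deviance.
    cv_deviance_ : ndarray of shape (max_trees,)
        Out-of-fold deviance per stage.
    auc_cv_ : float
        AUC of the pooled out-of-fold predictions at ``n_trees_``.
    auc_insample_ : float
        AUC of the refit model on its own training data.
    estimator_ : GradientBoostingClassifier
        Final model refit on all data with ``n_trees_`` trees.
    feature_importances_ : ndarray
        Impurity importances of the final model (sum to 1).
    """

    def __init__(
        self,
        folds: int = 10,
        max_trees: int = 10_000,
        interaction_depth: int = 2,
        min_leaf: int = 8,
        learning_rate: float = 0.001,
        random_state: int | None = None,
    ):
        self.folds = folds
        self.max_trees = max_trees
        self.interaction_depth = interaction_depth
        self.min_leaf = min_leaf
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _base(self, n_estimators: int, seed) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=self.interaction_depth,
            min_samples_leaf=self.min_leaf,
            learning_rate=self.learning_rate,
            random_state=seed,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes, y01 = np.unique(y, return_inverse=True)
        if classes.shape[0] != 2:
            raise FitError("no outcome variation: need exactly two classes")
        self.classes_ = classes
        n_min = int(np.bincount(y01).min())
        folds = min(self.folds, n_min)
        if folds < 2:
            raise FitError("no outcome variation: a class has < 2 members")

        rng = np.random.default_rng(self.random_state)
        split_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)
        oof_dec = []  # per fold: (n_stages, n_val)
        oof_y = []
        oof_idx = []
        for k, (tr, va) in enumerate(skf.split(X, y01)):
            est = self._base(self.max_trees, int(rng.integers(0, 2**31 - 1)))
            est.fit(X[tr], y01[tr])
            dec = np.vstack(
                [np.ravel(s) for s in est.staged_decision_function(X[va])]
            )
            oof_dec.append(dec)
            oof_y.append(y01[va])
            oof_idx.append(va)
        dec_all = np.hstack(oof_dec)  # (n_stages, n)
        y_all = np.concatenate(oof_y)
        idx_all = np.concatenate(oof_idx)
        # binomial deviance per stage, pooled over held-out folds
        loglik = y_all[None, :] * dec_all - np.logaddexp(0.0, dec_all)
        self.cv_deviance_ = -2.0 * loglik.mean(axis=1)
        self.n_trees_ = int(np.argmin(self.cv_deviance_)) + 1
        self.auc_cv_ = compute_auc(expit(dec_all[self.n_trees_ - 1]), y_all)
        self.oof_proba_ = np.empty(len(y_all))
        self.oof_proba_[idx_all] = expit(dec_all[self.n_trees_ - 1])

        self.estimator_ = self._base(
            self.n_trees_, int(rng.integers(0, 2**31 - 1))
        ).fit(X, y01)
        self.auc_insample_ = compute_auc(
            self.estimator_.predict_proba(X)[:, 1], y01
        )
        self.feature_importances_ = self.estimator_.feature_importances_
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Covariate encoding (missing-safe, unseen-level-safe)
# ---------------------------------------------------------------------------

class CovariateEncoder:
    """Encode schema covariates into a numeric design matrix.

    Real covariates pass through with training-median imputation plus a
    missing indicator; categorical covariates are one-hot encoded over the
    training levels plus an always-present ``(missing)`` level, to which both
    missing values and levels unseen at training time are mapped (scoring a
    new dataset therefore never fails on an unseen level).
    """

    def fit(self, dataset: TrialDataset) -> "CovariateEncoder":
        self.schema_ = list(dataset.covariate_schema)
        if not self.schema_:
            raise FitError("covariate schema is empty")
        cov = dataset.covariate_frame()
        self.medians_: dict[str, float] = {}
        self.levels_: dict[str, list[str]] = {}
        for spec in self.schema_:
            if spec.kind == "real":
                med = pd.to_numeric(cov[spec.name], errors="coerce").median()
                self.medians_[spec.name] = float(med) if pd.notna(med) else 0.0
            else:
                col = cov[spec.name].astype("object")
                levels = sorted(str(v) for v in col.dropna().unique())
                self.levels_[spec.name] = levels + [MISSING_LEVEL]
        self.feature_names_: list[str] = []
        self.feature_owner_: list[str] = []
        for spec in self.schema_:
            if spec.kind == "real":
                for suffix in ("", "__is_missing"):
                    self.feature_names_.append(spec.name + suffix)
                    self.feature_owner_.append(spec.name)
            else:
                for lv in self.levels_[spec.name]:
                    self.feature_names_.append(f"{spec.name}={lv}")
                    self.feature_owner_.append(spec.name)
        return self

    def transform(self, dataset: TrialDataset) -> np.ndarray:
        names = [(s.name, s.kind) for s in dataset.covariate_schema]
        if names != [(s.name, s.kind) for s in self.schema_]:
            raise FitError("covariate schema does not match the fitted schema")
        cov = dataset.covariate_frame()
        cols = []
        for spec in self.schema_:
            if spec.kind == "real":
                v = pd.to_numeric(cov[spec.name], errors="coerce").to_numpy(float)
                miss = np.isnan(v)
                filled = np.where(miss, self.medians_[spec.name], v)
                cols.append(filled)
                cols.append(miss.astype(float))
            else:
                col = cov[spec.name].astype("object")
                known = set(self.levels_[spec.name])
                as_str = np.array(
                    [
                        MISSING_LEVEL
                        if pd.isna(v) or str(v) not in known
                        else str(v)
                        for v in col
                    ]
                )
                for lv in self.levels_[spec.name]:
                    cols.append((as_str == lv).astype(float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Trial-level wrappers
# ---------------------------------------------------------------------------

@dataclass
class StageOneSettings:
    """Hyperparameters of the uptake model (passed through to the booster)."""

    folds: int = 10
    max_trees: int = 10_000
    interaction_depth: int = 2
    min_leaf: int = 8
    learning_rate: float = 0.001
    seed: int = 0
    oof_scores: bool = False  # out-of-fold scores for intervention arm


@dataclass
class ParticipationFit:
    """Fitted stage-one uptake model plus its summary metrics.

    ``auc`` is the cross-validated (out-of-fold) AUC — the headline metric;
    the in-sample AUC of the refit model is reported separately as
    ``auc_insample`` and is optimistic by construction.
    ``relative_influence`` maps each covariate to a nonnegative importance;
    the values sum to 100.
    """

    model: ParticipationClassifier
    encoder: CovariateEncoder
    cv_folds: int
    n_trees_selected: int
    auc: float
    auc_insample: float
    relative_influence: dict[str, float]
    settings: StageOneSettings = field(default_factory=StageOneSettings)
    #: out-of-fold scores for the training (intervention-arm) subjects
    oof_scores: pd.Series | None = None


def fit_participation_model(
    dataset: TrialDataset, settings: StageOneSettings | None = None
) -> ParticipationFit:
    """Fit the stage-one uptake model on the intervention arm.

    Raises :class:`FitError` when the intervention arm lacks enrollment
    variation (all enrolled or none) or when the covariate schema is empty.
    """
    settings = settings or StageOneSettings()
    interv = dataset.subset(
        dataset.subjects.loc[dataset.arm_mask("intervention"), "subject_id"]
    )
    y = (interv.subjects["enrolled"] == "yes").to_numpy().astype(int)
    if y.min() == y.max():
        raise FitError("no outcome variation in intervention-arm enrollment")
    encoder = CovariateEncoder().fit(interv)
    X = encoder.transform(interv)
    clf = ParticipationClassifier(
        folds=settings.folds,
        max_trees=settings.max_trees,
        interaction_depth=settings.interaction_depth,
        min_leaf=settings.min_leaf,
        learning_rate=settings.learning_rate,
        random_state=settings.seed,
    ).fit(X, y)

    # per-covariate relative influence: impurity importances summed over the
    # encoded columns belonging to each covariate, rescaled to sum to 100
    owner = np.array(clf.feature_importances_)
    per_cov: dict[str, float] = {s.name: 0.0 for s in encoder.schema_}
    for imp, name in zip(owner, encoder.feature_owner_):
        per_cov[name] += float(imp)
    total = sum(per_cov.values())
    if total <= 0:  # constant model: spread uniformly
        per_cov = {k: 100.0 / len(per_cov) for k in per_cov}
    else:
        per_cov = {k: 100.0 * v / total for k, v in per_cov.items()}

    oof = pd.Series(
        clf.oof_proba_,
        index=pd.Index(interv.subject_ids, name="subject_id"),
        name="score",
    )
    return ParticipationFit(
        model=clf,
        encoder=encoder,
        cv_folds=settings.folds,
        n_trees_selected=clf.n_trees_,
        auc=clf.auc_cv_,
        auc_insample=clf.auc_insample_,
        relative_influence=per_cov,
        settings=settings,
        oof_scores=oof,
    )


def score_subjects(fit: ParticipationFit, dataset: TrialDataset) -> pd.Series:
    """Score every subject (both arms) with the fitted uptake model.

    Returns a score table: a Series of predicted enrollment probabilities in
    [0, 1], indexed by ``subject_id`` and named ``score``.  Deterministic
    given the fit.  With ``settings.oof_scores`` enabled, intervention-arm
    subjects of the *training* dataset instead receive their out-of-fold
    cross-validation scores (a guard against in-sample optimism); this is
    not available for new data and falls back to refit-model scores there.
    """
    X = fit.encoder.transform(dataset)
    p = fit.model.predict_proba(X)[:, 1]
    scores = pd.Series(
        p, index=pd.Index(dataset.subject_ids, name="subject_id"), name="score"
    )
    if fit.settings.oof_scores and fit.oof_scores is not None:
        overlap = scores.index.intersection(fit.oof_scores.index)
        scores.loc[overlap] = fit.oof_scores.loc[overlap]
    return scores


def relative_influence(
    fit: ParticipationFit, top_k: int | None = None
) -> list[tuple[str, float]]:
    """Top-``top_k`` covariates by relative influence (descending).

    Influences are rescaled to sum to 100 over *all* covariates, so a
    truncated list sums to less than 100.
    """
    if top_k is not None and top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    ranked = sorted(fit.relative_influence.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if top_k is None else ranked[:top_k]


def write_score_table(scores: pd.Series, sink) -> None:
    """Serialize a score table to a two-column CSV (subject_id, score)."""
    scores.rename("score").to_csv(sink, index_label="subject_id")


def read_score_table(source) -> pd.Series:
    df = pd.read_csv(source, dtype={"subject_id": str})
    return df.set_index("subject_id")["score"]
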