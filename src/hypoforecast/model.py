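"""Risk-score modelling: classifier families, subject-level tenfold CV,
calibration-based selection, and per-minute scoring.

Four classifier families are supported — random forest, K-nearest
neighbours, gradient-boosted trees and L2-regularized logistic regression
(the distance/margin families are wrapped in a standardizing pipeline).
Cross-validation folds partition SUBJECTS, never rows, so windows from one
stay can never appear on both sides of a fold; folds are stratified on
subject group membership. Among families with statistically equivalent
discrimination (AUROC within a tolerance of the best), the best-calibrated
one (lowest Brier score) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .evaluation import auprc, auroc, brier

FAMILIES = ("random-forest", "k-nearest-neighbor", "gradient-boosted-trees", "logistic-L2")


@dataclass
class ModelSpec:
    family: str = "random-forest"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator for a model spec.

    Defaults: 500 trees for the forest families, k=11 neighbours, L2
    strength C=1.0; all overridable through ``spec.params``.
    """
    p = dict(spec.params)
    if spec.family == "random-forest":
        p.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **p)
    if spec.family == "gradient-boosted-trees":
        p.setdefault("n_estimators", 500)
        return GradientBoostingClassifier(random_state=spec.seed, **p)
    if spec.family == "k-nearest-neighbor":
        p.setdefault("n_neighbors", 11)
        return Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsClassifier(**p))]
        )
    p.setdefault("C", 1.0)
    p.setdefault("max_iter", 2000)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(random_state=spec.seed, **p)),  # L2 is the default penalty
        ]
    )


@dataclass
class CVResult:
    spec: ModelSpec
    fold_metrics: pd.DataFrame  # fold, auroc, auprc, brier, n_val_rows
    fold_of_subject: dict[str, int]
    fold_models: list
    final_model: object
    feature_names: list[str]

    @property
    def mean_auroc(self) -> float:
        return float(self.fold_metrics["auroc"].mean())

    @property
    def mean_auprc(self) -> float:
        return float(self.fold_metrics["auprc"].mean())

    @property
    def mean_brier(self) -> float:
        return float(self.fold_metrics["brier"].mean())


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
) -> CVResult:
    """Subject-partitioned stratified k-fold CV plus a final refit.

    ``subjects`` gives the owning subject of each row; a subject's class
    for stratification is 1 when it contributes any positive row. Requires
    at least k positive and k negative subjects so every fold can hold both
    classes.
    """
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects, dtype=object)
    subj_class = pd.Series(y).groupby(pd.Series(subjects)).max()
    n_pos_subj = int((subj_class == 1).sum())
    n_neg_subj = int((subj_class == 0).sum())
    if n_pos_subj < k or n_neg_subj < k:
        raise ValueError(
            f"need >= {k} positive and negative subjects (have {n_pos_subj}/{n_neg_subj})"
        )
    row_strata = subj_class.loc[subjects].to_numpy()
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    fold_of_subject: dict[str, int] = {}
    fold_models = []
    rows = []
    Xv = X.to_numpy(dtype=float)
    for fold, (tr, va) in enumerate(splitter.split(Xv, row_strata, groups=subjects)):
        if len(set(y[tr])) < 2 or len(set(y[va])) < 2:
            raise ValueError(f"fold {fold} lost a class; provide more subjects per class")
        est = make_estimator(spec)
        est.fit(Xv[tr], y[tr])
        s = est.predict_proba(Xv[va])[:, 1]
        rows.append((fold, auroc(s, y[va]), auprc(s, y[va]), brier(s, y[va]), len(va)))
        for subj in set(subjects[va]):
            fold_of_subject[str(subj)] = fold
        fold_models.append(est)
    final = make_estimator(spec)
    final.fit(Xv, y)
    return CVResult(
        spec=spec,
        fold_metrics=pd.DataFrame(
            rows, columns=["fold", "auroc", "auprc", "brier", "n_val_rows"]
        ),
        fold_of_subject=fold_of_subject,
        fold_models=fold_models,
        final_model=final,
        feature_names=list(X.columns),
    )


def select_model(results: dict[str, CVResult], auroc_tolerance: float = 0.02) -> str:
    """Pick the best-calibrated family among those with near-best AUROC.

    Families whose mean CV AUROC is within ``auroc_tolerance`` of the best
    are considered equivalent discriminators; the one with the lowest mean
    Brier score wins (ties broken by family order in the input).
    """
    if not results:
        raise ValueError("no CV results to select from")
    best_auroc = max(r.mean_auroc for r in results.values())
    candidates = [f for f, r in results.items() if r.mean_auroc >= best_auroc - auroc_tolerance]
    return min(candidates, key=lambda f: (results[f].mean_brier, list(results).index(f)))


def score_minutes(model, features: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    """Per-minute risk scores for a feature matrix.

    Returns a DataFrame (stay_id, minute, score) with scores in [0, 1]; an
    empty matrix yields an empty result. The matrix must carry exactly the
    training-time feature columns.
    """
    missing = [c for c in feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix is missing training columns: {missing[:5]}...")
    if len(features) == 0:
        return pd.DataFrame(columns=["stay_id", "minute", "score"])
    scores = model.predict_proba(features[feature_names].to_numpy(dtype=float))[:, 1]
    return pd.DataFrame(
        {
            "stay_id": features["stay_id"].to_numpy(),
            "minute": features["end_minute"].to_numpy(),
            "score": scores,
        }
    )


def oof_score_minutes(cv: CVResult, features: pd.DataFrame, subjects: np.ndarray) -> pd.DataFrame:
    """Out-of-fold scores for training stays: each row is scored by the fold
    model that held its subject out, avoiding in-sample optimism."""
    subjects = np.asarray(subjects, dtype=object)
    parts = []
    for fold, est in enumerate(cv.fold_models):
        sel = np.array([cv.fold_of_subject.get(str(s)) == fold for s in subjects])
        if not sel.any():
            continue
        parts.append(score_minutes(est, features.loc[sel], cv.feature_names))
    if not parts:
        return pd.DataFrame(columns=["stay_id", "minute", "score"])
    return (
        pd.concat(parts, ignore_index=True)
        .sort_values(["stay_id", "minute"], kind="stable")
        .reset_index(drop=True)
    )
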