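"""Classifier families behind one fit/predict/importance interface.

Three families are supported — L2-regularized logistic regression, random
forest, and gradient boosting — each as a scikit-learn pipeline whose
preprocessing is fitted on training folds only. No class reweighting or
resampling is applied anywhere: the natural outcome prevalence is preserved
because the decision-curve stage depends on calibrated absolute risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .cohort import feature_columns
from .errors import SchemaMismatchError, UndefinedMetricError

__all__ = ["FAMILIES", "FittedModel", "default_grids", "fit", "predict", "importance"]

FAMILIES = ("l2_logistic", "random_forest", "gradient_boosting")

LABEL = "label_exit_next_day"


def default_grids() -> dict[str, list[dict]]:
    """Small, documented hyperparameter grids per family.

    Kept deliberately compact: one axis per family that materially moves
    validation AUC at patient-day scale (regularization strength for the
    linear model, tree depth for the ensembles).
    """
    return {
        "l2_logistic": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
        "random_forest": [
            {"max_depth": 8, "n_estimators": 200},
            {"max_depth": None, "n_estimators": 200},
        ],
        "gradient_boosting": [
            {"max_depth": 2, "n_estimators": 200},
            {"max_depth": 4, "n_estimators": 200},
        ],
    }


def _make_estimator(family: str, params: dict, seed: int) -> Pipeline:
    if family == "l2_logistic":
        # LogisticRegression's default penalty is the L2 norm; C sets its strength
        clf = LogisticRegression(solver="lbfgs", max_iter=2000, random_state=seed, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if family == "random_forest":
        clf = RandomForestClassifier(
            min_samples_leaf=5, n_jobs=1, random_state=seed, **params
        )
        return Pipeline([("clf", clf)])
    if family == "gradient_boosting":
        clf = XGBClassifier(
            learning_rate=0.1,
            subsample=0.9,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            **params,
        )
        return Pipeline([("clf", clf)])
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class FittedModel:
    """A tuned, refitted classifier with its training provenance."""

    family: str
    estimator: Pipeline
    feature_names: list[str]
    best_params: dict
    cv_scores: dict = field(default_factory=dict)  # params-repr -> mean CV ROC AUC
    seed: int = 0


def _xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    X = table[feature_columns(table)]
    y = table[LABEL].to_numpy()
    return X, y


def fit(
    family: str,
    train_table: pd.DataFrame,
    folds: list[tuple[np.ndarray, np.ndarray]],
    grid: list[dict] | None = None,
    seed: int = 0,
) -> FittedModel:
    """Tune by mean cross-validated ROC AUC, then refit on all of train.

    ``folds`` are row-positional (train_idx, val_idx) pairs, normally the
    admission-grouped stratified folds from
    :func:`icudca.daybuild.cv_fold_indices`. The matrix must already be
    imputed. Ties in CV score go to the earlier grid entry; everything is
    deterministic given ``seed``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    X, y = _xy(train_table)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("training labels are single-class")
    if grid is None:
        grid = default_grids()[family]

    cv_scores: dict[str, float] = {}
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for tr, val in folds:
            est = _make_estimator(family, params, seed)
            est.fit(X.iloc[tr], y[tr])
            scores.append(roc_auc_score(y[val], est.predict_proba(X.iloc[val])[:, 1]))
        mean = float(np.mean(scores))
        cv_scores[repr(params)] = mean
        if mean > best_score + 1e-12:
            best_score, best_params = mean, params

    est = _make_estimator(family, best_params, seed)
    est.fit(X, y)
    return FittedModel(
        family=family,
        estimator=est,
        feature_names=list(X.columns),
        best_params=best_params,
        cv_scores=cv_scores,
        seed=seed,
    )


def predict(model: FittedModel, table: pd.DataFrame, partition: str = "") -> pd.DataFrame:
    """Score a patient-day matrix, returning one prediction row per day.

    Columns: ``admission_id``, ``day_index``, ``p`` (predicted probability of
    next-day exit), ``y`` (true label), ``family``, ``partition``.
    """
    feats = feature_columns(table)
    if set(feats) != set(model.feature_names):
        missing = set(model.feature_names) - set(feats)
        extra = set(feats) - set(model.feature_names)
        raise SchemaMismatchError(f"feature mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
    p = model.estimator.predict_proba(table[model.feature_names])[:, 1]
    return pd.DataFrame(
        {
            "admission_id": table["admission_id"].to_numpy(),
            "day_index": table["day_index"].to_numpy(),
            "p": p,
            "y": table[LABEL].to_numpy(),
            "family": model.family,
            "partition": partition,
        }
    )


def importance(model: FittedModel) -> pd.DataFrame:
    """Family-appropriate global feature importance, descending.

    Linear model: absolute coefficient on standardized features. Random
    forest: impurity reduction. Gradient boosting: split gain (features never
    used in a split score 0). All weights are non-negative.
    """
    names = model.feature_names
    clf = model.estimator.named_steps["clf"]
    if model.family == "l2_logistic":
        w = np.abs(clf.coef_[0])
    elif model.family == "random_forest":
        w = clf.feature_importances_
    else:
        booster = clf.get_booster()
        gain = booster.get_score(importance_type="gain")
        w = np.array([gain.get(f, 0.0) for f in booster.feature_names])
    out = pd.DataFrame({"feature": names, "weight": w})
    return out.sort_values("weight", ascending=False, kind="mergesort").reset_index(drop=True)
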