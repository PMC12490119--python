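"""ASD prediction from birth-available features.

Feature selection uses recursive feature elimination with random-forest
importances under cross-validation, followed by correlation pruning (of a
pair correlated above 0.7, the configured more-general feature is kept).
Model evaluation is nested cross-validation: an outer stratified k-fold
whose held-out folds are never touched by tuning, and an inner repeated
k-fold grid search choosing hyperparameters by AUROC. Metrics are pooled
over the out-of-fold predictions; per-feature attributions come from
TreeSHAP for gradient-boosted models (permutation importance as the
fallback for non-tree models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    StratifiedKFold,
)
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

GA_TERM_IMPUTE = 40  # weeks, for term births without a recorded gestational age

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "xgboost": [
        {"n_estimators": [50, 100], "max_depth": [2, 4], "learning_rate": [0.1, 0.3]},
    ],
    "random_forest": [
        {"n_estimators": [100, 300], "max_features": ["sqrt", None]},
    ],
    "linear_svm": [
        {"model__C": [0.01, 0.1, 1.0]},
    ],
}


@dataclass
class NestedCVResult:
    algorithm: str
    features: list[str]
    fold_params: list[dict]
    fold_test_index: list[np.ndarray]
    oof_pred: np.ndarray
    oof_score: np.ndarray
    labels: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    fold_models: list[object] = field(default_factory=list)


def assemble_features(
    cohort: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "asd",
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the birth-available feature table.

    Encodes sex as is_male, imputes a gestational age of 40 weeks for term
    births missing it, and requires a complete, binary-labelled table.
    """
    df = cohort.copy()
    if "sex" in df.columns and "is_male" not in df.columns:
        df["is_male"] = (df["sex"] == "male").astype(int)
    if "gestational_age_weeks" in df.columns:
        missing_ga = df["gestational_age_weeks"].isna()
        term_missing = missing_ga & ~df.get("preterm", False).astype(bool)
        df.loc[term_missing, "gestational_age_weeks"] = GA_TERM_IMPUTE
    cols = [c if c != "sex" else "is_male" for c in feature_cols]
    X = df[cols].astype(float)
    incomplete = X.isna().any(axis=1)
    if incomplete.any():
        # preterm births without a recorded gestational age cannot supply it
        logger.warning("dropping %d rows with un-imputable missing features", int(incomplete.sum()))
        X = X[~incomplete]
        df = df[~incomplete]
    y = df[label_col].astype(int)
    if set(y.unique()) - {0, 1}:
        raise ValueError("label must be binary")
    return X, y


def select_features(
    X: pd.DataFrame,
    y: pd.Series,
    n_folds: int = 10,
    generality_order: list[str] | None = None,
    corr_threshold: float = 0.7,
    seed: int = 0,
) -> list[str]:
    """RFE with random-forest importance and CV, then correlation pruning.

    Constant features are dropped with a warning before RFE. The
    cross-validated elimination picks the best-performing subset size by
    AUROC. For any remaining pair with |Pearson r| strictly above the
    threshold, the more general member is kept: the one appearing earlier
    in ``generality_order`` (earlier = more general, e.g. all LOF before
    LOF restricted to NDD genes); pairs absent from the ordering keep the
    earlier column.
    """
    constant = X.columns[X.nunique() <= 1].tolist()
    if constant:
        logger.warning("dropping constant features before RFE: %s", constant)
        X = X.drop(columns=constant)
    if X.shape[1] < 2:
        return list(X.columns)
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    cv = StratifiedKFold(n_splits=min(n_folds, int(y.value_counts().min())), shuffle=True, random_state=seed)
    selector = RFECV(rf, step=1, cv=cv, scoring="roc_auc", min_features_to_select=1)
    selector.fit(X.to_numpy(), y.to_numpy())
    selected = list(X.columns[selector.support_])
    return prune_correlated(X, selected, generality_order, corr_threshold)


def prune_correlated(
    X: pd.DataFrame,
    selected: list[str],
    generality_order: list[str] | None = None,
    corr_threshold: float = 0.7,
) -> list[str]:
    """Resolve feature pairs with |Pearson r| strictly above the threshold,
    keeping the more general member (earlier in ``generality_order``).

    The comparison is strict, so a pair at exactly the threshold is kept;
    correlations are rounded to 12 decimals first so floating-point noise
    cannot push a boundary pair over.
    """
    rank = {name: i for i, name in enumerate(generality_order or [])}
    corr = X[selected].corr().abs().round(12)
    dropped: set[str] = set()
    for i, f1 in enumerate(selected):
        for f2 in selected[i + 1:]:
            if f1 in dropped or f2 in dropped:
                continue
            if corr.loc[f1, f2] > corr_threshold:
                r1 = rank.get(f1, selected.index(f1) + len(rank))
                r2 = rank.get(f2, selected.index(f2) + len(rank))
                dropped.add(f2 if r1 <= r2 else f1)
    return [f for f in selected if f not in dropped]


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "xgboost":
        return xgb.XGBClassifier(
            random_state=seed, verbosity=0, eval_metric="logloss", n_jobs=1
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "linear_svm":
        return Pipeline(
            [("scale", StandardScaler()), ("model", LinearSVC(random_state=seed, dual="auto"))]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def nested_cv(
    X: pd.DataFrame,
    y: pd.Series,
    algorithm: str = "xgboost",
    grid: list[dict] | None = None,
    seed: int = 0,
    outer_folds: int = 10,
    inner_folds: int = 10,
    inner_repeats: int = 10,
    scoring: str = "roc_auc",
) -> NestedCVResult:
    """Nested cross-validation with inner grid search.

    The outer stratified k-fold partitions the data; within each outer
    training set, a repeated stratified k-fold grid search selects the
    hyperparameters, the winning configuration is refit on the full outer
    training fold, and predictions are collected on the held-out fold.
    Metrics are computed on the pooled out-of-fold predictions, with the
    accuracy CI by the exact (Clopper-Pearson) binomial method.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    Xa, ya = X.to_numpy(dtype=float), y.to_numpy(dtype=int)
    min_class = int(np.bincount(ya).min())
    if min_class < outer_folds:
        raise ValueError("too few samples in the minority class for stratified outer folds")
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    inner = RepeatedStratifiedKFold(n_splits=inner_folds, n_repeats=inner_repeats, random_state=seed)

    oof_pred = np.empty_like(ya)
    oof_score = np.empty(len(ya), dtype=float)
    fold_params, fold_test_index, fold_models = [], [], []
    for train_idx, test_idx in outer.split(Xa, ya):
        search = GridSearchCV(
            _make_estimator(algorithm, seed), grid, scoring=scoring, cv=inner, n_jobs=1, refit=True
        )
        search.fit(Xa[train_idx], ya[train_idx])
        best = search.best_estimator_
        oof_pred[test_idx] = best.predict(Xa[test_idx])
        oof_score[test_idx] = _decision_scores(best, Xa[test_idx])
        fold_params.append(dict(search.best_params_))
        fold_test_index.append(test_idx)
        fold_models.append(best)

    metrics = evaluate_confusion(ya, oof_pred, oof_score)
    return NestedCVResult(
        algorithm=algorithm,
        features=list(X.columns),
        fold_params=fold_params,
        fold_test_index=fold_test_index,
        oof_pred=oof_pred,
        oof_score=oof_score,
        labels=ya,
        metrics=metrics,
        fold_models=fold_models,
    )


def evaluate_confusion(
    labels: np.ndarray, predictions: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """Accuracy (with exact binomial CI), sensitivity, specificity, F1, AUROC.

    Sensitivity is recall of the positive (ASD) class; AUROC is reported
    as NaN when the labels are single-class.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    n = len(labels)
    acc = (tp + tn) / n
    ci = binomtest(tp + tn, n).proportion_ci(method="exact")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    if scores is not None and len(set(labels)) == 2:
        auroc = float(roc_auc_score(labels, scores))
    else:
        auroc = float("nan")
    return {
        "accuracy": float(acc),
        "accuracy_ci_low": float(ci.low),
        "accuracy_ci_high": float(ci.high),
        "auroc": auroc,
        "sensitivity": float(sens),
        "specificity": float(spec),
        "f1": float(f1),
    }


def shap_summary(result: NestedCVResult, X: pd.DataFrame, y: pd.Series | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Per-feature attribution summary over the out-of-fold predictions.

    For gradient-boosted models, exact TreeSHAP contributions are computed
    per person on that person's held-out fold; the summary reports mean
    absolute SHAP value and a direction (sign of the correlation between
    feature value and SHAP value). For non-tree models a permutation-
    importance fallback is used and flagged in the ``method`` column.
    """
    Xa = X.to_numpy(dtype=float)
    if result.algorithm == "xgboost":
        contribs = np.zeros((len(Xa), X.shape[1] + 1))
        for model, test_idx in zip(result.fold_models, result.fold_test_index):
            booster = model.get_booster()
            contribs[test_idx] = booster.predict(xgb.DMatrix(Xa[test_idx]), pred_contribs=True)
        shap_vals = contribs[:, :-1]
        rows = []
        for j, feat in enumerate(X.columns):
            vals = shap_vals[:, j]
            if np.std(vals) > 0 and np.std(Xa[:, j]) > 0:
                direction = float(np.sign(np.corrcoef(Xa[:, j], vals)[0, 1]))
            else:
                direction = 0.0
            rows.append(
                {"feature": feat, "mean_abs_shap": float(np.mean(np.abs(vals))),
                 "direction": direction, "method": "treeshap"}
            )
        df = pd.DataFrame(rows).sort_values("mean_abs_shap", ascending=False, ignore_index=True)
        df.attrs["shap_values"] = shap_vals
        df.attrs["shap_base"] = contribs[:, -1]
        return df

    logger.warning("%s has no TreeSHAP; falling back to permutation importance", result.algorithm)
    if y is None:
        y = pd.Series(result.labels)
    importances = np.zeros(X.shape[1])
    for model, test_idx in zip(result.fold_models, result.fold_test_index):
        perm = permutation_importance(
            model, Xa[test_idx], y.to_numpy()[test_idx], n_repeats=10, random_state=seed
        )
        importances += perm.importances_mean
    importances /= len(result.fold_models)
    df = pd.DataFrame(
        {"feature": X.columns, "mean_abs_shap": importances,
         "direction": np.nan, "method": "permutation"}
    ).sort_values("mean_abs_shap", ascending=False, ignore_index=True)
    return df
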