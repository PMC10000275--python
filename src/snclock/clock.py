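"""Age-prediction modeling: five regressors, age-stratified k-fold CV, metrics.

The clock is a regression y = f(X) from selected sncRNA expression features X
to chronological age y. Linear regression and elastic net serve as linear
baselines; adaptive boosting, gradient boosting and random forests are the
ensemble methods whose impurity-based feature importances (normalized to sum
to 1) feed the downstream rank-sum consensus. Cross-validation is stratified
by age group (young/adult/aged) so each fold carries approximately the same
age composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import AgeGrouping

__all__ = [
    "ModelSpec",
    "CVResult",
    "ENSEMBLE_METHODS",
    "ALL_METHODS",
    "stratified_age_folds",
    "fit_predict_cv",
    "evaluate",
    "cross_gender_eval",
]

ENSEMBLE_METHODS = ("adaptive_boosting", "gradient_boosting", "random_forest")
ALL_METHODS = ("linear_regression", "elastic_net") + ENSEMBLE_METHODS


@dataclass(frozen=True)
class ModelSpec:
    """One regression method and its hyperparameters.

    ``n_estimators`` is the number of weak learners (regression trees) in the
    ensemble methods; the remaining knobs apply where the method uses them.
    """

    method: str = "gradient_boosting"
    n_estimators: int = 100
    learning_rate: float = 0.1  # boosting only
    max_depth: int | None = 3  # gradient boosting; forests grow unrestricted
    l1_ratio: float = 0.5  # elastic net
    alpha: float = 1.0  # elastic net regularization strength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {ALL_METHODS}")
        if self.method in ENSEMBLE_METHODS and self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")

    def build(self):
        if self.method == "linear_regression":
            return LinearRegression()
        if self.method == "elastic_net":
            return make_pipeline(
                StandardScaler(),
                ElasticNet(alpha=self.alpha, l1_ratio=self.l1_ratio, max_iter=10_000),
            )
        if self.method == "adaptive_boosting":
            return AdaBoostRegressor(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                random_state=self.seed,
            )
        if self.method == "gradient_boosting":
            return GradientBoostingRegressor(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth if self.max_depth else 3,
                random_state=self.seed,
            )
        # random forest: trees grow to purity (unrestricted depth)
        return RandomForestRegressor(n_estimators=self.n_estimators, random_state=self.seed)


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold and averaged metrics, importances."""

    method: str
    fold_metrics: pd.DataFrame  # columns r2, rmse, mae; one row per fold
    r2: float
    rmse: float
    mae: float
    predictions: pd.Series  # out-of-fold predicted age per sample
    folds: pd.Series  # fold id per sample
    importance: pd.Series | None  # impurity importances (tree methods), sums to 1

    def summary(self) -> str:
        lines = [
            f"method: {self.method}",
            f"averaged over {len(self.fold_metrics)} folds: "
            f"R2={self.r2:.4f} RMSE={self.rmse:.3f}y MAE={self.mae:.3f}y",
        ]
        if self.importance is not None:
            top = self.importance.sort_values(ascending=False).head(5)
            lines.append("top importances: " + ", ".join(f"{g}={v:.3f}" for g, v in top.items()))
        return "\n".join(lines)


def evaluate(predicted, actual) -> tuple[float, float, float]:
    """(R^2, RMSE, MAE) of predictions: R^2 = 1 - SSE/SST on the given pairs."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    err = predicted - actual
    sst = ((actual - actual.mean()) ** 2).sum()
    r2 = 1.0 - (err**2).sum() / sst if sst > 0 else np.nan
    rmse = float(np.sqrt((err**2).mean()))
    mae = float(np.abs(err).mean())
    return float(r2), rmse, mae


def stratified_age_folds(
    meta: pd.DataFrame,
    k: int = 5,
    grouping: AgeGrouping = AgeGrouping(),
    seed: int = 0,
) -> pd.Series:
    """Assign each sample to one of k folds, stratified by age group.

    Within every age group the fold sizes differ by at most one; groups
    smaller than k are spread as evenly as possible. Deterministic under
    ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    groups = grouping.assign(meta["age"])
    fold = pd.Series(-1, index=meta.index, name="fold")
    start = 0
    for label in grouping.labels:
        members = np.array(groups.index[groups == label])
        rng.shuffle(members)
        for i, sid in enumerate(members):
            fold[sid] = (start + i) % k
        start += len(members)  # rotate so small groups don't pile onto fold 0
    return fold


def fit_predict_cv(
    expr_selected: pd.DataFrame,
    ages,
    spec: ModelSpec,
    folds: pd.Series,
) -> CVResult:
    """Out-of-fold CV of one model on a genes x samples feature matrix.

    For each fold the model trains on the remaining samples and predicts the
    held-out ones; metrics are computed per fold and averaged. Importances
    (tree methods) come from a final fit on all samples, normalized to sum
    to 1. Deterministic under ``spec.seed``.
    """
    X = expr_selected.to_numpy(dtype=float).T  # samples x genes
    y = np.asarray(ages, dtype=float)
    folds = folds.reindex(expr_selected.columns)
    if X.shape[0] != len(y) or folds.isna().any():
        raise ValueError("features, ages and folds must cover the same samples")
    ids = sorted(folds.unique())
    if X.shape[0] < len(ids):
        raise ValueError("fewer samples than folds")
    for fid in ids:
        if (folds == fid).all():
            raise ValueError("a single fold holds every sample; training set would be empty")
    rows = []
    preds = pd.Series(np.nan, index=expr_selected.columns, name="predicted_age")
    for fid in ids:
        test = (folds == fid).to_numpy()
        model = spec.build()
        model.fit(X[~test], y[~test])
        p = model.predict(X[test])
        preds.iloc[np.flatnonzero(test)] = p
        rows.append(evaluate(p, y[test]))
    fm = pd.DataFrame(rows, columns=["r2", "rmse", "mae"], index=ids)
    final = spec.build()
    final.fit(X, y)
    importance = None
    if hasattr(final, "feature_importances_"):
        imp = np.asarray(final.feature_importances_, dtype=float)
        total = imp.sum()
        importance = pd.Series(
            imp / total if total > 0 else imp, index=expr_selected.index, name="importance"
        )
    return CVResult(
        method=spec.method,
        fold_metrics=fm,
        r2=float(fm["r2"].mean()),
        rmse=float(fm["rmse"].mean()),
        mae=float(fm["mae"].mean()),
        predictions=preds,
        folds=folds,
        importance=importance,
    )


def cross_gender_eval(
    expr_selected: pd.DataFrame, meta: pd.DataFrame, spec: ModelSpec
) -> dict[str, dict]:
    """Train on one gender, test on the other, in both directions.

    Returns {"male_to_female": {...}, "female_to_male": {...}} with r2, rmse,
    mae, n_train, n_test and (tree methods) the training-fit importance
    vector, from which gender-specific consensus lists can be built.
    """
    gender = meta.loc[expr_selected.columns, "gender"]
    present = set(gender.unique())
    if not {"male", "female"} <= present:
        raise ValueError("cross-gender evaluation needs samples of both genders")
    X = expr_selected.to_numpy(dtype=float).T
    y = meta.loc[expr_selected.columns, "age"].to_numpy(dtype=float)
    out = {}
    for train_g, test_g in (("male", "female"), ("female", "male")):
        tr = (gender == train_g).to_numpy()
        model = spec.build()
        model.fit(X[tr], y[tr])
        r2, rmse, mae = evaluate(model.predict(X[~tr]), y[~tr])
        rec = {"r2": r2, "rmse": rmse, "mae": mae, "n_train": int(tr.sum()),
               "n_test": int((~tr).sum())}
        if hasattr(model, "feature_importances_"):
            imp = np.asarray(model.feature_importances_, dtype=float)
            total = imp.sum()
            rec["importance"] = pd.Series(
                imp / total if total > 0 else imp, index=expr_selected.index
            )
        out[f"{train_g}_to_{test_g}"] = rec
    return out
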