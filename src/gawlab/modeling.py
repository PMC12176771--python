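"""Probabilistic severity classifiers, grid search, CV, and ensembles.

Every roster member outputs a posterior probability of the positive class
(H >= 2); that probability y_hat in [0, 1] is the continuous hoarseness
severity score (0 = normal voice, 1 = severe hoarseness).  Training always
standardizes features with the training mean/std, weights classes inversely
proportional to their frequencies, and selects hyperparameters by an
exhaustive grid search minimizing mean log loss on an inner stratified
3-fold CV.  Equal-weight ensembles average the member probabilities.

The paper-style grids live in a supplement that is not part of this package;
the defaults below are small published-style grids, declared here rather
than inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "PredictionResult",
    "CVReport",
    "LINEAR_MODELS",
    "TREE_MODELS",
    "ROSTER",
    "DEFAULT_GRIDS",
    "make_estimator",
    "class_weights",
    "grid_search",
    "cross_validate",
    "fit_final",
    "predict_severity",
    "ensemble_predict",
]

LINEAR_MODELS = {"logistic_regression", "svm_linear"}
TREE_MODELS = {"xgboost_like_gbt", "lgbm_like_gbt", "catboost_like_gbt", "decision_tree",
               "adaboost", "logitboost"}
ROSTER = [
    "logistic_regression",
    "svm_linear",
    "svm_rbf",
    "decision_tree",
    "adaboost",
    "logitboost",
    "xgboost_like_gbt",
    "lgbm_like_gbt",
    "catboost_like_gbt",
]

# small published-style grids; order of dicts defines the tie-break order
DEFAULT_GRIDS = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm_linear": {"C": [0.1, 1.0, 10.0]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "decision_tree": {"max_depth": [3, 5, None]},
    "adaboost": {"n_estimators": [50, 200], "learning_rate": [0.5, 1.0]},
    "logitboost": {"n_estimators": [100, 300], "learning_rate": [0.1, 0.3]},
    "xgboost_like_gbt": {"n_estimators": [100, 300], "max_depth": [3, 5]},
    "lgbm_like_gbt": {"n_estimators": [100, 300], "num_leaves": [15, 31]},
    "catboost_like_gbt": {"max_iter": [100, 300], "max_depth": [3, 6]},
}


def make_estimator(algorithm_id: str, params: dict, seed: int = 0):
    """Instantiate a roster member with the given hyperparameters.

    All estimators accept ``fit(X, y, sample_weight=...)`` and expose
    ``predict_proba``; LogitBoost is realized as log-loss gradient boosting
    on decision stumps, and the XGBoost-/LGBM-/CatBoost-like slots are the
    corresponding conformant gradient-boosted-tree implementations.
    """
    params = dict(params)
    if algorithm_id == "logistic_regression":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if algorithm_id == "svm_linear":
        return SVC(kernel="linear", probability=True, random_state=seed, **params)
    if algorithm_id == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if algorithm_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm_id == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if algorithm_id == "logitboost":
        params.setdefault("max_depth", 1)  # decision stumps
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm_id == "xgboost_like_gbt":
        from xgboost import XGBClassifier

        params.setdefault("n_estimators", 100)
        params.setdefault("max_depth", 3)
        return XGBClassifier(
            learning_rate=0.1,
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            **params,
        )
    if algorithm_id == "lgbm_like_gbt":
        from lightgbm import LGBMClassifier

        params.setdefault("n_estimators", 100)
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    if algorithm_id == "catboost_like_gbt":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm_id: {algorithm_id}")


@dataclass(frozen=True)
class ModelSpec:
    """A roster member plus its hyperparameter grid and seed."""

    algorithm_id: str
    grid: dict = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm_id not in ROSTER:
            raise ValueError(f"unknown algorithm_id: {self.algorithm_id}")
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.algorithm_id])


@dataclass
class TrainedModel:
    """A fitted estimator with its standardization stats and feature contract."""

    spec: ModelSpec
    estimator: object
    feature_names: list
    mean: np.ndarray
    std: np.ndarray
    class_weight: dict
    best_params: dict

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValueError(f"missing required features: {missing}")
        x = table[self.feature_names].to_numpy(float)
        return (x - self.mean) / self.std


@dataclass
class PredictionResult:
    """Continuous severity scores y_hat in [0, 1] and 0.5-thresholded classes
    (a score of exactly 0.5 maps to the positive class)."""

    y_hat: np.ndarray
    y_bin: np.ndarray


@dataclass
class CVReport:
    """Per-fold metrics and pooled out-of-sample severity scores."""

    fold_metrics: list  # per fold: dict(accuracy, sensitivity, specificity)
    oos_y_hat: np.ndarray  # out-of-sample score for every visit, in row order
    fold_assignment: np.ndarray
    fold_scaler_means: list  # training-fold standardization means (audit trail)
    refold_log: list = field(default_factory=list)

    @property
    def mean_metrics(self) -> dict:
        keys = self.fold_metrics[0].keys()
        return {k: float(np.mean([m[k] for m in self.fold_metrics])) for k in keys}


def class_weights(labels: np.ndarray) -> dict:
    """Weights inversely proportional to class frequencies: w_k = n / (2 n_k)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n = len(labels)
    return {int(c): n / (2.0 * cnt) for c, cnt in zip(classes, counts)}


def _grid_points(grid: dict):
    """Exhaustive grid in documented order: first key varies slowest."""
    keys = list(grid.keys())
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _standardize_fit(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def grid_search(
    spec: ModelSpec,
    train_table: pd.DataFrame,
    labels: np.ndarray,
    inner_folds: int = 3,
    seed: int | None = None,
) -> dict:
    """Exhaustive grid search minimizing mean log loss on an inner 3-fold CV.

    Standardization and fitting happen inside each inner fold; ties resolve
    to the earlier point in the documented grid order.
    """
    labels = np.asarray(labels)
    seed = spec.seed if seed is None else seed
    x = train_table.to_numpy(float)
    candidates = list(_grid_points(spec.grid))
    if not candidates:
        raise ValueError("hyperparameter grid is empty")
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, labels))
    if any(len(np.unique(labels[tr])) < 2 for tr, _ in splits):
        raise ValueError("degenerate inner fold: a class is missing from training data")
    best_params, best_loss = None, np.inf
    for params in candidates:
        losses = []
        for tr, va in splits:
            cw = class_weights(labels[tr])
            sw = np.array([cw[int(v)] for v in labels[tr]])
            mu, sd = _standardize_fit(x[tr])
            est = make_estimator(spec.algorithm_id, params, seed=seed)
            est.fit((x[tr] - mu) / sd, labels[tr], sample_weight=sw)
            proba = est.predict_proba((x[va] - mu) / sd)
            losses.append(log_loss(labels[va], proba, labels=[0, 1]))
        mean_loss = float(np.mean(losses))
        if mean_loss < best_loss:  # strict: ties keep the earlier grid point
            best_loss = mean_loss
            best_params = params
    return best_params


def _fold_metrics(y_true: np.ndarray, y_hat: np.ndarray) -> dict:
    from .evaluation import classification_metrics

    m = classification_metrics(y_true, y_hat)
    return {k: m[k] for k in ("accuracy", "sensitivity", "specificity")}


def cross_validate(
    spec: ModelSpec,
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 5,
    seed: int | None = None,
) -> CVReport:
    """Stratified seeded K-fold CV with no leakage into validation folds.

    Per fold: standardize on the fold's training rows, grid-search on them
    alone, fit with class weights, and score the held-out rows.  Every visit
    receives exactly one out-of-sample severity score.  If a fold's training
    part misses a class, the split is redrawn with a bumped seed (logged).
    """
    labels = np.asarray(labels)
    seed = spec.seed if seed is None else seed
    x = table.to_numpy(float)
    refold_log: list[str] = []
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(x, labels))
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in splits):
            break
        refold_log.append(f"refold with seed {seed + attempt + 1}: class missing in a fold")
    else:
        raise ValueError("could not build folds containing both classes")

    oos = np.full(len(labels), np.nan)
    assignment = np.full(len(labels), -1)
    fold_metrics, scaler_means = [], []
    for fold_id, (tr, va) in enumerate(splits):
        sub = table.iloc[tr]
        best = grid_search(spec, sub, labels[tr], seed=seed)
        mu, sd = _standardize_fit(x[tr])
        cw = class_weights(labels[tr])
        sw = np.array([cw[int(v)] for v in labels[tr]])
        est = make_estimator(spec.algorithm_id, best, seed=seed)
        est.fit((x[tr] - mu) / sd, labels[tr], sample_weight=sw)
        proba = est.predict_proba((x[va] - mu) / sd)[:, 1]
        oos[va] = proba
        assignment[va] = fold_id
        fold_metrics.append(_fold_metrics(labels[va], proba))
        scaler_means.append(mu)
    return CVReport(
        fold_metrics=fold_metrics,
        oos_y_hat=oos,
        fold_assignment=assignment,
        fold_scaler_means=scaler_means,
        refold_log=refold_log,
    )


def fit_final(spec: ModelSpec, table: pd.DataFrame, labels: np.ndarray) -> TrainedModel:
    """Grid-search and fit on the complete training table."""
    labels = np.asarray(labels)
    best = grid_search(spec, table, labels)
    x = table.to_numpy(float)
    mu, sd = _standardize_fit(x)
    cw = class_weights(labels)
    sw = np.array([cw[int(v)] for v in labels])
    est = make_estimator(spec.algorithm_id, best, seed=spec.seed)
    est.fit((x - mu) / sd, labels, sample_weight=sw)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=list(table.columns),
        mean=mu,
        std=sd,
        class_weight=cw,
        best_params=best,
    )


def predict_severity(model: TrainedModel, table: pd.DataFrame) -> PredictionResult:
    """Continuous severity scores for a table of visits."""
    xs = model.transform(table)
    y_hat = model.estimator.predict_proba(xs)[:, 1]
    return PredictionResult(y_hat=y_hat, y_bin=(y_hat >= 0.5).astype(int))


def ensemble_predict(models: list, table: pd.DataFrame) -> PredictionResult:
    """Equal-weight ensemble: the unweighted mean of member severity scores.

    Each member predicts from its own feature block; a missing block raises
    an error naming the absent columns.
    """
    if len(models) < 2:
        raise ValueError("an ensemble needs at least 2 member models")
    member_scores = []
    for model in models:
        missing = [f for f in model.feature_names if f not in table.columns]
        if missing:
            raise ValueError(
                f"missing modality block for {model.spec.algorithm_id}: {missing}"
            )
        member_scores.append(predict_severity(model, table).y_hat)
    y_hat = np.mean(member_scores, axis=0)
    return PredictionResult(y_hat=y_hat, y_bin=(y_hat >= 0.5).astype(int))
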