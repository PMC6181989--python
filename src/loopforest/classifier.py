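"""The random-forest looping classifier and its interrogation tools.

``LoopClassifier`` wraps :class:`sklearn.ensemble.RandomForestClassifier`
with a fixed feature-name contract: the column names and order seen at fit
time are stored on the model and prediction refuses matrices that do not
match.  Cross-validation follows the evaluation protocol of repeated
stratified 10-fold CV (5 iterations differing only in the partition seed),
reporting AU-ROC and AU-PR with 95% confidence intervals and the
precision/recall operating point at probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LoopClassifier",
    "PerformanceSummary",
    "train",
    "predict",
    "cross_validate",
    "feature_importance",
    "recursive_feature_elimination",
    "save_model",
    "load_model",
]


@dataclass
class PerformanceSummary:
    """Repeated-CV performance: AU-ROC / AU-PR with 95% CIs and curves."""

    auroc_values: list[float]
    aupr_values: list[float]
    roc_curve_points: pd.DataFrame | None = None
    pr_curve_points: pd.DataFrame | None = None
    precision_at_half: float | None = None
    recall_at_half: float | None = None

    @staticmethod
    def _ci(values: Sequence[float]) -> float:
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            return 0.0
        return 1.96 * v.std(ddof=1) / np.sqrt(len(v))

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.auroc_values))

    @property
    def auroc_ci(self) -> float:
        return self._ci(self.auroc_values)

    @property
    def aupr_mean(self) -> float:
        return float(np.mean(self.aupr_values))

    @property
    def aupr_ci(self) -> float:
        return self._ci(self.aupr_values)

    def as_dict(self) -> dict:
        return {
            "auroc_mean": self.auroc_mean,
            "auroc_ci95": self.auroc_ci,
            "aupr_mean": self.aupr_mean,
            "aupr_ci95": self.aupr_ci,
            "precision_at_0.5": self.precision_at_half,
            "recall_at_0.5": self.recall_at_half,
            "n_iterations": len(self.auroc_values),
        }


class LoopClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest loop classifier with a persisted feature-order contract.

    Parameters mirror the forest defaults used throughout: 500 trees,
    sqrt-features per split, unlimited depth, uniform class weights (the
    positive:negative ratio is handled by training-set design).
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: str | float = "sqrt",
        max_depth: int | None = None,
        class_weight=None,
        random_state: int | None = 0,
        n_jobs: int | None = None,
        cell_type: str | None = None,
        negative_ratio: float | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.random_state = random_state
        self.n_jobs = n_jobs
        self.cell_type = cell_type
        self.negative_ratio = negative_ratio

    def _forest(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        )

    def fit(self, X, y) -> "LoopClassifier":
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            self.feature_names_ = [f"f{i}" for i in range(Xv.shape[1])]
        if Xv.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        self.forest_ = self._forest().fit(Xv, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = Xv.shape[1]
        return self

    def _validate_columns(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            got = list(X.columns)
            if got != self.feature_names_:
                missing = [c for c in self.feature_names_ if c not in got]
                extra = [c for c in got if c not in self.feature_names_]
                raise ValueError(
                    "feature columns do not match the trained model "
                    f"(missing: {missing or 'none'}; extra: {extra or 'none'}; "
                    "order must be identical)"
                )
            return X.to_numpy(dtype=float)
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xv.shape[1]}"
            )
        return Xv

    def predict_proba(self, X) -> np.ndarray:
        return self.forest_.predict_proba(self._validate_columns(X))

    def predict_probability(self, X) -> np.ndarray:
        """Probability of the positive (looping) class."""
        pos = int(np.flatnonzero(self.classes_ == 1)[0])
        return self.predict_proba(X)[:, pos]

    def predict(self, X, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_probability(X) >= cutoff).astype(int)

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.feature_importances_


def train(
    X: pd.DataFrame, y, seed: int = 0, **hyperparams
) -> LoopClassifier:
    """Fit a :class:`LoopClassifier`; deterministic given ``seed``."""
    return LoopClassifier(random_state=seed, **hyperparams).fit(X, y)


def predict(model: LoopClassifier, X: pd.DataFrame) -> np.ndarray:
    """Positive-class looping probabilities, refusing mismatched columns."""
    return model.predict_probability(X)


def feature_importance(model: LoopClassifier) -> list[tuple[str, float]]:
    """Mean-decrease-in-impurity importances, sorted descending; sums to 1."""
    imp = model.feature_importances_
    order = np.argsort(imp)[::-1]
    return [(model.feature_names_[i], float(imp[i])) for i in order]


def cross_validate(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    iterations: int = 5,
    seed: int = 0,
    model: LoopClassifier | None = None,
    **hyperparams,
) -> PerformanceSummary:
    """Repeated stratified k-fold CV with out-of-fold scoring.

    Each of the ``iterations`` repeats differs only in the partition seed.
    The returned curves are computed on the out-of-fold probabilities of the
    first iteration; AU-ROC / AU-PR statistics aggregate all iterations.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires both classes")
    proto = model if model is not None else LoopClassifier(random_state=seed, **hyperparams)
    auroc, aupr = [], []
    first_oof = None
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        oof = np.full(len(y), np.nan)
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            est = clone(proto)
            Xtr = X.iloc[train_idx] if isinstance(X, pd.DataFrame) else X[train_idx]
            Xte = X.iloc[test_idx] if isinstance(X, pd.DataFrame) else X[test_idx]
            est.fit(Xtr, y[train_idx])
            oof[test_idx] = est.predict_probability(Xte)
        auroc.append(float(roc_auc_score(y, oof)))
        aupr.append(float(average_precision_score(y, oof)))
        if it == 0:
            first_oof = oof
    fpr, tpr, roc_thr = roc_curve(y, first_oof)
    prec, rec, pr_thr = precision_recall_curve(y, first_oof)
    pred_half = (first_oof >= 0.5).astype(int)
    return PerformanceSummary(
        auroc_values=auroc,
        aupr_values=aupr,
        roc_curve_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_curve_points=pd.DataFrame({"precision": prec, "recall": rec}),
        precision_at_half=float(precision_score(y, pred_half, zero_division=0)),
        recall_at_half=float(recall_score(y, pred_half, zero_division=0)),
    )


def recursive_feature_elimination(
    X: pd.DataFrame,
    y,
    step: int = 1,
    seed: int = 0,
    folds: int = 10,
    iterations: int = 5,
    min_features: int = 1,
    **hyperparams,
) -> pd.DataFrame:
    """Recursive feature elimination with full re-evaluation at each size.

    At each round the current feature set is scored by
    :func:`cross_validate`, a forest is fit on all rows to rank features by
    impurity importance, and the ``step`` least-important features are
    dropped.  Returns one row per round: n_features, AU-ROC / AU-PR means
    and 95% CIs, and the surviving feature names.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    current = list(X.columns)
    rows = []
    while True:
        Xc = X[current]
        perf = cross_validate(
            Xc, y, folds=folds, iterations=iterations, seed=seed, **hyperparams
        )
        rows.append(
            {
                "n_features": len(current),
                "auroc_mean": perf.auroc_mean,
                "auroc_ci95": perf.auroc_ci,
                "aupr_mean": perf.aupr_mean,
                "aupr_ci95": perf.aupr_ci,
                "features": tuple(current),
            }
        )
        if len(current) <= min_features:
            break
        ranker = LoopClassifier(random_state=seed, **hyperparams).fit(Xc, y)
        imp = ranker.feature_importances_
        n_drop = min(step, len(current) - min_features)
        drop = set(np.argsort(imp)[:n_drop])
        current = [c for i, c in enumerate(current) if i not in drop]
    return pd.DataFrame(rows)


def save_model(model: LoopClassifier, path) -> None:
    """Persist a fitted model (forest + feature order + metadata)."""
    check_is_fitted(model, "forest_")
    joblib.dump(
        {
            "format_version": 1,
            "params": model.get_params(),
            "feature_names": model.feature_names_,
            "forest": model.forest_,
            "classes": model.classes_,
        },
        path,
    )


def load_model(path) -> LoopClassifier:
    payload = joblib.load(path)
    model = LoopClassifier(**payload["params"])
    model.forest_ = payload["forest"]
    model.feature_names_ = payload["feature_names"]
    model.classes_ = payload["classes"]
    model.n_features_in_ = len(payload["feature_names"])
    return model
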