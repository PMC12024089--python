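"""High-risk screening bench: five classifier families under nested CV.

Ten stratified outer folds; inside each outer-training fold a five-fold grid
search picks hyperparameters (F1 by default, the headline metric for a
positively skewed outcome), the winner is refit on the outer-training fold
and scored on the outer-test fold.  Fold-wise label metrics are summarized
as mean with a t-based 95% CI; ROC / precision-recall / calibration curves
and the Brier score are computed from the pooled out-of-fold probabilities.
The decision threshold for label metrics is fixed at 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core import ResponseMatrix, ValidationError

FAMILIES = ("logistic", "random_forest", "adaboost", "gbdt", "svc")


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family, its hyperparameter grid, and the decision threshold."""

    family: str
    grid: dict
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")
        if not 0 < self.decision_threshold < 1:
            raise ValidationError("decision_threshold must be in (0, 1)")

    def make_estimator(self, seed: int = 0):
        if self.family == "logistic":
            return LogisticRegression(max_iter=2000)
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=seed)
        if self.family == "adaboost":
            return AdaBoostClassifier(random_state=seed)
        if self.family == "gbdt":
            return GradientBoostingClassifier(random_state=seed)
        # RBF SVC with Platt-scaled probabilities (5-fold internal calibration)
        return CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                      ensemble=False)


def default_classifier_specs() -> list[ClassifierSpec]:
    """The five families with small printed grids."""
    return [
        # C=inf is an unpenalized fit; the finite grid point is plain L2
        ClassifierSpec("logistic", {"C": [1.0, np.inf]}),
        ClassifierSpec("random_forest",
                       {"n_estimators": [100, 300], "max_depth": [4, 8]}),
        ClassifierSpec("adaboost",
                       {"n_estimators": [100], "learning_rate": [0.05, 0.1]}),
        ClassifierSpec("gbdt",
                       {"max_depth": [2, 3], "learning_rate": [0.05, 0.1],
                        "n_estimators": [100]}),
        ClassifierSpec("svc", {"estimator__C": [0.1, 1.0, 10.0]}),
    ]


@dataclass(frozen=True)
class FoldMetrics:
    """Confusion counts and the standard binary metrics derived from them."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    mcc_degenerate: bool = False


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> FoldMetrics:
    """Standard formulas; an MCC with a zero denominator is 0 (flagged)."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValidationError("confusion counts must be non-negative")
    total = sum(counts)
    if total < 1:
        raise ValidationError("at least one observation required")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / np.sqrt(float(denom))
    return FoldMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                       sensitivity=sensitivity, specificity=specificity,
                       precision=precision, f1=f1, mcc=float(mcc),
                       mcc_degenerate=degenerate)


def roc_pr_curves(scores, labels):
    """Threshold-sweep ROC and PR curves with trapezoid AUROC and step AUPRC.

    The trapezoid AUROC equals the tie-corrected Mann-Whitney pair-counting
    statistic.  Returns (roc_points, pr_points, auroc, auprc) where the point
    sets are DataFrames.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present for curves")
    fpr, tpr, roc_thr = roc_curve(y, scores)
    precision, recall, pr_thr = precision_recall_curve(y, scores)
    auroc = float(auc(fpr, tpr))
    auprc = float(average_precision_score(y, scores))
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    pr_points = pd.DataFrame({"recall": recall, "precision": precision})
    return roc_points, pr_points, auroc, auprc


def brier_and_calibration(probs, labels, n_bins: int = 10):
    """Brier score plus equal-width calibration bins (empty bins omitted)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(float)
    if probs.shape != y.shape:
        raise ValidationError("probs and labels must align")
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    brier = float(np.mean((probs - y) ** 2))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append({"bin": b, "mean_predicted": float(probs[mask].mean()),
                     "observed_fraction": float(y[mask].mean()),
                     "count": int(mask.sum())})
    return brier, pd.DataFrame(rows)


@dataclass
class CVResult:
    """Fold-wise metrics with 95% CIs plus pooled out-of-fold curve data."""

    family: str
    folds: list
    summary: pd.DataFrame  # index metric, columns mean/ci_low/ci_high
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    auroc: float
    auprc: float
    brier: float
    calibration: pd.DataFrame
    oof_probs: np.ndarray = None
    best_params: list = field(default_factory=list)


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "mcc")


def _summarize_folds(folds) -> pd.DataFrame:
    rows = {}
    k = len(folds)
    tcrit = stats.t.ppf(0.975, df=k - 1) if k > 1 else 0.0
    for name in METRIC_NAMES:
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        mean = vals.mean()
        half = tcrit * vals.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
        rows[name] = {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}
    return pd.DataFrame(rows).T


def _as_feature_array(features):
    if isinstance(features, ResponseMatrix):
        return features.values.astype(float)
    return np.asarray(features, dtype=float)


def nested_cv_evaluate(features, labels, specs=None, seed: int = 0,
                       n_outer: int = 10, n_inner: int = 5,
                       scoring: str = "f1") -> dict:
    """Nested stratified CV over a list of classifier specs.

    Returns ``{family: CVResult}``.  Deterministic under ``seed``: the same
    seed reproduces fold assignments, tuned hyperparameters, and curves.
    """
    X = _as_feature_array(features)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels must align")
    if X.shape[0] < 20:
        raise ValidationError("need at least 20 observations for nested CV")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    if counts.min() < n_outer:
        raise ValidationError(
            f"minority class has {counts.min()} members; cannot stratify "
            f"{n_outer} outer folds"
        )
    if specs is None:
        specs = default_classifier_specs()
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    results = {}
    for spec in specs:
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True,
                                random_state=seed + 1)
        folds, oof = [], np.full(X.shape[0], np.nan)
        best_params = []
        for train_idx, test_idx in outer.split(X, y):
            search = GridSearchCV(spec.make_estimator(seed), spec.grid,
                                  scoring=scoring, cv=inner, refit=True)
            search.fit(X[train_idx], y[train_idx])
            best_params.append(dict(search.best_params_))
            probs = search.predict_proba(X[test_idx])[:, 1]
            oof[test_idx] = probs
            pred = probs >= spec.decision_threshold
            truth = y[test_idx].astype(bool)
            folds.append(confusion_metrics(
                tp=int(np.sum(pred & truth)), fp=int(np.sum(pred & ~truth)),
                tn=int(np.sum(~pred & ~truth)), fn=int(np.sum(~pred & truth)),
            ))
        roc_points, pr_points, auroc, auprc = roc_pr_curves(oof, y)
        brier, calibration = brier_and_calibration(oof, y)
        results[spec.family] = CVResult(
            family=spec.family, folds=folds, summary=_summarize_folds(folds),
            roc_points=roc_points, pr_points=pr_points, auroc=auroc,
            auprc=auprc, brier=brier, calibration=calibration, oof_probs=oof,
            best_params=best_params,
        )
    return results


@dataclass
class ScreeningModel:
    """A deployable classifier over a fixed item subset.

    Carries everything needed to score new response CSVs: the item ids, the
    GSI T-score norms used to define the high-risk label, the decision
    threshold, and the fitted estimator.
    """

    estimator: object
    item_ids: tuple
    norm_mean: float
    norm_sd: float
    decision_threshold: float
    family: str
    params: dict
    version: str = "1"

    def predict_proba(self, r) -> np.ndarray:
        X = self._features(r)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, r) -> np.ndarray:
        return self.predict_proba(r) >= self.decision_threshold

    def _features(self, r) -> np.ndarray:
        if isinstance(r, ResponseMatrix):
            present = set(map(str, r.item_ids))
            missing = [i for i in self.item_ids if str(i) not in present]
            if missing:
                raise ValidationError(f"responses are missing scale items: {missing}")
            return r.subset(list(self.item_ids)).values.astype(float)
        return np.asarray(r, dtype=float)

    def save(self, path) -> None:
        path = str(path)
        joblib.dump(self, path)
        meta = {
            "family": self.family, "item_ids": [str(i) for i in self.item_ids],
            "norm_mean": self.norm_mean, "norm_sd": self.norm_sd,
            "decision_threshold": self.decision_threshold,
            "params": {k: repr(v) for k, v in self.params.items()},
            "version": self.version,
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @staticmethod
    def load(path) -> "ScreeningModel":
        return joblib.load(str(path))


def train_final(features, labels, spec: ClassifierSpec, seed: int = 0,
                item_ids=None, norm_mean: float = None, norm_sd: float = None,
                n_inner: int = 5, scoring: str = "f1") -> ScreeningModel:
    """Tune on the full data by grid search and refit the final classifier."""
    X = _as_feature_array(features)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed + 1)
    search = GridSearchCV(spec.make_estimator(seed), spec.grid, scoring=scoring,
                          cv=inner, refit=True)
    search.fit(X, y)
    if item_ids is None and isinstance(features, ResponseMatrix):
        item_ids = tuple(features.item_ids)
    return ScreeningModel(
        estimator=search.best_estimator_,
        item_ids=tuple(item_ids) if item_ids is not None else tuple(range(X.shape[1])),
        norm_mean=float(norm_mean) if norm_mean is not None else float("nan"),
        norm_sd=float(norm_sd) if norm_sd is not None else float("nan"),
        decision_threshold=spec.decision_threshold,
        family=spec.family, params=dict(search.best_params_),
    )
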