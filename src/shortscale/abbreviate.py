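"""Iterative scale abbreviation driven by GSI prediction.

For each candidate size k the training items are divided into k variable
clusters, each cluster's minimum-RS-ratio item is selected, and a regression
of the full-scale GSI on the k selected items is fit on the training split
and evaluated on the held-out test split.  The sweep stops at the smallest k
whose test-set Pearson correlation between predicted and actual GSI reaches
the stopping threshold (default 0.96, the best correlation reported for
existing short forms of the instrument).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression, RidgeCV

from .core import ItemBank, ResponseMatrix, ValidationError, compute_scores, gsi_scores
from .psychometrics import cronbach_alpha
from .varclus import correlation_matrix, fit_varclus, select_representatives

METHODS = ("ols", "robust", "ridge")
RIDGE_PENALTY_GRID = tuple(10.0**k for k in range(-3, 3))
HUBER_TUNING_CONSTANT = 1.345


@dataclass(frozen=True)
class RegressionModel:
    """Fitted affine predictor ``y = b0 + x @ b``."""

    intercept: float
    coefficients: np.ndarray
    item_ids: tuple
    method: str
    ridge_penalty: float = None

    def predict(self, r: ResponseMatrix) -> np.ndarray:
        X = r.values[:, r.column_index(self.item_ids)].astype(float)
        return self.intercept + X @ self.coefficients


@dataclass(frozen=True)
class PredictionMetrics:
    """Held-out RMSE, coefficient of determination and Pearson correlation."""

    rmse: float
    r2: float
    pearson_r: float


def fit_gsi_regressor(train: ResponseMatrix, items, target, method: str = "ols",
                      ) -> RegressionModel:
    """Fit an OLS, Huber-robust, or cross-validated ridge regression.

    ``target`` is the per-respondent criterion (usually the full-scale GSI of
    the training rows).  Ridge chooses its penalty by 5-fold cross-validation
    over a fixed 10^-3..10^2 grid; robust regression is M-estimation with a
    Huber tuning constant of 1.345.
    """
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    items = list(items)
    if not items:
        raise ValidationError("need at least one predictor item")
    X = train.values[:, train.column_index(items)].astype(float)
    y = np.asarray(target, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("target length does not match training rows")
    penalty = None
    if method == "ols":
        if X.shape[0] <= X.shape[1] + 1:
            raise ValidationError("OLS needs n_train > n_items + 1")
        design = np.column_stack([np.ones(X.shape[0]), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(
                "rank-deficient design (collinear items); consider method='ridge'"
            )
        model = LinearRegression().fit(X, y)
        intercept, coef = float(model.intercept_), model.coef_.copy()
    elif method == "robust":
        design = sm.add_constant(X)
        fit = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=HUBER_TUNING_CONSTANT)).fit()
        intercept, coef = float(fit.params[0]), np.asarray(fit.params[1:])
    else:  # ridge
        model = RidgeCV(alphas=RIDGE_PENALTY_GRID, cv=5).fit(X, y)
        intercept, coef = float(model.intercept_), model.coef_.copy()
        penalty = float(model.alpha_)
    return RegressionModel(
        intercept=intercept, coefficients=coef, item_ids=tuple(items),
        method=method, ridge_penalty=penalty,
    )


def prediction_metrics(y_true, y_pred) -> PredictionMetrics:
    """RMSE, R-squared and Pearson r between actual and predicted values."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValidationError("targets and predictions must be same-length and nonempty")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("constant target: R^2 and Pearson r are undefined")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    if np.std(yhat) == 0:
        raise ValidationError("constant predictions: Pearson r is undefined")
    xc, yc = yhat - yhat.mean(), y - y.mean()
    pearson = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    return PredictionMetrics(rmse=rmse, r2=r2, pearson_r=pearson)


def evaluate_prediction(model: RegressionModel, test: ResponseMatrix, items,
                        target) -> PredictionMetrics:
    """Evaluate a fitted regressor on held-out rows against ``target``."""
    if test.n == 0:
        raise ValidationError("empty test set")
    del items  # the fitted model already carries its item subset
    return prediction_metrics(target, model.predict(test))


@dataclass
class AbbreviationTrace:
    """Per-k record of the sweep: items, internal consistency, test metrics."""

    table: pd.DataFrame  # columns: k, item_ids, cronbach_alpha, rmse, r2, pearson_r

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["item_ids"] = [
            ";".join(str(i) for i in ids) for ids in out["item_ids"]
        ]
        out.to_csv(path, index=False)


@dataclass
class AbbreviatedScale:
    """The selected item subset with its achieved metrics and fitted model."""

    item_ids: tuple
    k: int
    stop_threshold: float
    achieved_metrics: PredictionMetrics
    gsi_model: RegressionModel
    met_threshold: bool


def sweep_and_select(train: ResponseMatrix, test: ResponseMatrix, bank: ItemBank = None,
                     stop_r: float = 0.96, k_max: int = 30, method: str = "ols",
                     ) -> tuple[AbbreviatedScale, AbbreviationTrace]:
    """Sweep k = 1..k_max cluster solutions and stop at the Pearson criterion.

    Clustering, representative selection and regression fitting touch only the
    training split; the test split enters only through final evaluation of
    each k's regressor against the test rows' full-scale GSI.
    """
    if train.n == 0 or test.n == 0:
        raise ValidationError("train and test must both be nonempty")
    if not 0 < stop_r <= 1:
        raise ValidationError(f"stop_r must be in (0, 1], got {stop_r}")
    if not 1 <= k_max <= train.p:
        raise ValidationError(f"k_max must be in 1..{train.p}, got {k_max}")
    if list(train.item_ids) != list(test.item_ids):
        raise ValidationError("train and test must share the same items")
    y_train = gsi_scores(train)
    y_test = gsi_scores(test)
    corr = correlation_matrix(train)
    rows = []
    selected = None
    for k in range(1, k_max + 1):
        solution = fit_varclus(corr, target_clusters=k)
        items = list(select_representatives(solution).item_ids)
        model = fit_gsi_regressor(train, items, y_train, method=method)
        metrics = evaluate_prediction(model, test, items, y_test)
        alpha = cronbach_alpha(train, items) if len(items) >= 2 else np.nan
        rows.append(
            {
                "k": k, "item_ids": tuple(items), "cronbach_alpha": alpha,
                "rmse": metrics.rmse, "r2": metrics.r2,
                "pearson_r": metrics.pearson_r,
            }
        )
        if metrics.pearson_r >= stop_r:
            selected = AbbreviatedScale(
                item_ids=tuple(items), k=k, stop_threshold=stop_r,
                achieved_metrics=metrics, gsi_model=model, met_threshold=True,
            )
            break
    trace = AbbreviationTrace(pd.DataFrame(rows))
    if selected is None:
        last = rows[-1]
        selected = AbbreviatedScale(
            item_ids=last["item_ids"], k=last["k"], stop_threshold=stop_r,
            achieved_metrics=PredictionMetrics(last["rmse"], last["r2"],
                                               last["pearson_r"]),
            gsi_model=model, met_threshold=False,
        )
    return selected, trace


def predict_subscales(train: ResponseMatrix, test: ResponseMatrix, items,
                      bank: ItemBank, method: str = "ols") -> pd.DataFrame:
    """Regress each full-scale subscale score on the item subset.

    One regression per subscale (criterion = that subscale's mean score from
    the full item set), trained on the training rows and evaluated on the
    test rows.  Returns one metric row per subscale.
    """
    items = list(items)
    if not items:
        raise ValidationError("need a nonempty item subset")
    train_scores = compute_scores(train, bank).subscale_scores
    test_scores = compute_scores(test, bank).subscale_scores
    rows = []
    for sub in train_scores.columns:
        model = fit_gsi_regressor(train, items, train_scores[sub].to_numpy(),
                                  method=method)
        m = evaluate_prediction(model, test, items, test_scores[sub].to_numpy())
        rows.append({"subscale": sub, "rmse": m.rmse, "r2": m.r2,
                     "pearson_r": m.pearson_r})
    return pd.DataFrame(rows)


class ScaleAbbreviator(BaseEstimator, RegressorMixin):
    """Scale abbreviation as a scikit-learn style estimator.

    ``fit(X_train, X_test=...)`` runs the sweep; ``transform`` restricts a
    response matrix to the selected items; ``predict`` returns the fitted
    GSI prediction from the selected items.

    Attributes (after fit): ``item_ids_``, ``k_``, ``trace_``, ``metrics_``,
    ``scale_``.
    """

    def __init__(self, stop_r: float = 0.96, k_max: int = 30,
                 method: str = "ols", test_fraction: float = 0.2,
                 random_state: int = 0):
        self.stop_r = stop_r
        self.k_max = k_max
        self.method = method
        self.test_fraction = test_fraction
        self.random_state = random_state

    def fit(self, X, y=None, X_test=None):
        train = self._as_responses(X)
        if X_test is None:
            from .core import split_train_test

            train, test = split_train_test(train, self.test_fraction,
                                           self.random_state)
        else:
            test = self._as_responses(X_test)
        scale, trace = sweep_and_select(
            train, test, stop_r=self.stop_r, k_max=self.k_max, method=self.method
        )
        self.scale_ = scale
        self.trace_ = trace
        self.item_ids_ = list(scale.item_ids)
        self.k_ = scale.k
        self.metrics_ = scale.achieved_metrics
        self.met_threshold_ = scale.met_threshold
        return self

    def transform(self, X):
        r = self._as_responses(X)
        return r.subset(self.item_ids_).values

    def predict(self, X):
        return self.scale_.gsi_model.predict(self._as_responses(X))

    @staticmethod
    def _as_responses(X) -> ResponseMatrix:
        if isinstance(X, ResponseMatrix):
            return X
        X = np.asarray(X)
        return ResponseMatrix(X, [f"v{j + 1}" for j in range(X.shape[1])])
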