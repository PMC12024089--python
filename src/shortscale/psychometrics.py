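"""Reliability and factor-structure validation.

Covers Cronbach's alpha (covariance form), McDonald's omega for a one-factor
solution, exploratory factor analysis (eigenvalues, Kaiser-Guttman count,
principal-axis loadings, scree data), and a one-factor confirmatory factor
analysis estimated by maximum likelihood with the usual fit indices
(chi-square, SRMR, RMSEA, CFI, TLI).

The CFA minimizes the ML discrepancy

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over loadings lambda and unique variances theta, with Sigma = lambda lambda'
+ diag(theta), on the Pearson correlation matrix of raw Likert scores.
chi-square = (n - 1) * F_ML at the optimum.  The independence model (zero
covariances) is the CFI/TLI baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .core import ResponseMatrix, ValidationError
from .varclus import CorrelationMatrix

HEYWOOD_TOL = 1e-5


def _items_values(r, items=None) -> np.ndarray:
    if isinstance(r, ResponseMatrix):
        if items is not None:
            r = r.subset(list(items))
        return r.values.astype(float)
    X = np.asarray(r, dtype=float)
    if items is not None:
        X = X[:, np.asarray(items)]
    return X


def cronbach_alpha(r, items=None) -> float:
    """Covariance-based Cronbach's alpha: N*cbar / (vbar + (N-1)*cbar).

    ``cbar`` is the mean inter-item covariance and ``vbar`` the mean item
    variance, both with n-1 denominators.
    """
    X = _items_values(r, items)
    n, k = X.shape
    if k < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 items")
    cov = np.cov(X, rowvar=False, ddof=1)
    v = np.diag(cov)
    if np.any(v == 0):
        raise ValidationError("an item has zero variance")
    cbar = (cov.sum() - v.sum()) / (k * (k - 1))
    vbar = v.mean()
    return float(k * cbar / (vbar + (k - 1) * cbar))


@dataclass
class EFASolution:
    """Eigenvalues, Kaiser-Guttman factor count, and principal-axis loadings."""

    eigenvalues: np.ndarray
    n_factors_kaiser: int
    loadings: np.ndarray  # items x retained factors
    item_ids: tuple
    warnings: tuple = ()

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"factor": np.arange(1, len(self.eigenvalues) + 1),
             "eigenvalue": self.eigenvalues}
        )


def _pearson(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError(f"item at column {int(np.flatnonzero(sd == 0)[0])} "
                              "has zero variance")
    C = np.corrcoef(X, rowvar=False)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def _item_labels(r, items, p) -> tuple:
    if isinstance(r, ResponseMatrix):
        return tuple(items) if items is not None else tuple(r.item_ids)
    return tuple(items) if items is not None else tuple(f"v{j+1}" for j in range(p))


def efa(r, items=None, n_factors: int = None) -> EFASolution:
    """Unrotated principal-axis EFA on the item correlation matrix.

    The retained factor count defaults to the Kaiser-Guttman rule
    (eigenvalues > 1), floored at 1 so a factor always exists.
    """
    if isinstance(r, CorrelationMatrix):
        C, item_ids = r.values, r.item_ids
    else:
        X = _items_values(r, items)
        if X.shape[1] < 2:
            raise ValidationError("EFA needs at least 2 items")
        if X.shape[0] <= X.shape[1]:
            raise ValidationError("EFA needs more respondents than items")
        C, item_ids = _pearson(X), _item_labels(r, items, X.shape[1])
    p = C.shape[0]
    eigenvalues = np.sort(np.linalg.eigvalsh(C))[::-1]
    kaiser = max(1, int(np.sum(eigenvalues > 1.0)))
    m = n_factors if n_factors is not None else kaiser
    notes = []
    if np.linalg.matrix_rank(C) < p:
        notes.append("singular correlation matrix; reduced-rank loadings")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
    loadings = _principal_axis(C, m)
    # sign convention: each factor's loading sum is positive
    for j in range(loadings.shape[1]):
        if loadings[:, j].sum() < 0:
            loadings[:, j] = -loadings[:, j]
    return EFASolution(eigenvalues=eigenvalues, n_factors_kaiser=kaiser,
                       loadings=loadings, item_ids=tuple(item_ids),
                       warnings=tuple(notes))


def _principal_axis(C: np.ndarray, m: int, max_iter: int = 100,
                    tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring with SMC starting communalities."""
    p = C.shape[0]
    try:
        inv = np.linalg.inv(C)
        h2 = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.0, 1.0)
    loadings = np.zeros((p, m))
    for _ in range(max_iter):
        R = C.copy()
        np.fill_diagonal(R, h2)
        w, V = np.linalg.eigh(R)
        order = np.argsort(w)[::-1][:m]
        loadings = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))
        new_h2 = np.clip((loadings**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    return loadings


@dataclass
class CFAFit:
    """Standardized one-factor solution with ML fit statistics."""

    loadings: np.ndarray
    error_variances: np.ndarray
    chi_square: float
    df: int
    srmr: float
    rmsea: float
    cfi: float
    tli: float
    n: int
    f_ml: float
    converged: bool
    heywood: bool
    item_ids: tuple


def mcdonald_omega(fit) -> float:
    """One-factor McDonald's omega: (sum lambda)^2 / ((sum lambda)^2 + sum theta).

    ``fit`` is a :class:`CFAFit` or a ``(loadings, error_variances)`` pair.
    A Heywood solution (any non-positive unique variance) is an error, never
    silently clamped.
    """
    if isinstance(fit, CFAFit):
        lam, theta = fit.loadings, fit.error_variances
        if fit.heywood:
            raise ValidationError("Heywood case: omega undefined for this solution")
    else:
        lam, theta = (np.asarray(a, dtype=float) for a in fit)
    lam = np.asarray(lam, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValidationError("non-positive error variance (Heywood case)")
    s = lam.sum() ** 2
    return float(s / (s + theta.sum()))


def _ml_discrepancy_and_grad(params, S, p):
    lam, theta = params[:p], params[p:]
    Sigma = np.outer(lam, lam)
    Sigma[np.diag_indices(p)] += theta
    try:
        Sigma_inv = np.linalg.inv(Sigma)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10, np.zeros_like(params)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    sign_s, logdet_s = np.linalg.slogdet(S)
    F = logdet + np.trace(S @ Sigma_inv) - logdet_s - p
    A = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    grad = np.concatenate([2.0 * (A @ lam), np.diag(A)])
    return F, grad


def cfa_one_factor(r, items=None, max_iter: int = 500, tol: float = 1e-10,
                   n_starts: int = 3) -> CFAFit:
    """Fit the standardized one-factor model by maximum likelihood.

    Starting values are the first-principal-component loadings (plus two fixed
    alternative starts); the best of the converged objectives is kept.
    Degrees of freedom are p(p+1)/2 - 2p.
    """
    X = _items_values(r, items)
    n, p = X.shape
    if p < 3:
        raise ValidationError("one-factor CFA needs at least 3 items")
    if n <= p:
        raise ValidationError("need more respondents than items")
    S = _pearson(X)
    item_ids = _item_labels(r, items, p)
    return cfa_from_correlation(S, n, item_ids=item_ids, max_iter=max_iter,
                                tol=tol, n_starts=n_starts)


def cfa_from_correlation(S, n: int, item_ids=None, max_iter: int = 500,
                         tol: float = 1e-10, n_starts: int = 3) -> CFAFit:
    """Fit the one-factor model directly to a correlation matrix at sample size n."""
    if isinstance(S, CorrelationMatrix):
        item_ids = item_ids or S.item_ids
        S = S.values
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p < 3:
        raise ValidationError("one-factor CFA needs at least 3 items")
    if item_ids is None:
        item_ids = tuple(f"v{j+1}" for j in range(p))
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValidationError("singular sample correlation matrix")

    w, V = np.linalg.eigh(S)
    v1 = V[:, -1] * np.sqrt(max(w[-1], 0.0))
    if v1.sum() < 0:
        v1 = -v1
    starts = [np.clip(v1, -0.95, 0.95), np.full(p, 0.5), np.full(p, 0.3)][:n_starts]
    bounds = [(-2.0, 2.0)] * p + [(1e-6, 10.0)] * p
    best = None
    for lam0 in starts:
        x0 = np.concatenate([lam0, np.clip(1.0 - lam0**2, 0.05, 1.0)])
        res = minimize(
            _ml_discrepancy_and_grad, x0, args=(S, p), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValidationError("CFA did not converge")
    if not best.success and best.fun > 1e6:
        raise ValidationError(
            f"CFA non-convergence after iteration cap; last objective {best.fun:.3g}"
        )
    lam, theta = best.x[:p], best.x[p:]
    if lam.sum() < 0:
        lam = -lam
    heywood = bool(np.any(theta <= HEYWOOD_TOL))
    f_ml = float(max(best.fun, 0.0))
    chi_square = (n - 1) * f_ml
    df = p * (p + 1) // 2 - 2 * p
    # standardized solution (exact unit implied diagonal)
    total = lam**2 + theta
    lam_std = lam / np.sqrt(total)
    theta_std = 1.0 - lam_std**2
    Sigma_std = np.outer(lam_std, lam_std)
    Sigma_std[np.diag_indices(p)] = 1.0
    residuals = S - Sigma_std
    chi_b = (n - 1) * (-logdet_s)
    df_b = p * (p - 1) // 2
    if df == 0:  # just-identified (p = 3): saturated fit, indices degenerate
        tril = residuals[np.tril_indices(p)]
        srmr = float(np.sqrt(np.mean(tril**2)))
        rmsea, cfi, tli = 0.0, 1.0, 1.0
    else:
        srmr, rmsea, cfi, tli = fit_indices(chi_square, df, chi_b, df_b, n,
                                            residuals)
    return CFAFit(
        loadings=lam_std, error_variances=theta_std, chi_square=float(chi_square),
        df=df, srmr=srmr, rmsea=rmsea, cfi=cfi, tli=tli, n=n, f_ml=f_ml,
        converged=bool(best.success), heywood=heywood, item_ids=tuple(item_ids),
    )


def fit_indices(chi_square: float, df: int, baseline_chi_square: float,
                baseline_df: int, n: int, residuals) -> tuple[float, float, float, float]:
    """(SRMR, RMSEA, CFI, TLI) from chi-squares and the standardized residuals.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))); CFI and TLI use the
    independence baseline; SRMR is the root mean square of the lower-triangle
    (diagonal included) standardized residuals.
    """
    if df <= 0 or baseline_df <= 0:
        raise ValidationError("df and baseline_df must be positive")
    if n <= 1:
        raise ValidationError("n must exceed 1")
    residuals = np.asarray(residuals, dtype=float)
    tril = residuals[np.tril_indices(residuals.shape[0])]
    srmr = float(np.sqrt(np.mean(tril**2)))
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    num = max(chi_square - df, 0.0)
    denom = max(baseline_chi_square - baseline_df, chi_square - df, 0.0)
    cfi = 1.0 if denom == 0 else float(1.0 - num / denom)
    base_ratio = baseline_chi_square / baseline_df
    if base_ratio <= 1.0:
        tli = 1.0
    else:
        tli = float((base_ratio - chi_square / df) / (base_ratio - 1.0))
    return srmr, rmsea, cfi, tli


def split_half(r: ResponseMatrix, seed: int = 0) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Random 50/50 respondent split (disjoint halves for EFA vs CFA)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(r.n)
    half = r.n // 2
    a, b = np.sort(perm[:half]), np.sort(perm[half:])

    def take(idx):
        return ResponseMatrix(r.values[idx], r.item_ids,
                              [r.respondent_ids[i] for i in idx])

    return take(a), take(b)


class OneFactorCFA(BaseEstimator):
    """One-factor ML CFA as an estimator.

    After ``fit(X)``: ``loadings_``, ``error_variances_``, ``chi_square_``,
    ``df_``, ``srmr_``, ``rmsea_``, ``cfi_``, ``tli_``, ``omega_``.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-10, n_starts: int = 3):
        self.max_iter = max_iter
        self.tol = tol
        self.n_starts = n_starts

    def fit(self, X, y=None):
        fit = cfa_one_factor(X, max_iter=self.max_iter, tol=self.tol,
                             n_starts=self.n_starts)
        self.fit_ = fit
        self.loadings_ = fit.loadings
        self.error_variances_ = fit.error_variances
        self.chi_square_ = fit.chi_square
        self.df_ = fit.df
        self.srmr_ = fit.srmr
        self.rmsea_ = fit.rmsea
        self.cfi_ = fit.cfi
        self.tli_ = fit.tli
        self.heywood_ = fit.heywood
        self.omega_ = None if fit.heywood else mcdonald_omega(fit)
        return self
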