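"""Divisive variable clustering (VARCLUS) with RS-ratio representative selection.

The algorithm groups correlated items around cluster principal components:

1. start with all items in one cluster;
2. while some cluster's *second* eigenvalue exceeds a threshold (default 1.0,
   the Kaiser-style cutoff), split the worst such cluster in two along its
   first two principal components (quartimax-rotated), assigning each member
   to the component it correlates with more strongly;
3. after each split, iteratively reassign every item to the cluster whose
   first principal component explains more of its variance, until a fixed
   point (monotone in the summed explained variance).

For each item j in cluster i the RS ratio is ``(1 - gamma) / (1 - nu)`` where
``gamma`` is the proportion of j's variance explained by its own cluster's
first principal component and ``nu`` the best such proportion over all other
clusters.  The item minimizing the RS ratio is the cluster's representative:
maximally tied to its own cluster, minimally tied to the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .core import ResponseMatrix, ValidationError


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric PSD item correlation matrix with unit diagonal."""

    values: np.ndarray
    item_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if len(self.item_ids) != v.shape[0]:
            raise ValidationError("item_ids length mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise ValidationError("correlation entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(v).min() < -1e-8:
            raise ValidationError("correlation matrix is not PSD within tolerance")

    @property
    def p(self) -> int:
        return self.values.shape[0]


def correlation_matrix(r: ResponseMatrix) -> CorrelationMatrix:
    """Pearson product-moment correlations (n-1 denominators) of the items."""
    if r.n < 3:
        raise ValidationError("need at least 3 respondents for correlations")
    X = r.values.astype(float)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"item {r.item_ids[zero[0]]!r} has zero sample variance"
        )
    C = np.corrcoef(X, rowvar=False)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    # clip tiny negative eigenvalue noise is unnecessary for sample Pearson
    return CorrelationMatrix(np.clip(C, -1.0, 1.0), tuple(r.item_ids))


@dataclass(frozen=True)
class EigenSystem:
    """Descending eigenvalues with orthonormal eigenvector columns."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def eigendecompose(c: CorrelationMatrix) -> EigenSystem:
    """Full eigendecomposition, eigenvalues descending.

    Sign convention: each eigenvector's largest-magnitude entry is positive.
    """
    w, V = np.linalg.eigh(c.values)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return EigenSystem(eigenvalues=w, eigenvectors=V)


def _cluster_eigh(C: np.ndarray, members: np.ndarray):
    """Descending eigenvalues/vectors of a cluster's correlation submatrix."""
    sub = C[np.ix_(members, members)]
    w, V = np.linalg.eigh(sub)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def _pc_correlations(C: np.ndarray, members: np.ndarray, v1: np.ndarray,
                     lam1: float) -> np.ndarray:
    """Correlation of every item with the cluster's first principal component.

    The PC score is v1' z_members (standardized items), with variance lam1, so
    corr(x_j, PC) = (C[j, members] @ v1) / sqrt(lam1).
    """
    if lam1 <= 0:
        return np.zeros(C.shape[0])
    return (C[:, members] @ v1) / np.sqrt(lam1)


@dataclass
class ClusterSolution:
    """Item-to-cluster assignment plus per-cluster eigenstructure.

    ``rs_table`` is populated by :func:`rs_ratio_table` (or ``fit_varclus``):
    one row per item with its own-cluster explained variance ``gamma``, the
    best foreign explained variance ``nu`` and ``rs_ratio = (1-gamma)/(1-nu)``.
    """

    item_ids: tuple
    labels: np.ndarray  # cluster index per item position
    first_eigenvalues: np.ndarray
    second_eigenvalues: np.ndarray
    pc_loadings: list  # per cluster, first-eigenvector over its members
    converged: bool = True
    rs_table: pd.DataFrame = None

    @property
    def n_clusters(self) -> int:
        return len(self.first_eigenvalues)

    @property
    def assignment(self) -> dict:
        return {item: int(k) for item, k in zip(self.item_ids, self.labels)}

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def _solution_from_labels(c: CorrelationMatrix, labels: np.ndarray,
                          converged: bool = True) -> ClusterSolution:
    labels = _canonical_labels(labels)
    ks = int(labels.max()) + 1
    first = np.empty(ks)
    second = np.empty(ks)
    loadings = []
    for k in range(ks):
        members = np.flatnonzero(labels == k)
        w, V = _cluster_eigh(c.values, members)
        first[k] = w[0]
        second[k] = w[1] if len(w) > 1 else -np.inf
        v1 = V[:, 0]
        if v1[np.argmax(np.abs(v1))] < 0:
            v1 = -v1
        loadings.append(v1)
    return ClusterSolution(
        item_ids=c.item_ids, labels=labels, first_eigenvalues=first,
        second_eigenvalues=second, pc_loadings=loadings, converged=converged,
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (stable, permutation-safe)."""
    labels = np.asarray(labels)
    mapping = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _quartimax_rotate(loadings: np.ndarray) -> np.ndarray:
    """Orthogonally rotate a two-column loading matrix to maximize sum(l^4)."""

    def neg_criterion(theta):
        ct, st = np.cos(theta), np.sin(theta)
        R = np.array([[ct, -st], [st, ct]])
        L = loadings @ R
        return -np.sum(L**4)

    grid = np.linspace(0.0, np.pi / 2, 181)
    vals = [neg_criterion(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    lo, hi = max(0.0, t0 - 0.02), min(np.pi / 2, t0 + 0.02)
    res = minimize_scalar(neg_criterion, bounds=(lo, hi), method="bounded")
    theta = res.x if res.fun < neg_criterion(t0) else t0
    ct, st = np.cos(theta), np.sin(theta)
    return np.array([[ct, -st], [st, ct]])


def _split_cluster(C: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split one cluster's members along its quartimax-rotated first two PCs."""
    w, V = _cluster_eigh(C, members)
    sub = C[np.ix_(members, members)]
    L = V[:, :2] * np.sqrt(np.maximum(w[:2], 0.0))
    R = _quartimax_rotate(L)
    U = V[:, :2] @ R  # rotated component directions in member space
    var = np.einsum("jk,ji,ik->k", U, sub, U)  # variance of each rotated score
    var = np.maximum(var, 1e-12)
    corr = (sub @ U) / np.sqrt(var)  # member x component correlations
    child = np.argmax(corr**2, axis=1)
    if child.min() == child.max():  # degenerate: force a 1-vs-rest split
        j = int(np.argmin(corr[:, child[0]] ** 2))
        child = np.zeros(len(members), dtype=int)
        child[j] = 1
    return members[child == 0], members[child == 1]


def _own_gamma_total(C: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        w, V = _cluster_eigh(C, members)
        corr = _pc_correlations(C, members, V[:, 0], w[0])
        total += float(np.sum(corr[members] ** 2))
    return total


def _reassign(C: np.ndarray, labels: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Nearest-component reassignment to a fixed point.

    Each pass recomputes every cluster's first PC and moves each item to the
    cluster whose PC explains more of its variance.  A pass is accepted only
    if it strictly increases the summed own-cluster explained variance, which
    guarantees monotone convergence (cap ``max_iter`` passes).
    """
    labels = labels.copy()
    obj = _own_gamma_total(C, labels)
    for _ in range(max_iter):
        ks = np.unique(labels)
        gammas = np.empty((C.shape[0], len(ks)))
        for col, k in enumerate(ks):
            members = np.flatnonzero(labels == k)
            w, V = _cluster_eigh(C, members)
            gammas[:, col] = _pc_correlations(C, members, V[:, 0], w[0]) ** 2
        new_labels = ks[np.argmax(gammas, axis=1)]
        if np.array_equal(new_labels, labels):
            break
        if len(np.unique(new_labels)) < len(ks):
            break  # a cluster would empty; keep the current assignment
        new_obj = _own_gamma_total(C, new_labels)
        if new_obj <= obj + 1e-12:
            break
        labels, obj = new_labels, new_obj
    return _canonical_labels(labels)


def split_once(solution: ClusterSolution, c: CorrelationMatrix,
               threshold: float = 1.0) -> ClusterSolution:
    """One divisive step: split the cluster with the largest second eigenvalue.

    If no cluster's second eigenvalue exceeds ``threshold`` the input is
    returned unchanged with ``converged=True``.  Ties on the largest second
    eigenvalue break toward the lowest cluster index.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    second = solution.second_eigenvalues
    candidates = np.flatnonzero(second > threshold)
    if candidates.size == 0:
        return replace(solution, converged=True)
    worst = candidates[np.argmax(second[candidates])]
    # argmax returns the first maximum, which is the lowest cluster index
    members = solution.members(worst)
    left, right = _split_cluster(c.values, members)
    labels = solution.labels.copy()
    new_k = solution.n_clusters
    labels[right] = new_k
    labels = _reassign(c.values, labels)
    return _solution_from_labels(c, labels, converged=False)


def fit_varclus(c: CorrelationMatrix, threshold: float = None,
                target_clusters: int = None) -> ClusterSolution:
    """Run divisive clustering to convergence or to a target cluster count.

    Exactly one of ``threshold`` (stop when every cluster's second eigenvalue
    is at or below it) or ``target_clusters`` (split, largest second
    eigenvalue first, until the count is reached) must be given.  The returned
    solution carries a populated RS-ratio table.
    """
    if (threshold is None) == (target_clusters is None):
        raise ValidationError("give exactly one of threshold / target_clusters")
    solution = _solution_from_labels(c, np.zeros(c.p, dtype=int))
    if target_clusters is not None:
        if not 1 <= target_clusters <= c.p:
            raise ValidationError(
                f"target_clusters must be in 1..{c.p}, got {target_clusters}"
            )
        while solution.n_clusters < target_clusters:
            nxt = split_once(solution, c, threshold=0.0)
            if nxt.converged and nxt.n_clusters == solution.n_clusters:
                # nothing splittable (all singletons / collinear); split a
                # multi-member cluster arbitrarily to honor the target count
                sizes = np.bincount(solution.labels)
                big = int(np.argmax(sizes))
                if sizes[big] < 2:
                    break
                labels = solution.labels.copy()
                members = np.flatnonzero(labels == big)
                labels[members[-1]] = solution.n_clusters
                nxt = _solution_from_labels(c, labels, converged=False)
            solution = nxt
    else:
        for _ in range(c.p):  # at most p-1 splits are possible
            nxt = split_once(solution, c, threshold=threshold)
            if nxt.converged:
                solution = nxt
                break
            solution = nxt
    solution.rs_table = rs_ratio_table(solution, c)
    return solution


def rs_ratio_table(solution: ClusterSolution, c: CorrelationMatrix) -> pd.DataFrame:
    """Per-item gamma, nu and RS ratio against the solution's cluster PCs.

    ``gamma`` is the squared correlation of the item with its own cluster's
    first principal component, ``nu`` the maximum squared correlation with any
    other cluster's first PC (0 by convention when there is a single cluster),
    and ``rs_ratio = (1 - gamma) / (1 - nu)``.
    """
    C = c.values
    ks = solution.n_clusters
    corr = np.empty((C.shape[0], ks))
    for k in range(ks):
        members = solution.members(k)
        corr[:, k] = _pc_correlations(
            C, members, solution.pc_loadings[k], solution.first_eigenvalues[k]
        )
    sq = corr**2
    if np.any(sq > 1 + 1e-8):
        raise ValidationError("explained-variance proportion exceeds 1 beyond tolerance")
    sq = np.clip(sq, 0.0, 1.0)
    gamma = sq[np.arange(C.shape[0]), solution.labels]
    if ks == 1:
        nu = np.zeros(C.shape[0])
    else:
        masked = sq.copy()
        masked[np.arange(C.shape[0]), solution.labels] = -np.inf
        nu = masked.max(axis=1)
    denom = 1.0 - nu
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = np.where(denom > 1e-12, (1.0 - gamma) / np.maximum(denom, 1e-300), np.inf)
    rs = np.where((1.0 - gamma) <= 1e-12, 0.0, rs)  # an item identical to its PC
    return pd.DataFrame(
        {
            "item_id": list(solution.item_ids),
            "cluster": solution.labels,
            "own_variance_explained": gamma,
            "best_foreign_variance_explained": nu,
            "rs_ratio": rs,
        }
    )


@dataclass(frozen=True)
class RepresentativeSet:
    """One representative item per cluster with its selection rationale."""

    item_ids: tuple
    table: pd.DataFrame


def _id_sort_key(item):
    return (0, item) if isinstance(item, (int, float)) else (1, str(item))


def select_representatives(solution: ClusterSolution) -> RepresentativeSet:
    """Pick each cluster's minimum-RS-ratio item (ties: smallest item id)."""
    if solution.rs_table is None:
        raise ValidationError("rs_table not populated; run rs_ratio_table first")
    rows = []
    for k in range(solution.n_clusters):
        sub = solution.rs_table[solution.rs_table["cluster"] == k]
        best = min(
            sub.itertuples(index=False),
            key=lambda row: (row.rs_ratio, _id_sort_key(row.item_id)),
        )
        rows.append(best._asdict() if hasattr(best, "_asdict") else dict(best))
    table = pd.DataFrame(rows)
    return RepresentativeSet(item_ids=tuple(table["item_id"]), table=table)


class VarClus(BaseEstimator):
    """Divisive variable clustering as a scikit-learn style estimator.

    Parameters
    ----------
    n_clusters : int, optional
        Split until exactly this many clusters exist.  Mutually exclusive
        with ``max_second_eigenvalue``-driven stopping: when ``n_clusters``
        is None the algorithm splits while any cluster's second eigenvalue
        exceeds ``max_second_eigenvalue``.
    max_second_eigenvalue : float, default 1.0
        Kaiser-style splitting threshold used when ``n_clusters`` is None.

    Attributes
    ----------
    labels_ : ndarray of shape (p,)
        Cluster index per item (column).
    rs_table_ : DataFrame
        Per-item gamma / nu / RS ratio.
    representatives_ : tuple
        The minimum-RS-ratio item of each cluster.
    """

    def __init__(self, n_clusters: int = None, max_second_eigenvalue: float = 1.0):
        self.n_clusters = n_clusters
        self.max_second_eigenvalue = max_second_eigenvalue

    def fit(self, X, y=None):
        c = self._as_correlation(X)
        if self.n_clusters is not None:
            solution = fit_varclus(c, target_clusters=self.n_clusters)
        else:
            solution = fit_varclus(c, threshold=self.max_second_eigenvalue)
        self.correlation_ = c
        self.solution_ = solution
        self.labels_ = solution.labels
        self.item_ids_ = list(c.item_ids)
        self.rs_table_ = solution.rs_table
        reps = select_representatives(solution)
        self.representatives_ = reps.item_ids
        self.cluster_first_eigenvalues_ = solution.first_eigenvalues
        self.cluster_second_eigenvalues_ = solution.second_eigenvalues
        self.n_clusters_ = solution.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @staticmethod
    def _as_correlation(X) -> CorrelationMatrix:
        if isinstance(X, CorrelationMatrix):
            return X
        if isinstance(X, ResponseMatrix):
            return correlation_matrix(X)
        X = np.asarray(X)
        r = ResponseMatrix(X, [f"v{j + 1}" for j in range(X.shape[1])])
        return correlation_matrix(r)
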