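"""Divisive variable clustering: eigenstructure, splits, RS ratios, recovery."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

import shortscale as ss
from shortscale.core import ValidationError
from shortscale.varclus import CorrelationMatrix


def rs_oracle(values, labels):
    """Independent RS-ratio oracle: compute every cluster's first PC *scores*
    from the standardized raw data by explicit eigendecomposition, then take
    squared Pearson correlations of each item with each score vector."""
    X = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    C = np.corrcoef(values.T)
    ks = np.unique(labels)
    pc_scores = {}
    for k in ks:
        members = np.flatnonzero(labels == k)
        sub = C[np.ix_(members, members)]
        w, V = np.linalg.eigh(sub)
        pc_scores[k] = X[:, members] @ V[:, -1]
    p = values.shape[1]
    gamma = np.empty(p)
    nu = np.empty(p)
    for j in range(p):
        own = labels[j]
        gamma[j] = np.corrcoef(X[:, j], pc_scores[own])[0, 1] ** 2
        others = [np.corrcoef(X[:, j], pc_scores[k])[0, 1] ** 2
                  for k in ks if k != own]
        nu[j] = max(others) if others else 0.0
    return gamma, nu, (1 - gamma) / (1 - nu)


class TestCorrelationMatrix:
    def test_matches_covariance_ratio_oracle(self):
        vals = np.array([[1, 2, 5], [2, 3, 4], [3, 1, 3], [4, 5, 2],
                         [5, 4, 1], [1, 1, 5]])
        r = ss.ResponseMatrix(vals, ["a", "b", "c"])
        C = ss.correlation_matrix(r).values
        # oracle: direct covariance / sqrt(var*var) from raw sums
        n = 6
        for i in range(3):
            for j in range(3):
                xi, xj = vals[:, i].astype(float), vals[:, j].astype(float)
                cov = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (n - 1)
                var_i = np.sum((xi - xi.mean()) ** 2) / (n - 1)
                var_j = np.sum((xj - xj.mean()) ** 2) / (n - 1)
                assert C[i, j] == pytest.approx(cov / np.sqrt(var_i * var_j), abs=1e-12)
        assert np.all(np.diag(C) == 1.0)

    def test_duplicated_columns_give_unit_offdiagonal(self):
        vals = np.array([[1, 1], [3, 3], [5, 5], [2, 2]])
        C = ss.correlation_matrix(ss.ResponseMatrix(vals, ["a", "b"])).values
        assert C[0, 1] == pytest.approx(1.0)

    def test_zero_variance_item_named(self):
        vals = np.array([[1, 2], [1, 3], [1, 4]])
        with pytest.raises(ValidationError, match="'a'"):
            ss.correlation_matrix(ss.ResponseMatrix(vals, ["a", "b"]))


class TestEigendecompose:
    def test_identity(self):
        c = CorrelationMatrix(np.eye(4), ["a", "b", "c", "d"])
        es = ss.eigendecompose(c)
        np.testing.assert_allclose(es.eigenvalues, np.ones(4))

    def test_two_by_two_closed_form(self):
        c = CorrelationMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]), ["a", "b"])
        es = ss.eigendecompose(c)
        np.testing.assert_allclose(es.eigenvalues, [1.6, 0.4], atol=1e-12)

    def test_trace_reconstruction_and_sign(self, bifactor_1200):
        c = ss.correlation_matrix(bifactor_1200)
        es = ss.eigendecompose(c)
        assert es.eigenvalues.sum() == pytest.approx(90, abs=1e-8)
        recon = es.eigenvectors @ np.diag(es.eigenvalues) @ es.eigenvectors.T
        assert np.max(np.abs(recon - c.values)) < 1e-8
        for k in range(90):
            v = es.eigenvectors[:, k]
            assert v[np.argmax(np.abs(v))] > 0


class TestSplitOnce:
    def test_small_second_eigenvalue_is_converged(self):
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        c = CorrelationMatrix(C, ["a", "b"])
        sol = ss.fit_varclus(c, target_clusters=1)
        out = ss.split_once(sol, c, threshold=1.0)
        assert out.converged and out.n_clusters == 1

    def test_planted_pairs_split_matches_brute_force(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.8
        C[2, 3] = C[3, 2] = 0.8
        c = CorrelationMatrix(C, ["a", "b", "c", "d"])
        sol = ss.fit_varclus(c, target_clusters=1)
        out = ss.split_once(sol, c, threshold=1.0)
        assert out.n_clusters == 2
        # brute force: the 2-partition maximizing summed first eigenvalues
        from itertools import combinations
        best, best_val = None, -np.inf
        for size in (1, 2):
            for left in combinations(range(4), size):
                right = tuple(j for j in range(4) if j not in left)
                val = sum(
                    np.linalg.eigvalsh(C[np.ix_(part, part)]).max()
                    for part in (left, right)
                )
                if val > best_val:
                    best, best_val = (set(left), set(right)), val
        found = (set(out.members(0)), set(out.members(1)))
        assert found in (best, (best[1], best[0]))

    def test_threshold_zero_always_splits(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 6, size=(100, 3))
        c = ss.correlation_matrix(ss.ResponseMatrix(vals, ["a", "b", "c"]))
        sol = ss.fit_varclus(c, target_clusters=1)
        out = ss.split_once(sol, c, threshold=0.0)
        assert out.n_clusters == 2


class TestFitVarclus:
    def test_target_p_gives_singletons_with_zero_rs(self, tiny_responses):
        c = ss.correlation_matrix(tiny_responses)
        sol = ss.fit_varclus(c, target_clusters=5)
        assert sol.n_clusters == 5
        np.testing.assert_allclose(
            sol.rs_table["own_variance_explained"], np.ones(5), atol=1e-10
        )
        np.testing.assert_allclose(sol.rs_table["rs_ratio"], np.zeros(5), atol=1e-10)

    def test_single_cluster_uses_nu_zero_convention(self, tiny_responses):
        c = ss.correlation_matrix(tiny_responses)
        sol = ss.fit_varclus(c, target_clusters=1)
        tab = sol.rs_table
        assert np.all(tab["best_foreign_variance_explained"] == 0.0)
        np.testing.assert_allclose(
            tab["rs_ratio"], 1.0 - tab["own_variance_explained"], atol=1e-12
        )

    def test_planted_block_recovery(self, block_responses_5x6):
        spec, r = block_responses_5x6
        c = ss.correlation_matrix(r)
        sol = ss.fit_varclus(c, threshold=1.0)
        assert adjusted_rand_score(spec.assignment, sol.labels) == 1.0

    def test_threshold_convergence_postcondition(self, bifactor_1200):
        c = ss.correlation_matrix(bifactor_1200.subset(list(range(1, 21))))
        sol = ss.fit_varclus(c, threshold=1.0)
        finite = sol.second_eigenvalues[np.isfinite(sol.second_eigenvalues)]
        assert np.all(finite <= 1.0 + 1e-10)

    def test_exchangeable_correlation_single_cluster(self):
        C = np.full((5, 5), 0.5)
        np.fill_diagonal(C, 1.0)
        sol = ss.fit_varclus(CorrelationMatrix(C, list("abcde")), threshold=1.0)
        assert sol.n_clusters == 1  # second eigenvalue 1 - r = 0.5 < 1

    def test_exactly_one_of_modes(self, tiny_responses):
        c = ss.correlation_matrix(tiny_responses)
        with pytest.raises(ValidationError):
            ss.fit_varclus(c)
        with pytest.raises(ValidationError):
            ss.fit_varclus(c, threshold=1.0, target_clusters=2)
        with pytest.raises(ValidationError):
            ss.fit_varclus(c, target_clusters=6)

    def test_permutation_invariance(self, block_responses_5x6):
        spec, r = block_responses_5x6
        rng = np.random.default_rng(8)
        perm = rng.permutation(r.p)
        r2 = ss.ResponseMatrix(r.values[:, perm], [r.item_ids[j] for j in perm])
        sol1 = ss.fit_varclus(ss.correlation_matrix(r), threshold=1.0)
        sol2 = ss.fit_varclus(ss.correlation_matrix(r2), threshold=1.0)
        # same partition up to relabeling, after aligning item order
        lab2 = np.empty(r.p, dtype=int)
        ids2 = {item: sol2.labels[j] for j, item in enumerate(r2.item_ids)}
        for j, item in enumerate(r.item_ids):
            lab2[j] = ids2[item]
        assert adjusted_rand_score(sol1.labels, lab2) == 1.0


class TestSplitPathMonotonicity:
    def test_each_split_adds_one_cluster_and_variance_never_drops(self, bifactor_1200):
        c = ss.correlation_matrix(bifactor_1200.subset(list(range(1, 31))))
        sol = ss.fit_varclus(c, target_clusters=1)
        prev_explained = sol.first_eigenvalues.sum()
        for _ in range(6):
            nxt = ss.split_once(sol, c, threshold=0.0)
            assert nxt.n_clusters == sol.n_clusters + 1
            explained = nxt.first_eigenvalues.sum()
            assert explained >= prev_explained - 1e-10
            sol, prev_explained = nxt, explained


class TestRSRatio:
    def test_matches_independent_oracle(self, block_responses_5x6):
        spec, r = block_responses_5x6
        c = ss.correlation_matrix(r)
        sol = ss.fit_varclus(c, threshold=1.0)
        gamma, nu, rs = rs_oracle(r.values, sol.labels)
        tab = sol.rs_table
        np.testing.assert_allclose(tab["own_variance_explained"], gamma, atol=1e-8)
        np.testing.assert_allclose(tab["best_foreign_variance_explained"], nu, atol=1e-8)
        np.testing.assert_allclose(tab["rs_ratio"], rs, atol=1e-8)


class TestRepresentatives:
    def test_high_loading_item_wins(self):
        # cluster where one item loads 0.9 and five load 0.6 on the factor
        lam = np.array([0.9, 0.6, 0.6, 0.6, 0.6, 0.6])
        C = np.outer(lam, lam)
        np.fill_diagonal(C, 1.0)
        c = CorrelationMatrix(C, [f"i{j}" for j in range(6)])
        sol = ss.fit_varclus(c, target_clusters=1)
        reps = ss.select_representatives(sol)
        assert reps.item_ids == ("i0",)
        # cross-check: the oracle rs ranking also puts i0 first
        assert sol.rs_table.sort_values("rs_ratio").iloc[0]["item_id"] == "i0"

    def test_tie_breaks_to_smallest_id(self):
        vals = np.array([[1, 1], [3, 3], [5, 5], [2, 2], [4, 4]])
        r = ss.ResponseMatrix(vals, [7, 3])
        sol = ss.fit_varclus(ss.correlation_matrix(r), target_clusters=1)
        assert ss.select_representatives(sol).item_ids == (3,)

    def test_one_representative_per_cluster(self, block_responses_5x6):
        spec, r = block_responses_5x6
        sol = ss.fit_varclus(ss.correlation_matrix(r), threshold=1.0)
        reps = ss.select_representatives(sol)
        assert len(reps.item_ids) == sol.n_clusters
        assert len(set(reps.item_ids)) == sol.n_clusters
        assignment = sol.assignment
        clusters = {assignment[i] for i in reps.item_ids}
        assert clusters == set(range(sol.n_clusters))


class TestVarClusEstimator:
    def test_sklearn_protocol(self, block_responses_5x6):
        spec, r = block_responses_5x6
        est = ss.VarClus(n_clusters=5)
        assert clone(est).get_params()["n_clusters"] == 5
        labels = est.fit_predict(r.values)
        assert est.n_clusters_ == 5
        assert adjusted_rand_score(spec.assignment, labels) == 1.0
        assert len(est.representatives_) == 5

    def test_threshold_mode_default(self, block_responses_5x6):
        spec, r = block_responses_5x6
        est = ss.VarClus().fit(r)
        assert est.n_clusters_ == 5
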