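import numpy as np
import pandas as pd
import pytest
from helpers_oracles import brute_force_first_canonical_r
from scipy.optimize import linear_sum_assignment

from connectodyn import (
    bandwise_pca,
    canonical_loadings,
    cca,
    cognitive_factors,
    gen_cognition,
    permutation_test,
    residualize,
    variance_contribution,
    zscore_table,
)
from connectodyn.association import _block_permutation


class TestZscore:
    def test_shift_invariance(self, rng):
        X = rng.standard_normal((50, 4))
        Z1, _ = zscore_table(X)
        Z2, _ = zscore_table(X + 100.0)
        assert np.allclose(Z1, Z2, atol=1e-10)

    def test_columns_standardized_exactly(self, rng):
        Z, _ = zscore_table(rng.standard_normal((200, 5)) * 7 + 3)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        assert np.abs(Z.std(axis=0) - 1.0).max() < 1e-12

    def test_missingness_inclusion_rule(self, rng):
        X = rng.standard_normal((10, 5))
        X[0, :3] = np.nan          # 60% missing -> subject dropped
        X[1:5, 1] = np.nan         # 40% missing column -> retained
        Z, info = zscore_table(X)
        assert list(info["dropped_subjects"]) == [0]
        assert Z.shape == (9, 5)
        assert np.allclose(Z[:4, 1], 0.0)  # mean-imputed after standardization

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, info = zscore_table(X)
        assert Z.shape[1] == 2
        assert list(info["dropped_columns"]) == [1]


class TestBandwisePCA:
    def test_eigenvalues_sum_to_dimension(self, rng):
        Z, _ = zscore_table(rng.standard_normal((300, 7)))
        res = bandwise_pca(Z)
        assert abs(res.eigenvalues.sum() - 7.0) < 1e-8

    def test_single_common_factor_retains_one_pc(self, rng):
        # 6 variables loading 0.9 on one factor: top eigenvalue 1 + 5*0.81,
        # remaining eigenvalues 0.19 << 1
        f = rng.standard_normal(1000)
        X = 0.9 * f[:, None] + np.sqrt(1 - 0.81) * rng.standard_normal((1000, 6))
        Z, _ = zscore_table(X)
        assert bandwise_pca(Z).n_retained == 1

    def test_eigenvectors_orthonormal_and_sign_fixed(self, rng):
        Z, _ = zscore_table(rng.standard_normal((500, 6)))
        res = bandwise_pca(Z)
        C = res.coeffs.T @ res.coeffs
        assert np.allclose(C, np.eye(res.n_retained), atol=1e-10)
        for j in range(res.n_retained):
            assert res.coeffs[np.argmax(np.abs(res.coeffs[:, j])), j] > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bandwise_pca(np.empty((10, 0)))


class TestVarianceContribution:
    def test_single_variable_identical_to_pc_gives_100(self, rng):
        # with one variable the sole PC is that variable itself
        Z, _ = zscore_table(rng.standard_normal((400, 1)))
        res = bandwise_pca(Z)
        contrib = variance_contribution(res.coeffs, res.eigenvalues, [0])
        assert abs(contrib[0] - 100.0) < 1e-9

    def test_completeness_sums_to_100(self, rng):
        Z, _ = zscore_table(rng.standard_normal((300, 5)))
        C = np.corrcoef(Z, rowvar=False)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        contrib = variance_contribution(V[:, order], w[order], [0, 2, 4])
        assert abs(contrib.sum() - 100.0) < 1e-6

    def test_matches_regression_r2_oracle(self, rng):
        Z, _ = zscore_table(rng.standard_normal((400, 4)))
        res = bandwise_pca(Z)
        subset = [1, 3]
        contrib = variance_contribution(res.coeffs, res.eigenvalues, subset)
        scores = res.scores / res.scores.std(axis=0)
        for j in range(res.n_retained):
            r2 = [np.corrcoef(Z[:, i], scores[:, j])[0, 1] ** 2 for i in subset]
            assert abs(contrib[j] - 100.0 * np.mean(r2)) < 1e-6

    def test_empty_subset_rejected(self, rng):
        Z, _ = zscore_table(rng.standard_normal((100, 3)))
        res = bandwise_pca(Z)
        with pytest.raises(ValueError):
            variance_contribution(res.coeffs, res.eigenvalues, [])


class TestCognitiveFactors:
    @pytest.fixture(scope="class")
    def planted_two_factor(self):
        rng = np.random.default_rng(5)
        L = np.zeros((10, 2))
        L[:5, 0], L[5:, 1] = 0.8, 0.7
        F = rng.standard_normal((2000, 2))
        noise = rng.standard_normal((2000, 10)) * np.sqrt(1 - (L ** 2).sum(axis=1))
        Z, _ = zscore_table(F @ L.T + noise)
        return L, cognitive_factors(np.asarray(Z), n_factors=2)

    def test_factor_congruence_with_truth(self, planted_two_factor):
        L, fm = planted_two_factor
        C = np.abs(fm.loadings.T @ L)
        C /= np.linalg.norm(fm.loadings, axis=0)[:, None] * np.linalg.norm(L, axis=0)
        ri, ci = linear_sum_assignment(-C)
        assert (C[ri, ci] >= 0.95).all()

    def test_orthogonal_truth_gives_uncorrelated_factors(self, planted_two_factor):
        _, fm = planted_two_factor
        assert abs(fm.phi[0, 1]) < 0.1

    def test_regression_and_bartlett_scores_agree(self, planted_two_factor):
        _, fm = planted_two_factor
        for j in range(2):
            r = np.corrcoef(fm.scores_regression[:, j], fm.scores_bartlett[:, j])[0, 1]
            assert abs(r) > 0.95

    def test_kaiser_default_factor_count(self, rng):
        f = rng.standard_normal(800)
        X = 0.8 * f[:, None] + 0.6 * rng.standard_normal((800, 6))
        Z, _ = zscore_table(X)
        fm = cognitive_factors(np.asarray(Z))
        assert fm.n_factors == 1


class TestResidualize:
    def test_covariate_equal_column_zeroed(self, rng):
        c = rng.standard_normal(100)
        X = np.column_stack([c, rng.standard_normal(100)])
        R = residualize(X, c)
        assert np.abs(R[:, 0]).max() < 1e-10

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.standard_normal((200, 4))
        C = rng.standard_normal((200, 2))
        R = residualize(X, C)
        assert np.abs(R.T @ C).max() < 1e-8
        assert np.abs(R.sum(axis=0)).max() < 1e-8  # intercept removed

    def test_rank_deficient_covariates_rejected(self, rng):
        C = np.ones((50, 2))
        with pytest.raises(ValueError):
            residualize(rng.standard_normal((50, 2)), C)


class TestCCA:
    def test_duplicate_sets_give_unit_correlations(self, rng):
        U = rng.standard_normal((40, 3))
        res = cca(U, U.copy())
        assert np.allclose(res.r, 1.0, atol=1e-10)

    def test_univariate_case_equals_pearson(self, rng):
        x = rng.standard_normal((60, 1))
        y = 0.5 * x + rng.standard_normal((60, 1))
        r_ref = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert abs(cca(x, y).r[0] - r_ref) < 1e-12

    def test_matches_direct_maximization_oracle(self):
        rng = np.random.default_rng(8)
        U = rng.standard_normal((6, 3))
        V = rng.standard_normal((6, 2))
        res = cca(U, V)
        ref = brute_force_first_canonical_r(U, V)
        assert abs(res.r[0] - ref) < 1e-6

    def test_invariant_to_invertible_mixing(self, rng):
        U = rng.standard_normal((80, 4))
        V = rng.standard_normal((80, 3))
        MU = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        MV = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        r1 = cca(U, V).r
        r2 = cca(U @ MU, V @ MV).r
        assert np.allclose(r1, r2, atol=1e-8)

    def test_correlations_sorted_and_bounded(self, rng):
        res = cca(rng.standard_normal((100, 5)), rng.standard_normal((100, 4)))
        assert np.all(res.r[:-1] >= res.r[1:] - 1e-12)
        assert res.r.min() >= 0.0 and res.r.max() <= 1.0


class TestPermutation:
    def test_p_value_lower_bound(self, rng):
        U = rng.standard_normal((50, 3))
        V = U + 0.01 * rng.standard_normal((50, 3))
        p, _ = permutation_test(U, V, n_perm=200, seed=0)
        assert p.min() >= 1.0 / 201.0

    def test_reproducible_given_seed(self, rng):
        U = rng.standard_normal((60, 3))
        V = rng.standard_normal((60, 2))
        p1, null1 = permutation_test(U, V, n_perm=300, seed=42)
        p2, null2 = permutation_test(U, V, n_perm=300, seed=42)
        assert np.array_equal(p1, p2)
        assert np.array_equal(null1, null2)

    def test_planted_mode_detected(self, rng):
        X = rng.standard_normal((500, 5))
        X = (X - X.mean(0)) / X.std(0)
        M, _ = gen_cognition(X, planted_mode_r=0.5, rng=rng)
        p, _ = permutation_test(X, M, n_perm=500, seed=1)
        assert p[0] < 0.01

    def test_small_n_perm_warns(self, rng):
        U, V = rng.standard_normal((30, 2)), rng.standard_normal((30, 2))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(U, V, n_perm=50, seed=0)

    def test_block_permutation_moves_families_as_units(self):
        labels = np.array([0, 0, 1, 1, 2, 3, 3, 4])
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = _block_permutation(labels, rng)
            assert sorted(perm) == list(range(8))
            # pair slots must receive pairs, singleton slots singletons
            moved = labels[perm]
            for fam in np.unique(labels):
                slots = np.flatnonzero(labels == fam)
                assert len(np.unique(moved[slots])) == 1
                assert (np.bincount(labels)[moved[slots][0]]
                        == len(slots))


class TestCanonicalLoadings:
    def test_self_loading_is_one(self, rng):
        s = rng.standard_normal(100)
        ld = canonical_loadings(s, s[:, None])
        assert abs(ld["r"].iloc[0] - 1.0) < 1e-12

    def test_matches_direct_pearson_formula(self, rng):
        s = rng.standard_normal(150)
        X = rng.standard_normal((150, 4))
        ld = canonical_loadings(s, X)
        for j in range(4):
            assert abs(ld["r"].iloc[j] - np.corrcoef(s, X[:, j])[0, 1]) < 1e-12

    def test_orthogonal_variable_loads_zero(self, rng):
        s = rng.standard_normal(200)
        x = rng.standard_normal(200)
        x = x - (x @ s) / (s @ s) * s
        x -= x.mean()
        s_c = s - s.mean()
        x -= (x @ s_c) / (s_c @ s_c) * s_c
        ld = canonical_loadings(s, x[:, None])
        assert abs(ld["r"].iloc[0]) < 1e-10
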