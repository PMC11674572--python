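import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectodyn import (
    SyntheticConfig,
    cca,
    gen_cognition,
    gen_cohort,
    gen_envelopes,
    gen_state_sequence,
    make_transition_matrix,
)


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        path = gen_state_sequence(np.eye(3), [1.0, 0.0, 0.0], 200, 0)
        assert (path == 0).all()

    def test_uniform_chain_occupancy_converges(self):
        K, T = 4, 50_000
        A = np.full((K, K), 1.0 / K)
        path = gen_state_sequence(A, np.full(K, 1.0 / K), T, 1)
        fo = np.bincount(path, minlength=K) / T
        assert np.abs(fo - 1.0 / K).max() < 0.02

    def test_transition_frequencies_converge_to_chain(self):
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        path = gen_state_sequence(A, [0.5, 0.5], 100_000, 2)
        C = np.zeros((2, 2))
        np.add.at(C, (path[:-1], path[1:]), 1.0)
        emp = C / C.sum(axis=1, keepdims=True)
        assert np.abs(emp - A).max() < 0.01

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            gen_state_sequence(np.array([[0.5, 0.4], [0.2, 0.8]]), [0.5, 0.5], 10, 0)

    @given(k=st.integers(2, 5), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_paths_stay_in_label_set(self, k, seed):
        rng = np.random.default_rng(seed)
        A = rng.dirichlet(np.ones(k), size=k)
        pi = rng.dirichlet(np.ones(k))
        path = gen_state_sequence(A, pi, 500, seed)
        assert path.min() >= 0 and path.max() < k


class TestEnvelopes:
    def test_zero_covariance_reproduces_means(self, rng):
        means = np.array([[1.0, -2.0], [3.0, 0.5]])
        covs = np.zeros((2, 2, 2)) + 1e-30 * np.eye(2)
        path = np.array([0, 1, 1, 0])
        env = gen_envelopes(path, means, covs, rng)
        assert np.allclose(env, means[path], atol=1e-12)

    def test_sample_covariance_recovered(self, rng):
        C = np.array([[2.0, 0.6], [0.6, 1.0]])
        env = gen_envelopes(np.zeros(50_000, dtype=int), np.zeros((1, 2)), C[None], rng)
        S = np.cov(env.T)
        assert np.linalg.norm(S - C) / np.linalg.norm(C) < 0.05

    def test_nearest_mean_classification_recovers_path(self, rng):
        means = np.array([[0.0] * 4, [8.0] * 4])
        covs = np.stack([np.eye(4)] * 2)
        path = np.tile([0, 1], 2_000)
        env = gen_envelopes(path, means, covs, rng)
        d = np.stack([np.linalg.norm(env - m, axis=1) for m in means])
        assert np.mean(d.argmin(axis=0) == path) >= 0.99

    def test_non_pd_covariance_rejected(self, rng):
        bad = -np.eye(2)[None]
        with pytest.raises(ValueError):
            gen_envelopes(np.zeros(5, dtype=int), np.zeros((1, 2)), bad, rng)


class TestCognition:
    @staticmethod
    def _std_features(rng, n, p):
        X = rng.standard_normal((n, p))
        return (X - X.mean(axis=0)) / X.std(axis=0)

    def test_null_construction_uncorrelated(self, rng):
        X = self._std_features(rng, 500, 4)
        M, _ = gen_cognition(X, n_measures=10, planted_mode_r=0.0, rng=rng)
        corr = np.corrcoef(np.hstack([X, M]), rowvar=False)[:4, 4:]
        assert np.abs(corr).max() < 0.2  # consistent with null at n=500

    @pytest.mark.parametrize("r_true", [0.3, 0.5])
    def test_planted_r_recovered_by_sample_cca(self, rng, r_true):
        X = self._std_features(rng, 2_000, 6)
        M, _ = gen_cognition(X, planted_mode_r=r_true, rng=rng)
        assert abs(cca(X, M).r[0] - r_true) < 0.05

    def test_noiseless_single_indicator_carries_link_exactly(self, rng):
        X = self._std_features(rng, 300, 3)
        L = np.zeros((5, 1))
        L[0, 0] = 1.0
        M, truth = gen_cognition(X, planted_mode_r=0.7, noise_sd=0.0,
                                 loadings=L, rng=rng)
        # degenerate emission: measure 1 IS the latent factor, which carries
        # the planted combination at the calibrated strength alpha = r
        assert np.allclose(M[:, 0], truth["factors"][:, 0])
        assert abs(truth["alpha"] - 0.7) < 1e-12
        r = np.corrcoef(M[:, 0], truth["planted_s"])[0, 1]
        assert abs(r - 0.7) < 0.1  # sample correlation at n = 300

    def test_unreachable_mode_rejected(self, rng):
        X = self._std_features(rng, 100, 3)
        weak = np.full((6, 2), 0.1)
        with pytest.raises(ValueError, match="unreachable"):
            gen_cognition(X, planted_mode_r=0.9, noise_sd=2.0, loadings=weak, rng=rng)

    def test_planted_r_out_of_range_rejected(self, rng):
        X = self._std_features(rng, 50, 2)
        with pytest.raises(ValueError):
            gen_cognition(X, planted_mode_r=1.0, rng=rng)


class TestCohort:
    @staticmethod
    def _tiny_config(**kw):
        base = dict(n_subjects=10, n_regions=5, K=3, T=300,
                    bands=(("alpha", 8.0, 12.0),), separation=3.0,
                    planted_mode_r=0.3, seed=7)
        base.update(kw)
        return SyntheticConfig(**base)

    def test_same_seed_reproduces_cohort_exactly(self):
        a = gen_cohort(self._tiny_config())
        b = gen_cohort(self._tiny_config())
        assert np.array_equal(a.truth.state_paths["alpha"], b.truth.state_paths["alpha"])
        assert np.array_equal(a.envelopes["alpha"][0], b.envelopes["alpha"][0])
        assert a.cognition.equals(b.cognition)
        assert a.covariates.equals(b.covariates)

    def test_pair_fraction_zero_gives_unique_families(self):
        coh = gen_cohort(self._tiny_config(pair_fraction=0.0), make_envelopes=False)
        labels = coh.truth.pair_labels
        assert len(np.unique(labels)) == len(labels)

    def test_family_ids_occur_at_most_twice(self):
        coh = gen_cohort(self._tiny_config(pair_fraction=1.0), make_envelopes=False)
        _, counts = np.unique(coh.truth.pair_labels, return_counts=True)
        assert counts.max() <= 2
        assert (counts == 2).sum() == 5  # all 10 subjects paired

    def test_truth_matrices_are_stochastic(self):
        coh = gen_cohort(self._tiny_config(), make_envelopes=False)
        fo = coh.truth.true_fo["alpha"]
        tp = coh.truth.true_tp["alpha"]
        assert np.allclose(fo.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fo >= 0)
        assert np.allclose(tp.sum(axis=2), 1.0, atol=1e-9)

    def test_twins_share_sex_and_age(self):
        coh = gen_cohort(self._tiny_config(pair_fraction=1.0), make_envelopes=False)
        cov = coh.covariates
        for fam, grp in cov.groupby("family"):
            assert grp["sex"].nunique() == 1
            assert grp["age"].nunique() == 1
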