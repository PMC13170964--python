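import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln
from sklearn.metrics import adjusted_rand_score

from celladapt import (
    ClusterState,
    NIWPrior,
    adapt_clusters,
    fit_subclusters,
    init_gmm,
    log_marginal_likelihood,
    merge_log_ratio,
    simulate_gaussian_clusters,
    split_log_ratio,
    split_merge_epoch,
)


class TestNIWPrior:
    def test_defaults_from_data(self):
        Z = np.random.default_rng(0).normal(size=(50, 3))
        prior = NIWPrior.from_data(Z, initial_clusters=4)
        np.testing.assert_allclose(prior.m, Z.mean(0))
        np.testing.assert_allclose(prior.psi, 0.005 * np.eye(3))
        assert prior.kappa == 1e-4
        assert prior.nu == 6  # K + 2 with K = 4 (> dim + 1)

    def test_nu_floor_in_high_dim(self):
        Z = np.random.default_rng(0).normal(size=(100, 64))
        prior = NIWPrior.from_data(Z, initial_clusters=4)
        assert prior.nu >= 65  # multivariate gamma requires nu > dim - 1

    def test_invalid_nu_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            NIWPrior(nu=1.0, kappa=1.0, m=np.zeros(3), psi=np.eye(3))


class TestMarginalLikelihood:
    def test_empty_set_is_zero(self):
        prior = NIWPrior(nu=3.0, kappa=1.0, m=np.zeros(1), psi=np.eye(1))
        assert log_marginal_likelihood(np.empty((0, 1)), prior) == 0.0

    def test_single_point_matches_numeric_integration(self):
        """1-D, k=1: closed form equals the integral over the conjugate prior.

        The NIW in one dimension factorizes as
        N(mu | m, s2/kappa) * InvGamma(s2 | nu/2, psi/2), so the marginal of
        one observation is
        int InvGamma(s2) N(x | m, s2 (1 + 1/kappa)) ds2.
        """
        nu, kappa, m, psi, x = 3.2, 0.8, 0.3, 0.7, 0.9
        prior = NIWPrior(nu=nu, kappa=kappa, m=np.array([m]), psi=np.array([[psi]]))
        lm = log_marginal_likelihood(np.array([[x]]), prior)
        f = lambda s2: stats.invgamma.pdf(s2, a=nu / 2, scale=psi / 2) * \
            stats.norm.pdf(x, m, np.sqrt(s2 * (1 + 1 / kappa)))
        val, err = integrate.quad(f, 0, np.inf, limit=200)
        assert lm == pytest.approx(np.log(val), rel=1e-4)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(10, 2))
        shift = np.array([5.0, -3.0])
        p1 = NIWPrior(nu=5.0, kappa=0.1, m=np.zeros(2), psi=np.eye(2))
        p2 = NIWPrior(nu=5.0, kappa=0.1, m=shift, psi=np.eye(2))
        assert log_marginal_likelihood(Z, p1) == pytest.approx(
            log_marginal_likelihood(Z + shift, p2), rel=1e-12
        )


class TestHastingsRatios:
    def prior_for(self, Z, K=4):
        return NIWPrior.from_data(Z, K)

    def test_split_favored_for_two_separated_blobs(self):
        X, y = simulate_gaussian_clusters(2, 40, 2, 25.0, seed=0)
        prior = self.prior_for(X)
        assert split_log_ratio(X, X[y == 0], X[y == 1], prior) > 0

    def test_split_disfavored_for_single_blob(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 2))
        prior = self.prior_for(X)
        half = rng.permutation(80)
        assert split_log_ratio(X, X[half[:40]], X[half[40:]], prior) < 0

    def test_merge_favored_for_one_common_blob(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        prior = self.prior_for(X)
        assert merge_log_ratio(X[:30], X[30:], prior) > 0

    def test_merge_disfavored_for_separated_blobs(self):
        X, y = simulate_gaussian_clusters(2, 40, 2, 25.0, seed=4)
        prior = self.prior_for(X)
        assert merge_log_ratio(X[y == 0], X[y == 1], prior) < 0

    def test_log_space_matches_naive_arithmetic_on_toy(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(6, 1))
        prior = NIWPrior(nu=3.0, kappa=0.5, m=np.zeros(1), psi=np.eye(1))
        log_h = split_log_ratio(Z, Z[:2], Z[2:], prior)
        naive = (
            math.factorial(1) * math.factorial(3)
            / math.factorial(5)
            * np.exp(log_marginal_likelihood(Z[:2], prior))
            * np.exp(log_marginal_likelihood(Z[2:], prior))
            / np.exp(log_marginal_likelihood(Z, prior))
        )
        assert log_h == pytest.approx(np.log(naive), abs=1e-9)

    def test_merge_is_inverse_of_split_on_random_partitions(self):
        """H_merge(i,j) * H_split(union -> (i,j)) == 1 in log-space."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = rng.integers(4, 40)
            d = rng.integers(1, 5)
            Z = rng.normal(scale=rng.uniform(0.5, 3.0), size=(n, d))
            cut = rng.integers(1, n)
            prior = NIWPrior.from_data(Z, 3)
            ls = split_log_ratio(Z, Z[:cut], Z[cut:], prior)
            lm = merge_log_ratio(Z[:cut], Z[cut:], prior)
            assert ls + lm == pytest.approx(0.0, abs=1e-9)

    def test_log_gamma_path_matches_factorials(self):
        for n in range(1, 21):
            assert gammaln(n) == pytest.approx(
                np.log(float(math.factorial(n - 1))), rel=1e-12
            )


class TestGmmInit:
    def test_separable_blobs_recovered(self):
        X, y = simulate_gaussian_clusters(3, 60, 2, 20.0, seed=0)
        state = init_gmm(X, 3, seed=0)
        assert adjusted_rand_score(y, state.assignments) == 1.0

    def test_single_component(self):
        X, _ = simulate_gaussian_clusters(2, 20, 2, 10.0, seed=1)
        state = init_gmm(X, 1, seed=0)
        assert state.C == 1
        assert set(state.assignments) == {0}

    def test_deterministic(self):
        X, _ = simulate_gaussian_clusters(3, 30, 2, 8.0, seed=2)
        a = init_gmm(X, 4, seed=7)
        b = init_gmm(X, 4, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            init_gmm(np.ones((2, 2)), 3, seed=0)


class TestSubclusters:
    def test_two_blob_cluster_subdivided(self):
        X, y = simulate_gaussian_clusters(2, 40, 2, 20.0, seed=3)
        state = init_gmm(X, 1, seed=0)
        state = fit_subclusters(X, state, seed=0)
        sub = state.sub_assignments
        assert adjusted_rand_score(y, sub) == 1.0
        assert 0 not in state.split_exempt

    def test_tiny_cluster_exempt(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        state = ClusterState(
            assignments=np.zeros(2, dtype=int),
            sub_assignments=np.ones(2, dtype=int),
            C=1, centroids=X.mean(0, keepdims=True),
        )
        out = fit_subclusters(X, state, seed=0)
        assert set(out.sub_assignments) == {1}
        assert 0 in out.split_exempt

    def test_deterministic(self):
        X, _ = simulate_gaussian_clusters(2, 30, 3, 10.0, seed=4)
        st = init_gmm(X, 2, seed=0)
        a = fit_subclusters(X, st, seed=5)
        b = fit_subclusters(X, st, seed=5)
        np.testing.assert_array_equal(a.sub_assignments, b.sub_assignments)


class TestSplitMergeEpoch:
    def test_under_split_state_splits_to_truth(self):
        # two clusters, each holding two separable blobs: one epoch of
        # split moves must cut both, giving C = 4
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [0, 20], [60, 0], [60, 20]], dtype=float)
        X = np.vstack([c + rng.normal(size=(40, 2)) for c in centers])
        assignments = np.repeat([0, 0, 1, 1], 40)
        state = ClusterState(
            assignments=assignments,
            sub_assignments=np.ones(len(X), dtype=int),
            C=2,
            centroids=np.vstack([X[assignments == c].mean(0) for c in (0, 1)]),
        )
        prior = NIWPrior.from_data(X, 2)
        state = fit_subclusters(X, state, seed=0)
        out = split_merge_epoch(X, state, prior, seed=0)
        assert out.C == 4

    def test_over_split_state_merges_to_truth(self):
        X, y = simulate_gaussian_clusters(3, 80, 2, 20.0, seed=6)
        state = adapt_clusters(X, 6, seed=0, max_rounds=3)
        assert state.C == 3

    def test_single_blob_is_fixed_point(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 2))
        state = adapt_clusters(X, 1, seed=0)
        assert state.C == 1

    def test_membership_conserved_no_empty_clusters(self):
        X, _ = simulate_gaussian_clusters(4, 50, 3, 12.0, seed=8)
        state = init_gmm(X, 5, seed=0)
        prior = NIWPrior.from_data(X, 5)
        for r in range(4):
            state = fit_subclusters(X, state, seed=r)
            state = split_merge_epoch(X, state, prior, seed=r)
            state.validate()
            assert len(state.assignments) == len(X)

    def test_cluster_number_recovery_across_inits_and_seeds(self):
        X, _ = simulate_gaussian_clusters(4, 100, 2, 12.0, seed=0)
        for C0 in range(2, 9):
            for seed in range(3):
                final = adapt_clusters(X, C0, seed=seed)
                assert final.C == 4, (C0, seed)

    def test_mh_policy_runs_and_conserves(self):
        X, _ = simulate_gaussian_clusters(3, 40, 2, 15.0, seed=9)
        state = adapt_clusters(X, 5, policy="mh", seed=0, max_rounds=4)
        state.validate()
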