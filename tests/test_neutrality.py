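"""Gaussian KL distance to neutrality and the neutral covariance test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochglv import (
    AbundanceSeries,
    GaussianSummary,
    gaussian_summary,
    kl_divergence_gaussian,
    kl_neutrality,
    neutral_covariance_test,
    neutral_projection,
    wright_fisher_simulate,
)


def make_series(values):
    values = np.asarray(values, dtype=float)
    return AbundanceSeries(times=np.arange(values.shape[0], dtype=float), values=values)


class TestGaussianSummary:
    def test_perfectly_correlated_species_attain_correlation_bound(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(5, 1, 100))
        summ = gaussian_summary(make_series(np.column_stack([x, 3 * x])))
        K = summ.covariance
        assert np.isclose(K[0, 1], np.sqrt(K[0, 0] * K[1, 1]), rtol=1e-9)

    def test_independent_species_have_vanishing_covariance(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(10, 1, (4000, 2)))
        summ = gaussian_summary(make_series(vals))
        se = 1.0 / np.sqrt(4000)  # sd of sample correlation under independence
        corr = summ.covariance[0, 1] / np.sqrt(summ.covariance[0, 0] * summ.covariance[1, 1])
        assert abs(corr) < 3 * se

    def test_constant_series_gives_zero_covariance(self):
        summ = gaussian_summary(make_series(np.ones((10, 3)) * [1.0, 2.0, 3.0]))
        assert np.allclose(summ.covariance, 0.0)
        assert np.allclose(summ.mean, [1.0, 2.0, 3.0])


class TestNeutralProjection:
    def test_hand_computed_two_species_case(self):
        summ = GaussianSummary(mean=np.array([1.0, 3.0]),
                               covariance=np.array([[2.0, 0.5], [0.5, 4.0]]))
        proj = neutral_projection(summ)
        assert np.allclose(proj.mean, [2.0, 2.0])
        assert np.allclose(np.diag(proj.covariance), [3.0, 3.0])
        assert np.isclose(proj.covariance[0, 1], 0.5)

    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_and_permutation_invariant(self, S, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(S, S))
        summ = GaussianSummary(mean=rng.normal(size=S), covariance=A @ A.T)
        proj = neutral_projection(summ)
        again = neutral_projection(proj)
        assert np.allclose(proj.mean, again.mean)
        assert np.allclose(proj.covariance, again.covariance)
        perm = rng.permutation(S)
        permuted = GaussianSummary(mean=summ.mean[perm],
                                   covariance=summ.covariance[np.ix_(perm, perm)])
        proj_p = neutral_projection(permuted)
        assert np.allclose(proj.mean, proj_p.mean)
        assert np.allclose(proj.covariance, proj_p.covariance)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            neutral_projection(GaussianSummary(mean=np.array([1.0]),
                                               covariance=np.array([[1.0]])))


class TestKLDivergence:
    def test_identical_distributions_give_zero(self):
        summ = GaussianSummary(mean=np.array([1.0, 2.0]),
                               covariance=np.array([[2.0, 0.3], [0.3, 1.0]]))
        assert kl_divergence_gaussian(summ, summ) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form(self):
        P = GaussianSummary(mean=np.array([0.0]), covariance=np.array([[1.0]]))
        Q = GaussianSummary(mean=np.array([1.0]), covariance=np.array([[1.0]]))
        assert kl_divergence_gaussian(P, Q, regularization=0.0) == pytest.approx(0.5, abs=1e-12)

    def test_diagonal_case_separates_into_scalar_terms(self):
        def scalar_kl(mp, vp, mq, vq):
            return 0.5 * (np.log(vq / vp) - 1 + vp / vq + (mq - mp) ** 2 / vq)

        P = GaussianSummary(mean=np.array([0.0, 1.0]), covariance=np.diag([1.0, 2.0]))
        Q = GaussianSummary(mean=np.array([0.5, 0.0]), covariance=np.diag([2.0, 1.0]))
        expected = scalar_kl(0.0, 1.0, 0.5, 2.0) + scalar_kl(1.0, 2.0, 0.0, 1.0)
        assert kl_divergence_gaussian(P, Q, regularization=0.0) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(min_value=1, max_value=4), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_nonnegative_for_random_gaussians(self, n, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.normal(size=(n, n)), rng.normal(size=(n, n))
        P = GaussianSummary(mean=rng.normal(size=n), covariance=A @ A.T + 0.1 * np.eye(n))
        Q = GaussianSummary(mean=rng.normal(size=n), covariance=B @ B.T + 0.1 * np.eye(n))
        assert kl_divergence_gaussian(P, Q) >= 0.0


class TestKLNeutrality:
    def test_exchangeable_series_approaches_zero_with_length(self):
        rng = np.random.default_rng(3)
        vals = {}
        for T in (200, 5000):
            vals[T] = kl_neutrality(make_series(np.abs(rng.normal(10, 1, (T, 5)))))
        assert vals[5000] < vals[200]
        assert vals[5000] < 0.05

    def test_heterogeneous_community_is_far_from_neutral(self, logistic_series):
        series, _, _ = logistic_series
        assert kl_neutrality(series) > 10.0

    def test_duplicating_species_roughly_doubles_divergence(self):
        # adding an independent, statistically identical copy of every species
        # leaves the neutral projection unchanged and doubles the divergence
        rng = np.random.default_rng(4)
        mu, sd = [5.0, 20.0, 60.0], [1.0, 3.0, 8.0]
        base = np.abs(rng.normal(mu, sd, (3000, 3)))
        twins = np.abs(rng.normal(mu, sd, (3000, 3)))
        d1 = kl_neutrality(make_series(base))
        d2 = kl_neutrality(make_series(np.column_stack([base, twins])))
        assert d2 == pytest.approx(2 * d1, rel=0.1)

    def test_matches_direct_formula_evaluation(self):
        # independent dense evaluation of the closed form on the same summary
        rng = np.random.default_rng(10)
        vals = np.abs(rng.normal([5.0, 20.0, 60.0, 10.0], 2.0, (500, 4)))
        series = make_series(vals)
        P = gaussian_summary(series)
        Q = neutral_projection(P)
        n = 4
        direct = 0.5 * (np.log(np.linalg.det(Q.covariance) / np.linalg.det(P.covariance))
                        - n + np.trace(np.linalg.solve(Q.covariance, P.covariance))
                        + (Q.mean - P.mean) @ np.linalg.solve(Q.covariance, Q.mean - P.mean))
        assert kl_neutrality(series) == pytest.approx(direct, rel=1e-6)


class TestNeutralCovarianceTest:
    def test_wright_fisher_frequencies_are_valid(self):
        rng = np.random.default_rng(5)
        f = wright_fisher_simulate(np.full(10, 0.1), 50, 1000, rng, n_replicates=3)
        assert f.shape == (3, 51, 10)
        assert np.allclose(f.sum(axis=2), 1.0)
        assert np.all((f >= 0) & (f <= 1))

    def test_neutral_data_is_not_systematically_rejected(self):
        rng = np.random.default_rng(6)
        f0 = rng.dirichlet(np.ones(12) * 3)
        pvals = []
        for k in range(25):
            f = wright_fisher_simulate(f0, 99, 2000, rng)[0]
            pvals.append(neutral_covariance_test(make_series(f), n_null=49, seed=100 + k))
        assert np.mean(pvals) > 0.25
        assert np.mean(np.array(pvals) < 0.05) < 0.25

    def test_niche_structured_series_is_rejected(self, logistic_series):
        series, _, _ = logistic_series
        p = neutral_covariance_test(series, n_null=99, seed=0)
        assert p < 0.05

    def test_too_few_species_rejected(self):
        rng = np.random.default_rng(7)
        vals = np.abs(rng.normal(5, 1, (50, 2)))
        with pytest.raises(ValueError):
            neutral_covariance_test(make_series(vals), seed=0)
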