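import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from deersurvey import (
    CountMatrix,
    ModelSpec,
    candidate_model_set,
    fit_nmix,
    nmix_density_estimate,
    select_by_aic,
    site_abundance_posterior,
    site_marginal_loglik,
)
from deersurvey.nmixture import NMixFit, SiteAbundancePosterior

# Independent oracle: direct summation with scipy pmfs (no log-space tricks)


def brute_marginal(counts, lam, p, K):
    counts = np.asarray(counts)
    p = np.broadcast_to(np.asarray(p, float), counts.shape)
    total = 0.0
    for N in range(int(counts.max()), K + 1):
        term = stats.poisson.pmf(N, lam)
        for c, pj in zip(counts, p):
            term *= stats.binom.pmf(c, N, pj)
        total += term
    return np.log(total)


def brute_posterior(counts, lam, p, K):
    w = np.zeros(K + 1)
    for N in range(K + 1):
        term = stats.poisson.pmf(N, lam)
        for c in counts:
            term *= stats.binom.pmf(c, N, p)
        w[N] = term
    return w / w.sum()


class TestSiteMarginalLoglik:
    def test_poisson_thinning_closed_form(self):
        # C ~ Poisson(lambda p): log f(1; lam=2, p=.5) = log Pois(1; 1) = -1
        assert site_marginal_loglik([1], 2.0, 0.5, 500) == pytest.approx(-1.0, abs=1e-10)

    def test_zero_count_closed_form(self):
        # Pois(0; lam p) = exp(-0.5)
        assert site_marginal_loglik([0], 1.0, 0.5, 500) == pytest.approx(-0.5, abs=1e-10)

    def test_matches_frozen_brute_force_value(self):
        # brute-force summation over N = 2..50, computed with scipy pmfs
        got = site_marginal_loglik([1, 2], 3.0, 0.4, 50)
        assert got == pytest.approx(-2.550690825626698, abs=1e-12)

    def test_k_below_max_count_errors(self):
        with pytest.raises(ValueError, match="K"):
            site_marginal_loglik([5], 2.0, 0.5, 3)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            site_marginal_loglik([-1], 2.0, 0.5, 50)

    def test_k_stability(self):
        # increasing K beyond lam + 10 sqrt(lam) + max count changes nothing
        lam, counts = 6.0, [3, 1, 2]
        K0 = int(lam + 10 * np.sqrt(lam)) + 3
        base = site_marginal_loglik(counts, lam, 0.45, K0)
        for K in (K0 + 50, K0 + 200):
            assert abs(site_marginal_loglik(counts, lam, 0.45, K) - base) < 1e-8

    def test_occasion_varying_detection(self):
        got = site_marginal_loglik([2, 0, 1], 4.0, [0.3, 0.5, 0.7], 60)
        want = brute_marginal([2, 0, 1], 4.0, [0.3, 0.5, 0.7], 60)
        assert got == pytest.approx(want, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        lam=st.floats(0.2, 15.0),
        p=st.floats(0.05, 0.95),
        counts=st.lists(st.integers(0, 8), min_size=1, max_size=5),
    )
    def test_agrees_with_enumeration_oracle(self, lam, p, counts):
        K = max(counts) + 60
        got = site_marginal_loglik(counts, lam, p, K)
        assert got == pytest.approx(brute_marginal(counts, lam, p, K), abs=1e-12)


class TestFitNmix:
    def test_intercept_only_matches_grid_search_oracle(self, toy_counts, toy_covariates):
        # oracle: dense coarse-to-fine grid over (lambda, p), final step 5e-5,
        # on the brute-force likelihood; optimum lambda=1.82125, p=0.36605
        fit = fit_nmix(toy_counts, toy_covariates, ModelSpec(), K=50)
        lam = np.exp(fit.beta[0])
        p = 1 / (1 + np.exp(-fit.alpha[0]))
        assert lam == pytest.approx(1.82125, abs=1e-3)
        assert p == pytest.approx(0.36605, abs=1e-3)

    def test_aic_satisfies_definition(self, toy_counts, toy_covariates):
        fit = fit_nmix(toy_counts, toy_covariates, ModelSpec(), K=50)
        assert fit.aic == pytest.approx(2 * fit.n_coef - 2 * fit.loglik, abs=1e-9)

    def test_all_zero_counts_flagged_not_crashed(self, toy_covariates):
        cm = CountMatrix(["A", "B", "C"],
                         [dt.date(2018, 1, 1), dt.date(2018, 1, 2)],
                         np.zeros((3, 2)))
        fit = fit_nmix(cm, toy_covariates, ModelSpec(), K=50)
        assert not fit.converged

    def test_k_defaults_to_max_count_plus_100(self, toy_counts, toy_covariates):
        fit = fit_nmix(toy_counts, toy_covariates, ModelSpec())
        assert fit.K == toy_counts.max_count() + 100

    def test_loglik_stable_in_k(self, toy_counts, toy_covariates):
        f1 = fit_nmix(toy_counts, toy_covariates, ModelSpec(), K=60)
        f2 = fit_nmix(toy_counts, toy_covariates, ModelSpec(), K=200)
        assert abs(f1.loglik - f2.loglik) < 1e-6

    def test_unknown_predictor_errors(self, toy_counts, toy_covariates):
        with pytest.raises(ValueError, match="unknown predictor"):
            fit_nmix(toy_counts, toy_covariates, ModelSpec(abundance=("bogus",)))


class TestCandidateModelSet:
    def test_four_predictors_with_null(self):
        specs = candidate_model_set(["elevation", "slope", "aspect_ns", "dist_edge"])
        assert len(specs) == 101  # (C(4,1)+C(4,2))^2 + null
        assert specs[0] == ModelSpec((), ())
        assert len(set(specs)) == 101

    def test_one_predictor_with_null(self):
        assert len(candidate_model_set(["elevation"])) == 2

    def test_two_predictors_no_null(self):
        assert len(candidate_model_set(["a", "b"], include_null=False)) == 9

    def test_duplicate_names_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            candidate_model_set(["a", "a"])

    def test_deterministic_ordering(self):
        a = candidate_model_set(["x", "y", "z"])
        b = candidate_model_set(["z", "y", "x"])
        assert a == b


def _fake_fit(loglik, n_pred, label="m"):
    k = 2 + n_pred
    spec = ModelSpec(tuple(f"{label}{i}" for i in range(min(n_pred, 2))), ())
    return NMixFit(
        spec=spec, link="logit", coef_names=[], beta=np.zeros(1 + min(n_pred, 2)),
        alpha=np.zeros(k - 1 - min(n_pred, 2)), se=np.zeros(k), z=np.zeros(k),
        p_values=np.zeros(k), loglik=loglik, K=50, converged=True,
        site_ids=[], lambda_hat=np.zeros(1), p_hat=np.zeros(1), max_count=1,
    )


class TestSelectByAic:
    def test_minimum_aic_selected_with_delta(self):
        f1 = _fake_fit(-100.0, 1, "a")   # AIC 206.0
        f2 = _fake_fit(-101.15, 2, "b")  # AIC 210.3
        best, table = select_by_aic([f2, f1])
        assert best is f1
        assert table["aic"].iloc[0] == pytest.approx(206.0)
        assert table["delta_aic"].iloc[1] == pytest.approx(4.3)

    def test_tie_broken_by_fewer_coefficients(self):
        f3 = _fake_fit(-100.0, 1, "a")  # 3 coefs, AIC 206
        f4 = _fake_fit(-99.0, 2, "b")   # 4 coefs, AIC 206
        best, _ = select_by_aic([f4, f3])
        assert best is f3

    def test_no_converged_fits_errors(self):
        f = _fake_fit(-10.0, 1)
        f.converged = False
        with pytest.raises(ValueError, match="converged"):
            select_by_aic([f])


def _manual_fit(counts, lam, p, K=120):
    n = counts.n_sites
    return NMixFit(
        spec=ModelSpec(), link="logit", coef_names=[], beta=np.array([np.log(lam)]),
        alpha=np.array([0.0]), se=np.zeros(2), z=np.zeros(2), p_values=np.zeros(2),
        loglik=0.0, K=K, converged=True, site_ids=list(counts.site_ids),
        lambda_hat=np.full(n, lam), p_hat=np.full(n, p),
        max_count=counts.max_count(),
    )


class TestSiteAbundancePosterior:
    def test_perfect_detection_is_point_mass(self):
        cm = CountMatrix(["A"], [dt.date(2018, 1, 1), dt.date(2018, 1, 2)],
                         np.array([[3.0, 3.0]]))
        post = site_abundance_posterior(_manual_fit(cm, lam=3.0, p=1.0), cm)[0]
        assert post.pmf[3] == pytest.approx(1.0, abs=1e-12)
        assert post.bup == pytest.approx(3.0)
        assert (post.ci_low, post.ci_high) == (3, 3)

    def test_zero_count_thinning_complement(self):
        # posterior of N given c=0 is Poisson(lam (1-p)): mean 2 * 0.5 = 1
        cm = CountMatrix(["A", "B"], [dt.date(2018, 1, 1)], np.zeros((2, 1)))
        post = site_abundance_posterior(_manual_fit(cm, lam=2.0, p=0.5), cm)[0]
        assert post.bup == pytest.approx(1.0, abs=1e-10)
        want = stats.poisson.pmf(np.arange(post.support.size), 1.0)
        np.testing.assert_allclose(post.pmf, want, atol=1e-10)

    def test_pmf_zero_below_max_count(self):
        cm = CountMatrix(["A"], [dt.date(2018, 1, 1), dt.date(2018, 1, 2)],
                         np.array([[4.0, 2.0]]))
        post = site_abundance_posterior(_manual_fit(cm, lam=3.0, p=0.5), cm)[0]
        assert (post.pmf[:4] == 0).all()
        assert post.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        lam=st.floats(0.5, 10.0),
        p=st.floats(0.1, 0.9),
        counts=st.lists(st.integers(0, 6), min_size=1, max_size=4),
    )
    def test_agrees_with_enumeration_oracle(self, lam, p, counts):
        K = max(counts) + 60
        cm = CountMatrix(
            ["A"],
            [dt.date(2018, 1, 1) + dt.timedelta(days=j) for j in range(len(counts))],
            np.array([counts], dtype=float),
        )
        post = site_abundance_posterior(_manual_fit(cm, lam, p, K=K), cm)[0]
        np.testing.assert_allclose(post.pmf, brute_posterior(counts, lam, p, K),
                                   atol=1e-12)


def _point_mass(site, n, K=40):
    pmf = np.zeros(K + 1)
    pmf[n] = 1.0
    return SiteAbundancePosterior(site_id=site, support=np.arange(K + 1), pmf=pmf,
                                  bup=float(n), ci_low=n, ci_high=n)


class TestNmixDensityEstimate:
    def test_hand_arithmetic(self):
        posts = [_point_mass(f"S{i}", 10) for i in range(22)]
        est = nmix_density_estimate(posts, 10.24, n_draws=100, seed=0)
        assert est.density == pytest.approx(21.484375)

    def test_point_masses_give_zero_width(self):
        posts = [_point_mass(f"S{i}", 5) for i in range(4)]
        est = nmix_density_estimate(posts, 2.0, n_draws=500, seed=1)
        assert est.ci_low == est.ci_high == est.density == pytest.approx(10.0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        posts = []
        for i in range(6):
            w = rng.dirichlet(np.ones(12))
            pmf = np.zeros(41)
            pmf[:12] = w
            bup = float(np.dot(np.arange(41), pmf))
            posts.append(SiteAbundancePosterior(f"S{i}", np.arange(41), pmf, bup, 0, 11))
        a = nmix_density_estimate(posts, 3.0, n_draws=2000, seed=9)
        b = nmix_density_estimate(posts, 3.0, n_draws=2000, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
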