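"""Shrinkage estimator, MSE-minimizing grid search, jackknife SE."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groupslope import (
    DegenerateVarianceError,
    GridSpec,
    GroupedData,
    InvalidPriorError,
    PriorParams,
    RBOptions,
    bayes_estimate,
    compute_sufficient_stats,
    estimated_mse,
    grid_search_prior,
    jackknife_se,
    lambda_weight,
    ml_estimate,
    ml_result,
    regularized_bayes,
)
from groupslope.regularize import _grid_axes, project_plugin_slope
from conftest import make_dataset


class TestLambdaWeight:
    def test_ml_special_case(self):
        assert lambda_weight(0.0, 10) == 1.0

    def test_limit_large_J(self):
        assert abs(lambda_weight(3.0, 10**6) - 1.0) < 1e-4

    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            lambda_weight(-0.1, 10)

    @given(eps1=st.floats(min_value=0.0, max_value=50.0),
           eps2=st.floats(min_value=0.0, max_value=50.0),
           J=st.integers(min_value=2, max_value=1000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, eps1, eps2, J):
        lo, hi = sorted((eps1, eps2))
        l_lo, l_hi = lambda_weight(lo, J), lambda_weight(hi, J)
        assert 0.0 < l_hi <= l_lo <= 1.0

    def test_formula_oracle(self):
        # direct evaluation of the posterior-weight form at mid-range eps
        assert lambda_weight(2.5, 10) == pytest.approx(10 / (10 + 5.0))


class TestBayesEstimate:
    def test_ml_special_case_identity(self, small_random_data):
        st_ = compute_sufficient_stats(small_random_data)
        prior = PriorParams.ml_special(st_.J)
        assert bayes_estimate(st_, prior) == ml_estimate(st_)

    def test_ml_identity_many_datasets(self):
        for seed in range(30):
            d = make_dataset(icc_x=0.1, J=6, n=4, seed=seed)
            st_ = compute_sufficient_stats(d)
            prior = PriorParams.ml_special(st_.J)
            assert bayes_estimate(st_, prior) == ml_estimate(st_)

    def test_full_shrinkage_prior_implied_value(self, small_random_data):
        """At the lambda -> 0 endpoint the denominator is the prior
        location alone."""
        st_ = compute_sufficient_stats(small_random_data)
        prior = PriorParams(eps=1e12, prior_loc=0.4, J=st_.J)
        assert prior.lam < 1e-10
        expected = st_.s_bxy_hat / (prior.lam * st_.s_bx_hat
                                    + (1 - prior.lam) * 0.4)
        assert bayes_estimate(st_, prior) == expected
        assert bayes_estimate(st_, prior) == pytest.approx(
            st_.s_bxy_hat / 0.4, rel=1e-9)

    def test_transcription_oracle(self, small_random_data):
        """Independent evaluation of the shrinkage formula."""
        st_ = compute_sufficient_stats(small_random_data)
        prior = PriorParams(eps=2.0, prior_loc=0.3, J=st_.J)
        lam = st_.J / (st_.J + 4.0)
        expected = st_.s_bxy_hat / (lam * st_.s_bx_hat + (1 - lam) * 0.3)
        assert bayes_estimate(st_, prior) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_invalid_denominator(self):
        # identical group means with within-group spread force s_bx < 0
        x = np.tile([-1.0, 1.0], 4)
        y = np.tile([0.3, -0.2], 4)
        d = GroupedData(x=x, y=y, group=np.repeat([0, 1, 2, 3], 2))
        st_ = compute_sufficient_stats(d)
        assert st_.s_bx_hat < 0
        prior = PriorParams(eps=1.0, prior_loc=0.0, J=st_.J)
        with pytest.raises(InvalidPriorError):
            bayes_estimate(st_, prior)


class TestEstimatedMSE:
    def test_matches_ml_mse_at_special_case(self, small_random_data):
        st_ = compute_sufficient_stats(small_random_data)
        beta = ml_estimate(st_)
        prior = PriorParams.ml_special(st_.J)
        m1 = estimated_mse(prior, st_, beta)
        m2 = ml_result(small_random_data).mse_hat_at_opt
        assert m1 == m2

    def test_nonnegative_over_grid(self, small_random_data):
        st_ = compute_sufficient_stats(small_random_data)
        beta = ml_estimate(st_)
        for lam in np.linspace(0.05, 1.0, 12):
            for loc in np.linspace(0.0, 1.0, 12):
                m = estimated_mse(PriorParams.from_lambda(lam, loc, st_.J),
                                  st_, beta)
                assert m >= 0.0

    def test_sweep_matches_independent_reimplementation(self):
        """The estimated-MSE curve over eps equals a from-scratch
        re-evaluation of the moment formulas."""
        d = make_dataset(icc_x=0.3, J=10, n=5, seed=3)
        s = compute_sufficient_stats(d)
        beta = project_plugin_slope(s, ml_estimate(s))
        loc = 0.25

        # independent scalar re-implementation of the gamma-ratio moments
        def mse_oracle(lam):
            J, n = s.J, s.n
            sbx = max(s.s_bx_hat, 0.0)
            swx = s.s_wx_hat
            bw = s.s_wxy_hat / swx
            seb = max(s.s_by_hat - beta**2 * sbx, 0.0)
            sew = max(s.s_wy_hat - bw**2 * swx, 0.0)
            m_xx = sbx + swx / n
            m_xy = beta * sbx + bw * swx / n
            m_yy = beta**2 * sbx + seb + (bw**2 * swx + sew) / n
            w_xx, w_xy, w_yy = swx, bw * swx, bw**2 * swx + sew
            cb, cw = 1 / (J - 1), 1 / (n**2 * J * (n - 1))
            var_sbx = 2 * m_xx**2 * cb + 2 * w_xx**2 * cw
            var_sbxy = (m_xx * m_yy + m_xy**2) * cb + (w_xx * w_yy
                                                       + w_xy**2) * cw
            cov = 2 * m_xx * m_xy * cb + 2 * w_xx * w_xy * cw
            bstar = cov / var_sbx
            m_c = (beta - bstar) * sbx
            s2_c = var_sbxy - cov**2 / var_sbx
            mu = lam * sbx + (1 - lam) * loc
            k = max(mu**2 / (lam**2 * var_sbx), (J - 1) / 2)
            th = mu / k
            r1 = 1 / (th * (k - 1))
            r2 = 1 / (th**2 * (k - 1) * (k - 2))
            a0, t = bstar / lam, m_c - bstar * (1 - lam) * loc / lam
            mean = a0 + t * r1
            var = s2_c * r2 + t**2 / (th**2 * (k - 1)**2 * (k - 2))
            return var + (mean - beta)**2

        for lam in np.linspace(0.1, 1.0, 10):
            got = estimated_mse(PriorParams.from_lambda(lam, loc, s.J),
                                s, ml_estimate(s))
            assert got == pytest.approx(mse_oracle(lam), rel=1e-10), lam


class TestGridSearch:
    def test_single_point_grid_returns_ml(self, small_random_data):
        st_ = compute_sufficient_stats(small_random_data)
        prior, diag = grid_search_prior(st_, ml_estimate(st_),
                                        GridSpec(n_lambda=1, n_loc=1, d=0.0))
        assert prior.lam == 1.0
        assert bayes_estimate(st_, prior) == ml_estimate(st_)

    def test_matches_exhaustive_evaluation(self):
        """Selected point identical to brute-force argmin of estimated_mse
        over the same grid with the documented tie-break."""
        grid = GridSpec(n_lambda=25, n_loc=25)
        for seed in range(5):
            d = make_dataset(icc_x=0.1, J=8, n=5, seed=seed)
            s = compute_sufficient_stats(d)
            beta = ml_estimate(s)
            prior, diag = grid_search_prior(s, beta, grid)
            lam_grid, loc_grid, _ = _grid_axes(s, grid)
            best_key, best = None, None
            for lam, loc in itertools.product(lam_grid, loc_grid):
                m = estimated_mse(PriorParams.from_lambda(lam, loc, s.J),
                                  s, beta)
                key = (m, 1.0 - lam, loc)   # min mse, then max lam, min loc
                if best_key is None or key < best_key:
                    best_key, best = key, (lam, loc)
            assert prior.lam == best[0]
            assert prior.prior_loc == best[1]
            assert diag["mse_at_opt"] == best_key[0]

    def test_dominates_ml(self):
        for seed in range(10):
            d = make_dataset(icc_x=0.05, J=10, n=5, seed=seed)
            s = compute_sufficient_stats(d)
            beta = ml_estimate(s)
            _, diag = grid_search_prior(s, beta)
            assert diag["mse_at_opt"] <= diag["mse_at_ml"]

    def test_bound_d_is_five_sds(self, small_random_data):
        s = compute_sufficient_stats(small_random_data)
        _, _, d = _grid_axes(s, GridSpec())
        from groupslope.distributions import (plugin_second_moments,
                                              sbx_sampling_sd)
        sm, _ = plugin_second_moments(s, 0.0)
        assert d == pytest.approx(5.0 * sbx_sampling_sd(sm))


class TestRegularizedBayes:
    def test_bit_identical_rerun(self, small_random_data):
        r1 = regularized_bayes(small_random_data)
        r2 = regularized_bayes(small_random_data)
        assert r1.beta_hat == r2.beta_hat
        assert r1.se == r2.se
        assert r1.prior_star == r2.prior_star

    def test_large_sample_converges_to_ml(self):
        d = make_dataset(icc_x=0.5, J=500, n=30, seed=3)
        rb = regularized_bayes(d)
        ml = ml_estimate(compute_sufficient_stats(d))
        assert abs(rb.beta_hat - ml) < 0.01

    def test_small_sample_beats_ml(self):
        """Empirical MSE of the shrinkage estimator is below ML's over
        seeded replications at J=5, n=5, icc_x=0.05."""
        reps = 300
        err_rb, err_ml = [], []
        for rep in range(reps):
            d = make_dataset(icc_x=0.05, J=5, n=5, seed=31, rep=rep)
            s = compute_sufficient_stats(d)
            err_ml.append(ml_estimate(s) - 0.5)
            err_rb.append(regularized_bayes(d).beta_hat - 0.5)
        assert np.mean(np.square(err_rb)) < np.mean(np.square(err_ml))

    def test_zero_covariance_advice(self):
        x = np.array([-1.0, -1.0, 0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        d = GroupedData(x=x, y=y, group=np.repeat([0, 1, 2, 3], 2))
        s = compute_sufficient_stats(d)
        assert s.s_bxy_hat == pytest.approx(0.0, abs=1e-15)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = regularized_bayes(d)
        assert res.diagnostics["advice"] is not None
        assert any("simpler" in str(w.message) for w in rec)

    def test_exactly_zero_between_variance_raises(self):
        d = GroupedData(x=np.ones(8), y=np.arange(8.0),
                        group=np.repeat([0, 1, 2, 3], 2))
        with pytest.raises(DegenerateVarianceError):
            regularized_bayes(d)

    def test_jackknife_se_option(self, small_random_data):
        res = regularized_bayes(
            small_random_data,
            RBOptions(grid=GridSpec(n_lambda=15, n_loc=15),
                      se_method="jackknife", jackknife_d=1, seed=0))
        assert res.se_method == "jackknife"
        assert res.se > 0


class TestJackknife:
    @staticmethod
    def _mean_of_group_means(data):
        s = compute_sufficient_stats(data)
        return float(s.xbar_j.mean())

    def test_linear_statistic_closed_form(self):
        d = make_dataset(J=12, n=4, seed=8)
        se = jackknife_se(d, estimator=self._mean_of_group_means, d_groups=1)
        means = compute_sufficient_stats(d).xbar_j
        closed = means.std(ddof=1) / np.sqrt(len(means))
        assert se == pytest.approx(closed, rel=1e-10)

    def test_zero_variance_data(self):
        d = GroupedData(x=np.ones(12), y=np.ones(12),
                        group=np.repeat(range(6), 2))
        se = jackknife_se(d, estimator=lambda dd: 1.0, d_groups=2)
        assert se == 0.0

    def test_delete2_enumeration_oracle(self):
        """delete-2 SE equals a from-scratch enumeration over all C(J,2)
        deletion sets."""
        d = make_dataset(J=8, n=4, seed=4)
        se = jackknife_se(d, estimator=self._mean_of_group_means, d_groups=2)
        idx = d.group_index
        thetas = []
        for dele in itertools.combinations(range(8), 2):
            mask = ~np.isin(idx, dele)
            sub = GroupedData(x=d.x[mask], y=d.y[mask], group=d.group[mask])
            thetas.append(self._mean_of_group_means(sub))
        thetas = np.array(thetas)
        expected = np.sqrt((8 - 2) / (2 * len(thetas))
                           * ((thetas - thetas.mean())**2).sum())
        assert se == pytest.approx(expected, rel=1e-12)
        assert len(thetas) == 28

    def test_too_few_groups(self):
        d = make_dataset(J=3, n=4, seed=1)
        with pytest.raises(ValueError):
            jackknife_se(d, estimator=self._mean_of_group_means, d_groups=2)
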