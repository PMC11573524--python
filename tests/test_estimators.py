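"""MR estimators against independent regression and interpolation oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate.estimators import (EggerEstimator, IVWEstimator,
                                  InsufficientInstrumentsError, egger, ivw,
                                  wald_ratio, weighted_median)
from mrmediate.synthetic import SimConfig, harmonized_sets, simulate_study

from conftest import make_hset


def random_hset(rng, J=None):
    J = J or int(rng.integers(3, 20))
    gamma = rng.uniform(0.02, 0.2, J) * rng.choice([-1, 1], J)
    se_g = rng.uniform(0.001, 0.01, J)
    se_G = rng.uniform(0.005, 0.05, J)
    Gamma = 0.3 * gamma + rng.normal(0, se_G)
    return make_hset(gamma, Gamma, se_g, se_G)


class TestWaldRatio:
    @pytest.mark.parametrize("gamma, Gamma, se_G, beta, se", [
        (0.1, 0.05, 0.01, 0.5, 0.1),
        (-0.1, 0.05, 0.01, -0.5, 0.1),
        (0.1, 0.0, 0.01, 0.0, 0.1),
    ])
    def test_closed_form(self, gamma, Gamma, se_G, beta, se):
        res = wald_ratio(gamma, 0.01, Gamma, se_G)
        assert res.beta == pytest.approx(beta)
        assert res.se == pytest.approx(se)
        if Gamma == 0:
            assert res.pval == pytest.approx(1.0)

    def test_zero_gamma_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_single_snp_equals_wald(self):
        h = make_hset([0.1], [0.05], [0.01], [0.02])
        res = ivw(h)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert res.beta == pytest.approx(wald.beta)
        assert res.se == pytest.approx(wald.se)

    def test_equal_weight_symmetry(self):
        h = make_hset([0.1, 0.1], [0.04, 0.06])
        assert ivw(h).beta == pytest.approx(0.5)

    def test_matches_wls_through_origin_oracle(self):
        """Closed form vs statsmodels WLS with no intercept, tol 1e-10."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            h = random_hset(rng)
            res = ivw(h)
            fit = sm.WLS(h.beta_outcome, h.beta_exposure,
                         weights=1 / h.se_outcome**2).fit()
            assert res.beta == pytest.approx(fit.params[0], abs=1e-10)
            # fixed-effect SE: unscaled (X'WX)^{-1/2}
            se_fe = float(np.sqrt(
                1 / np.sum(h.beta_exposure**2 / h.se_outcome**2)))
            assert res.se == pytest.approx(se_fe, abs=1e-12)

    def test_mre_se_never_below_fe(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            h = random_hset(rng)
            fe = ivw(h, mode="fixed")
            mre = ivw(h, mode="multiplicative_random")
            assert mre.se >= fe.se - 1e-15
            assert mre.beta == pytest.approx(fe.beta)

    def test_identical_ratios_give_that_value_and_zero_q(self):
        h = make_hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        est = IVWEstimator().fit(h.beta_exposure, h.beta_outcome,
                                 se_outcome=h.se_outcome)
        assert est.beta_ == pytest.approx(0.5)
        assert est.q_ == pytest.approx(0.0, abs=1e-20)
        assert est.q_pval_ == pytest.approx(1.0)

    def test_auto_mode_escalates_on_heterogeneity(self):
        h_het = make_hset([0.1, 0.1, 0.1, 0.1], [0.0, 0.2, -0.1, 0.4],
                          se_Gamma=[0.005] * 4)
        assert ivw(h_het, mode="auto").method == "ivw_mre"
        h_hom = make_hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        assert ivw(h_hom, mode="auto").method == "ivw_fe"

    def test_zero_gamma_rejected(self):
        h = make_hset([0.1, 0.2], [0.05, 0.1])
        h.beta_exposure[0] = 0.0
        with pytest.raises(ValueError, match="zero exposure"):
            ivw(h)

    def test_or_scale_consistency(self):
        res = ivw(make_hset([0.1, 0.2], [0.05, 0.1]))
        assert res.or_point == pytest.approx(np.exp(res.beta))
        lo, hi = res.or_ci
        assert lo < res.or_point < hi


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        gamma = np.array([0.05, 0.1, 0.15, 0.2])
        Gamma = 0.02 + 0.5 * gamma
        h = make_hset(gamma, Gamma)
        res = egger(h)
        assert res.intercept == pytest.approx(0.02, abs=1e-12)
        assert res.beta == pytest.approx(0.5, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        h = random_hset(rng, J=10)
        res = egger(h)
        flipped = make_hset(-h.beta_exposure, -h.beta_outcome,
                            h.se_exposure, h.se_outcome)
        res2 = egger(flipped)
        assert res2.beta == pytest.approx(res.beta, abs=1e-12)
        assert res2.intercept == pytest.approx(res.intercept, abs=1e-12)

    def test_matches_weighted_regression_oracle(self):
        """Slope/intercept/SEs vs statsmodels WLS on oriented data."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            h = random_hset(rng, J=10)
            res = egger(h)
            sign = np.sign(h.beta_exposure)
            g, G = h.beta_exposure * sign, h.beta_outcome * sign
            X = sm.add_constant(g)
            fit = sm.WLS(G, X, weights=1 / h.se_outcome**2).fit()
            assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
            # fixed-effect SEs = unscaled (X'WX)^{-1} diagonal
            cov = np.linalg.inv(X.T @ np.diag(1 / h.se_outcome**2) @ X)
            assert res.intercept_se == pytest.approx(np.sqrt(cov[0, 0]),
                                                     abs=1e-10)
            assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.05, 0.1]))

    def test_collinear_gamma_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            egger(make_hset([0.1, 0.1, 0.1], [0.05, 0.1, 0.2]))

    def test_less_biased_than_ivw_under_directional_pleiotropy(self):
        """With all-positive pleiotropy the Egger slope averages closer to
        the truth than IVW (500 seeded replicates)."""
        cfg_base = dict(n_snps=30, pleiotropy="directional",
                        pleiotropy_scale=0.01)
        true_alpha = SimConfig(**cfg_base, seed=0).alpha_total
        ivw_err, egger_err = [], []
        for seed in range(500):
            study = simulate_study(SimConfig(**cfg_base, seed=seed))
            h = harmonized_sets(study)["exposure_outcome"]
            ivw_err.append(ivw(h).beta - true_alpha)
            egger_err.append(egger(h).beta - true_alpha)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))


def brute_force_weighted_median(b, w):
    """Direct evaluation of the interpolation definition."""
    order = np.argsort(b)
    b, w = np.asarray(b, float)[order], np.asarray(w, float)[order]
    wn = w / w.sum()
    mids = np.cumsum(wn) - wn / 2
    if 0.5 <= mids[0]:
        return b[0]
    if 0.5 >= mids[-1]:
        return b[-1]
    k = np.searchsorted(mids, 0.5)
    x0, x1 = mids[k - 1], mids[k]
    return b[k - 1] + (b[k] - b[k - 1]) * (0.5 - x0) / (x1 - x0)


class TestWeightedMedian:
    def test_equal_weights_is_simple_median(self):
        h = make_hset([0.1, 0.1, 0.1], [0.02, 0.05, 0.09])
        res = weighted_median(h, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.5)

    def test_interpolation_example(self):
        # b = {0.1, 0.2, 0.3}, raw weights {1, 1, 2}
        # midpoints 0.125, 0.375, 0.75 -> interpolate at 0.5 -> 0.2333..
        se_G = np.array([1.0, 1.0, 1 / np.sqrt(2)])
        h = make_hset([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], se_Gamma=se_G)
        res = weighted_median(h, n_boot=50, seed=0)
        assert res.beta == pytest.approx(7 / 30)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            h = random_hset(rng)
            res = weighted_median(h, n_boot=10, seed=1)
            b = h.beta_outcome / h.beta_exposure
            w = h.beta_exposure**2 / h.se_outcome**2
            assert res.beta == pytest.approx(
                brute_force_weighted_median(b, w), abs=1e-12)

    def test_boundary_no_extrapolation(self):
        from mrmediate.estimators import _weighted_median_point
        # degenerate weights: first midpoint at/above 0.5 -> nearest ratio
        assert _weighted_median_point(np.array([0.4, 0.6]),
                                      np.array([1.0, 0.0])) == 0.4
        assert _weighted_median_point(np.array([0.4, 0.6]),
                                      np.array([0.0, 1.0])) == 0.6
        # near-degenerate weights stay near the dominating ratio
        se_G = np.array([0.001, 1.0, 1.0])
        h = make_hset([1.0, 1.0, 1.0], [0.4, 0.6, 0.9], se_Gamma=se_G)
        res = weighted_median(h, n_boot=10, seed=0)
        assert res.beta == pytest.approx(0.4, abs=1e-5)

    def test_bootstrap_se_deterministic_given_seed(self):
        h = make_hset([0.1, 0.12, 0.2, 0.05], [0.05, 0.07, 0.11, 0.02],
                      [0.01] * 4, [0.02] * 4)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se
        c = weighted_median(h, n_boot=200, seed=43)
        assert c.se != a.se


class TestSklearnCompat:
    def test_get_set_params_roundtrip(self):
        est = IVWEstimator(mode="auto", q_escalation_p=0.01)
        params = est.get_params()
        assert params == {"mode": "auto", "q_escalation_p": 0.01}
        clone = IVWEstimator().set_params(**params)
        assert clone.get_params() == params

    def test_fitted_attributes_and_predict(self):
        h = make_hset([0.1, 0.2, 0.4], [0.05, 0.11, 0.19])
        est = IVWEstimator().fit(h.beta_exposure, h.beta_outcome,
                                 se_outcome=h.se_outcome)
        for attr in ("beta_", "se_", "ci_low_", "ci_high_", "pval_",
                     "n_snps_"):
            assert hasattr(est, attr)
        pred = est.predict([0.1])
        assert pred[0] == pytest.approx(est.beta_ * 0.1)
        egg = EggerEstimator().fit(h.beta_exposure, h.beta_outcome,
                                   se_outcome=h.se_outcome)
        assert egg.predict([0.1])[0] == pytest.approx(
            egg.intercept_ + egg.beta_ * 0.1)
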