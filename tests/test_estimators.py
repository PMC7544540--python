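"""Estimator correctness: hand-computed cases, WLS oracles, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from smokemr import errors, estimators
from smokemr.estimators import HeterogeneityStats
from smokemr.harmonize import HarmonizedSet


def hs(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    return HarmonizedSet.from_arrays(bx, sx, np.asarray(by, float), np.asarray(sy, float))


class TestWaldRatio:
    def test_direct_evaluation(self):
        est = estimators.wald_ratio(0.5, 0.02, 0.25, 0.1)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_unit_exposure_is_identity(self):
        est = estimators.wald_ratio(1.0, 0.02, 0.37, 0.1)
        assert est.beta == pytest.approx(0.37)

    def test_negative_exposure_beta(self):
        est = estimators.wald_ratio(-0.5, 0.02, 0.25, 0.1)
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(errors.DomainError):
            estimators.wald_ratio(0.0, 0.02, 0.25, 0.1)

    def test_second_order_se_is_larger(self):
        first = estimators.wald_ratio(0.5, 0.1, 0.25, 0.1)
        second = estimators.wald_ratio(0.5, 0.1, 0.25, 0.1, second_order=True)
        assert second.se > first.se

    def test_or_transforms(self):
        est = estimators.wald_ratio(1.0, 0.02, 0.5, 0.1)
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))
        assert est.ci_low < est.beta < est.ci_high


class TestIvwMre:
    def test_two_snp_hand_example(self):
        est, het = estimators.ivw_mre(hs([1, 1], [1, 3], [1, 1]))
        assert est.beta == pytest.approx(2.0)
        assert het.q == pytest.approx(2.0)
        assert het.df == 1
        assert het.i_squared == pytest.approx(50.0)
        assert het.phi == pytest.approx(2.0)
        assert est.se == pytest.approx(1.0)

    def test_zero_heterogeneity_limit(self):
        # all Wald ratios equal c: theta = c, Q = 0, SE = fixed-effect SE
        bx = np.array([0.5, 1.0, 2.0])
        c = 0.3
        est, het = estimators.ivw_mre(hs(bx, c * bx, [0.1, 0.2, 0.3]))
        assert est.beta == pytest.approx(c)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i_squared == 0.0 and het.phi == 1.0
        se_fixed = 1.0 / np.sqrt(np.sum(bx**2 / np.array([0.1, 0.2, 0.3]) ** 2))
        assert est.se == pytest.approx(se_fixed)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 30))
            bx = rng.normal(0, 0.1, k)
            by = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.01, 0.5, k)
            est, het = estimators.ivw_mre(hs(bx, by, sy))
            fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
            # multiplicative random-effects SE = fixed SE * sqrt(max(1, Q/df))
            se_fixed = 1.0 / np.sqrt(np.sum(bx**2 / sy**2))
            q = np.sum((by - est.beta * bx) ** 2 / sy**2)
            assert est.se == pytest.approx(se_fixed * np.sqrt(max(1.0, q / (k - 1))), rel=1e-10)
            assert het.q == pytest.approx(q, rel=1e-10)

    def test_scale_invariance_of_point_estimate(self, rng):
        bx, by, sy = rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.uniform(0.1, 1, 10)
        e1, _ = estimators.ivw_mre(hs(bx, by, sy))
        e2, _ = estimators.ivw_mre(hs(bx, by, 7.3 * sy))
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)

    def test_single_snp_falls_back_to_wald(self):
        with pytest.warns(UserWarning, match="falling back"):
            est, het = estimators.ivw_mre(hs([0.5], [0.25], [0.1]))
        assert est.method == "ivw_mre"
        assert est.beta == pytest.approx(0.5)
        assert het.df == 0 and het.phi == 1.0

    def test_all_zero_exposure_betas_rejected(self):
        with pytest.raises(errors.DomainError):
            estimators.ivw_mre(hs([0.0, 0.0], [0.1, 0.2], [0.1, 0.1]))


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        bx = np.array([0.5, 1.0, 2.0, 0.2])
        est = estimators.weighted_median(hs(bx, 0.7 * bx, [0.1] * 4), n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.7)

    def test_equal_weight_interpolation_example(self):
        # ratios (1, 2, 9), equal weights: midpoints 1/6, 1/2, 5/6 -> median 2
        bx = np.array([1.0, 1.0, 1.0])
        est = estimators.weighted_median(hs(bx, [1.0, 2.0, 9.0], [1.0] * 3), n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_within_ratio_range(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 20))
            bx = rng.choice([-1, 1], k) * rng.uniform(0.05, 0.5, k)
            by = rng.normal(0, 0.2, k)
            sy = rng.uniform(0.05, 0.5, k)
            ratios = np.asarray(by) / bx
            point = estimators.weighted_median_point(hs(bx, by, sy))
            assert ratios.min() - 1e-12 <= point <= ratios.max() + 1e-12

    def test_seed_reproducibility(self):
        data = hs([0.5, 1.0, 2.0], [0.2, 0.5, 1.1], [0.1, 0.2, 0.3])
        a = estimators.weighted_median(data, n_boot=300, seed=42)
        b = estimators.weighted_median(data, n_boot=300, seed=42)
        c = estimators.weighted_median(data, n_boot=300, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_preconditions(self):
        data2 = hs([0.5, 1.0], [0.2, 0.5], [0.1, 0.2])
        with pytest.raises(errors.EstimatorError):
            estimators.weighted_median(data2, seed=1)
        data3 = hs([0.5, 1.0, 2.0], [0.2, 0.5, 1.1], [0.1, 0.2, 0.3])
        with pytest.raises(errors.DomainError):
            estimators.weighted_median(data3, n_boot=50, seed=1)
        with pytest.raises(errors.DomainError):
            estimators.weighted_median(data3, n_boot=200, seed=None)


class TestMrEgger:
    def test_exact_recovery_on_noiseless_line(self):
        # beta_Y = a + theta * beta_X exactly (positive exposure betas)
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        a, theta = 0.02, 0.6
        res = estimators.mr_egger(hs(bx, a + theta * bx, [0.1] * 4))
        assert res.intercept == pytest.approx(a, abs=1e-12)
        assert res.slope.beta == pytest.approx(theta, abs=1e-12)

    def test_orientation_invariance(self, rng):
        bx = rng.uniform(0.05, 0.5, 8)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.05, 0.2, 8)
        base = estimators.mr_egger(hs(bx, by, sy))
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        flipped = estimators.mr_egger(hs(bx2, by2, sy))
        assert flipped.slope.beta == pytest.approx(base.slope.beta)
        assert flipped.intercept == pytest.approx(base.intercept)
        assert flipped.intercept_p == pytest.approx(base.intercept_p)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 25))
            bx = rng.uniform(0.01, 0.5, k)
            by = rng.normal(0, 0.2, k)
            sy = rng.uniform(0.05, 0.5, k)
            res = estimators.mr_egger(hs(bx, by, sy))
            X = sm.add_constant(bx)
            fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
            assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_collinear_exposures_rejected(self):
        with pytest.raises(errors.CollinearityError):
            estimators.mr_egger(hs([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.1] * 3))

    def test_too_few_snps(self):
        with pytest.raises(errors.EstimatorError):
            estimators.mr_egger(hs([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]))


class TestMvmrIvw:
    def test_single_exposure_reduces_to_ivw(self, rng):
        bx = rng.normal(0, 0.1, 12)
        by = rng.normal(0, 0.1, 12)
        sy = rng.uniform(0.05, 0.3, 12)
        ivw, _ = estimators.ivw_mre(hs(bx, by, sy))
        mv = estimators.mvmr_ivw(bx[:, None], by, sy, ["exposure"])
        assert mv[0].beta == pytest.approx(ivw.beta, rel=1e-12)
        assert mv[0].se == pytest.approx(ivw.se, rel=1e-12)

    def test_exact_recovery_noiseless_two_exposures(self, rng):
        X = rng.normal(0, 0.1, size=(20, 2))
        by = 0.3 * X[:, 0] + 0.1 * X[:, 1]
        mv = estimators.mvmr_ivw(X, by, np.full(20, 0.1), ["smoking", "alcohol"])
        assert mv[0].beta == pytest.approx(0.3, abs=1e-12)
        assert mv[1].beta == pytest.approx(0.1, abs=1e-12)
        assert [e.exposure for e in mv] == ["smoking", "alcohol"]

    def test_rank_deficiency_names_offender(self, rng):
        x = rng.normal(0, 0.1, 10)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(errors.CollinearityError, match="bmi"):
            estimators.mvmr_ivw(X, rng.normal(0, 0.1, 10), np.full(10, 0.1), ["smoking", "bmi"])

    def test_needs_more_snps_than_exposures(self, rng):
        X = rng.normal(0, 0.1, size=(2, 2))
        with pytest.raises(errors.EstimatorError):
            estimators.mvmr_ivw(X, np.zeros(2), np.full(2, 0.1))

    def test_matches_wls_oracle(self, rng):
        for _ in range(30):
            k = int(rng.integers(5, 30))
            X = rng.normal(0, 0.1, size=(k, 3))
            by = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.05, 0.3, k)
            mv = estimators.mvmr_ivw(X, by, sy)
            fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
            for j in range(3):
                assert mv[j].beta == pytest.approx(fit.params[j], abs=1e-10)


class TestHeterogeneityStats:
    @given(
        st.floats(min_value=0.0, max_value=1e6),
        st.integers(min_value=1, max_value=500),
    )
    def test_invariants(self, q, df):
        h = HeterogeneityStats.from_q(q, df)
        assert 0.0 <= h.i_squared <= 100.0
        assert h.phi >= 1.0
        if q <= df:
            assert h.phi == 1.0

    def test_q_zero(self):
        h = HeterogeneityStats.from_q(0.0, 10)
        assert h.i_squared == 0.0 and h.phi == 1.0
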