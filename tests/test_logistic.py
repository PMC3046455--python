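"""IRLS core: closed-form oracles, statsmodels cross-check, LRT, Wald CIs,
separation handling and the batched many-outcomes fitter."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from gxescan.errors import (CollinearityError, DegenerateVarianceError,
                            NestingError, SeparationError)
from gxescan.logistic import (fit_logistic, fit_logistic_many, lrt,
                              wald_or_ci)


def _two_by_two(a, b, c, d):
    """cases: a exposed / b unexposed; controls: c exposed / d unexposed."""
    exposed = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    x = pd.DataFrame({"intercept": np.ones_like(exposed), "exposed": exposed})
    return x, y


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        x, y = _two_by_two(30, 10, 20, 40)
        fit = fit_logistic(x, y)
        assert math.exp(fit.coef("exposed")) == pytest.approx(6.0, abs=1e-8)

    def test_intercept_only_recovers_case_fraction(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        x = pd.DataFrame({"intercept": np.ones(100)})
        fit = fit_logistic(x, y)
        assert 1 / (1 + math.exp(-fit.coef("intercept"))) == pytest.approx(0.3)

    def test_separation_raises(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = pd.DataFrame({"intercept": np.ones(40),
                          "perfect": y.astype(float)})
        with pytest.raises(SeparationError, match="perfect"):
            fit_logistic(x, y)

    def test_collinearity_raises(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=80)
        x = pd.DataFrame({"intercept": np.ones(80), "z": z, "z2": 2 * z})
        y = (rng.random(80) < 0.5).astype(float)
        with pytest.raises(CollinearityError):
            fit_logistic(x, y)

    def test_matches_statsmodels_on_random_data(self):
        """Independent oracle: statsmodels MLE on a multi-covariate problem."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 600
        x = pd.DataFrame({
            "intercept": np.ones(n),
            "d": rng.binomial(2, 0.3, n).astype(float),
            "e": rng.poisson(2.0, n).astype(float),
            "z": rng.normal(size=n),
        })
        eta = -1.0 + 0.2 * x["d"] - 0.1 * x["e"] + 0.3 * x["z"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(x, y)
        ref = sm.Logit(y, x.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.log_likelihood, ref.llf, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.covariance)),
                                   ref.bse, rtol=1e-5)

    def test_affine_recoding_invariance(self):
        """LRT is unchanged by affine recoding; OR rescales as predicted."""
        rng = np.random.default_rng(3)
        n = 500
        e = rng.normal(28.0, 4.0, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.05 * (e - 28))))
             ).astype(float)
        ones = np.ones(n)
        x1 = pd.DataFrame({"intercept": ones, "e": e})
        x2 = pd.DataFrame({"intercept": ones, "e": (e - 20.0) / 5.0})
        null = fit_logistic(pd.DataFrame({"intercept": ones}), y)
        f1, f2 = fit_logistic(x1, y), fit_logistic(x2, y)
        s1, _, _ = lrt(f1, null)
        s2, _, _ = lrt(f2, null)
        assert s1 == pytest.approx(s2, abs=1e-6)
        or_per_unit = math.exp(f1.coef("e"))
        or_per_5 = math.exp(f2.coef("e"))
        assert or_per_5 == pytest.approx(or_per_unit ** 5, rel=1e-6)


class TestLrt:
    def _fits(self):
        rng = np.random.default_rng(1)
        n = 200
        z = rng.normal(size=n)
        y = (rng.random(n) < 0.4).astype(float)
        ones = np.ones(n)
        null = fit_logistic(pd.DataFrame({"intercept": ones}), y)
        full = fit_logistic(pd.DataFrame({"intercept": ones, "z": z}), y)
        return full, null

    def test_equal_likelihoods_give_zero_and_p_one(self):
        """When the extra term buys no likelihood, stat = 0 and p = 1."""
        from gxescan.logistic import ModelFit

        def fake(terms, ll):
            k = len(terms)
            return ModelFit(coefficients=np.zeros(k), covariance=np.eye(k),
                            log_likelihood=ll, n_used=50, converged=True,
                            term_names=terms)

        stat, df, p = lrt(fake(("intercept", "x"), -30.0),
                          fake(("intercept",), -30.0))
        assert stat == 0.0
        assert df == 1
        assert p == 1.0

    def test_df_equals_number_of_added_terms(self):
        full, null = self._fits()
        stat, df, p = lrt(full, null)
        assert df == 1
        assert stat >= 0.0 and 0.0 < p <= 1.0

    def test_chi_square_tail_value(self):
        assert chi2.sf(3.84, 1) == pytest.approx(0.0500, abs=5e-4)

    def test_non_nested_raises(self):
        full, null = self._fits()
        with pytest.raises(NestingError):
            lrt(null, full)

    def test_mismatched_n_raises(self):
        rng = np.random.default_rng(5)
        y = (rng.random(100) < 0.5).astype(float)
        f_all = fit_logistic(pd.DataFrame({"intercept": np.ones(100),
                                           "z": rng.normal(size=100)}), y)
        f_sub = fit_logistic(pd.DataFrame({"intercept": np.ones(80)}), y[:80])
        with pytest.raises(NestingError):
            lrt(f_all, f_sub)

    def test_null_pvalues_uniform(self):
        """LRT p on a null covariate is Uniform(0,1) across simulations."""
        rng = np.random.default_rng(99)
        n = 300
        ones = np.ones(n)
        pvals = []
        for _ in range(2000):
            z = rng.normal(size=n)
            y = (rng.random(n) < 0.3).astype(float)
            null = fit_logistic(pd.DataFrame({"intercept": ones}), y)
            full = fit_logistic(pd.DataFrame({"intercept": ones, "z": z}), y)
            pvals.append(lrt(full, null)[2])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestWaldCi:
    def test_interval_arithmetic(self):
        # beta = 0, SE = 0.1 -> OR 1, CI exp(+/- 1.96 * 0.1)
        fit = fit_logistic(
            pd.DataFrame({"intercept": np.ones(4), "x": [0., 1., 0., 1.]}),
            np.array([0., 1., 1., 0.]))
        fake = fit.__class__(coefficients=np.array([0.0]),
                             covariance=np.array([[0.01]]),
                             log_likelihood=0.0, n_used=4, converged=True,
                             term_names=("x",))
        or_, lo, hi = wald_or_ci(fake, "x")
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(math.exp(-1.959964 * 0.1), abs=1e-4)
        assert hi == pytest.approx(math.exp(1.959964 * 0.1), abs=1e-4)

    def test_wider_level_contains_narrower(self):
        fake = TestWaldCi._fake(beta=0.3, var=0.02)
        _, lo95, hi95 = wald_or_ci(fake, "x", 0.95)
        _, lo99, hi99 = wald_or_ci(fake, "x", 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_tiny_se_hugs_point_estimate(self):
        fake = TestWaldCi._fake(beta=math.log(1.22), var=1e-8)
        or_, lo, hi = wald_or_ci(fake, "x")
        assert or_ == pytest.approx(1.22)
        assert lo == pytest.approx(1.22, abs=1e-3)
        assert hi == pytest.approx(1.22, abs=1e-3)

    def test_degenerate_variance_raises(self):
        fake = TestWaldCi._fake(beta=0.0, var=0.0)
        with pytest.raises(DegenerateVarianceError):
            wald_or_ci(fake, "x")

    @staticmethod
    def _fake(beta, var):
        from gxescan.logistic import ModelFit
        return ModelFit(coefficients=np.array([beta]),
                        covariance=np.array([[var]]), log_likelihood=0.0,
                        n_used=10, converged=True, term_names=("x",))


class TestFitMany:
    def test_matches_single_fits(self):
        rng = np.random.default_rng(7)
        n, B = 400, 25
        x = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n),
                             rng.poisson(2, n)]).astype(float)
        Y = (rng.random((n, B)) < 0.3).astype(float)
        betas, lls, ok = fit_logistic_many(x, Y)
        assert ok.all()
        for j in range(0, B, 5):
            single = fit_logistic(x, Y[:, j])
            np.testing.assert_allclose(betas[:, j], single.coefficients,
                                       atol=1e-5)
            assert lls[j] == pytest.approx(single.log_likelihood, abs=1e-6)

    def test_separated_column_flagged_not_raised(self):
        n = 60
        x = np.column_stack([np.ones(n),
                             np.r_[np.ones(30), np.zeros(30)]])
        Y = np.column_stack([
            np.r_[np.ones(30), np.zeros(30)],      # perfectly separated
            (np.arange(n) % 2).astype(float),      # fine
        ])
        _, _, ok = fit_logistic_many(x, Y)
        assert not ok[0]
        assert ok[1]
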