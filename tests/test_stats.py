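"""Odds ratios, contingency tests, t-tests, IRLS logistic regression,
Hosmer-Lemeshow calibration and likelihood-ratio comparison."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize
from scipy import stats as sps
from scipy.special import comb

from vittabo.cohort import ContingencyTable
from vittabo.stats import (
    chisq_test,
    fisher_exact_2x2,
    hosmer_lemeshow,
    logistic_fit,
    lr_test,
    mann_whitney_u,
    odds_ratio_2x2,
    t_test_from_summary,
)


def table2x2(cells):
    return ContingencyTable(np.array(cells), ("exposed", "unexposed"), ("case", "control"))


class TestOddsRatio:
    def test_o_vs_a_cross_product(self):
        res = odds_ratio_2x2(table2x2([[20, 74], [22, 312]]))
        assert round(res.or_point, 2) == 3.83
        assert not res.correction_applied
        # Wald interval asserted to 6 dp against an independent hand computation
        se = math.sqrt(1 / 20 + 1 / 74 + 1 / 22 + 1 / 312)
        z = sps.norm.ppf(0.975)
        assert res.ci_lower == pytest.approx(math.exp(math.log(3.832923832923833) - z * se), abs=5e-7)
        assert res.ci_upper == pytest.approx(math.exp(math.log(3.832923832923833) + z * se), abs=5e-7)

    def test_unit_table_symmetric(self):
        res = odds_ratio_2x2(table2x2([[1, 1], [1, 1]]))
        assert res.or_point == 1.0
        assert math.log(res.ci_lower) == pytest.approx(-math.log(res.ci_upper))

    def test_haldane_anscombe_correction(self):
        res = odds_ratio_2x2(table2x2([[0, 10], [10, 10]]))
        assert res.correction_applied
        assert res.or_point == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_zero_line_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_2x2(table2x2([[0, 0], [10, 10]]))

    def test_equals_logistic_slope(self):
        # saturated one-predictor identity: exp(slope) == cross-product OR
        cells = [[20, 74], [22, 312]]
        res = odds_ratio_2x2(table2x2(cells))
        y = [1] * 20 + [0] * 74 + [1] * 22 + [0] * 312
        x = [[1.0]] * 94 + [[0.0]] * 334
        fit = logistic_fit(np.array(x), y, names=["O"])
        assert math.exp(fit.coefficients["O"]) == pytest.approx(res.or_point, abs=1e-6)


class TestChisq:
    def test_blood_type_table(self, vaccinated_counts, unvaccinated_counts):
        from vittabo.cohort import make_contingency
        res = chisq_test(make_contingency(vaccinated_counts, unvaccinated_counts))
        assert res.p_value < 0.001
        assert res.df == 3

    def test_identical_columns(self):
        t = ContingencyTable(np.array([[5, 5], [7, 7], [3, 3]]), ("a", "b", "c"), ("x", "y"))
        res = chisq_test(t)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_term_by_term_hand_computation(self):
        cells = np.array([[10, 20, 30], [15, 10, 5]])
        t = ContingencyTable(cells, ("r1", "r2"), ("c1", "c2", "c3"))
        exp = np.outer(cells.sum(1), cells.sum(0)) / cells.sum()
        stat = ((cells - exp) ** 2 / exp).sum()
        res = chisq_test(t)
        assert res.statistic == pytest.approx(stat)
        assert res.df == 2

    def test_zero_marginal_rejected(self):
        t = ContingencyTable(np.array([[0, 0], [5, 5]]), ("a", "b"), ("x", "y"))
        with pytest.raises(ValueError, match="marginal"):
            chisq_test(t)

    def test_permutation_invariance_and_scaling(self):
        cells = np.array([[4, 9], [7, 2]])
        t = ContingencyTable(cells, ("a", "b"), ("x", "y"))
        t_perm = ContingencyTable(cells[::-1, ::-1].copy(), ("b", "a"), ("y", "x"))
        assert chisq_test(t).statistic == pytest.approx(chisq_test(t_perm).statistic)
        t3 = ContingencyTable(3 * cells, ("a", "b"), ("x", "y"))
        assert chisq_test(t3).statistic == pytest.approx(3 * chisq_test(t).statistic)


def fisher_enumeration_p(cells):
    """Exact two-sided p by direct hypergeometric enumeration."""
    a, b = cells[0]
    c, d = cells[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    def prob(k):
        return comb(c1, k, exact=True) * comb(n - c1, r1 - k, exact=True) / comb(n, r1, exact=True)
    p_obs = prob(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_against_enumeration_oracle(self):
        res = fisher_exact_2x2(table2x2([[1, 9], [9, 1]]))
        assert res.p_value == pytest.approx(fisher_enumeration_p([[1, 9], [9, 1]]))

    def test_balanced_table(self):
        assert fisher_exact_2x2(table2x2([[5, 5], [5, 5]])).p_value == 1.0

    def test_zero_margin_degenerate(self):
        assert fisher_exact_2x2(table2x2([[0, 0], [4, 6]])).p_value == 1.0

    def test_enumeration_equivalence_small_tables(self, rng):
        # all tables with total <= 16, plus a random sample up to 30
        tables = [t for t in itertools.product(range(9), repeat=4) if 0 < sum(t) <= 16]
        tables += [tuple(rng.multinomial(n, [0.25] * 4))
                   for n in rng.integers(17, 31, size=150)]
        for t in tables:
            cells = [[t[0], t[1]], [t[2], t[3]]]
            p = fisher_exact_2x2(table2x2(cells)).p_value
            assert p == pytest.approx(fisher_enumeration_p(cells), abs=1e-9), cells


class TestTFromSummary:
    def test_age_comparison(self):
        res = t_test_from_summary(47.8, 15.1, 82, 47.4, 15.4, 441, variant="welch")
        assert round(res.p_value, 2) == 0.83
        assert res.method == "welch-t"

    def test_identical_summaries(self):
        res = t_test_from_summary(10, 2, 30, 10, 2, 30)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_pooled_hand_formula(self):
        res = t_test_from_summary(10, 2, 5, 12, 2, 5, variant="pooled")
        assert res.statistic == pytest.approx(-1.5811, abs=1e-4)
        assert res.df == 8

    def test_sign_flip_invariance(self):
        a = t_test_from_summary(47.8, 15.1, 82, 47.4, 15.4, 441)
        b = t_test_from_summary(47.4, 15.4, 441, 47.8, 15.1, 82)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(-b.statistic)

    @pytest.mark.parametrize("kw", [dict(n1=1), dict(sd1=0.0)])
    def test_invalid_inputs(self, kw):
        args = dict(mean1=1, sd1=1, n1=5, mean2=2, sd2=1, n2=5)
        args.update(kw)
        with pytest.raises(ValueError):
            t_test_from_summary(**args)


class TestMannWhitney:
    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        # oracle: exhaustive permutation of group labels
        pooled = [1, 2, 3, 4, 5, 6]
        us = []
        for idx in itertools.combinations(range(6), 3):
            x = [pooled[i] for i in idx]
            y = [pooled[i] for i in range(6) if i not in idx]
            us.append(sum(1 for xi in x for yi in y if xi < yi))
        obs_u = 0
        p = np.mean([min(u, 9 - u) <= min(obs_u, 9 - obs_u) for u in us])
        assert res.p_value == pytest.approx(p)

    def test_exact_close_to_normal_approx(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
        exact = sps.mannwhitneyu(x, y, method="exact").pvalue
        approx = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(exact - approx) < 0.05

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning, match="tied"):
            res = mann_whitney_u([2, 2], [2, 2, 2])
        assert res.p_value == 1.0


def neg_loglik(beta, X, y):
    eta = X @ beta
    return -np.sum(y * eta - np.log1p(np.exp(eta)))


class TestLogistic:
    def test_matches_independent_optimizer(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50), rng.normal(size=50)])
        y = (rng.random(50) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])))).astype(int)
        fit = logistic_fit(X[:, 1:], y, names=["a", "b"])
        res = optimize.minimize(neg_loglik, np.zeros(3), args=(X, y), method="BFGS",
                                options={"gtol": 1e-10})
        assert np.array(list(fit.coefficients.values())) == pytest.approx(res.x, abs=1e-5)
        assert fit.converged

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(80, 2))
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.2 + X[:, 0])))).astype(int)
        fit = logistic_fit(X, y, names=["a", "b"])
        ref = sm.Logit(y, np.column_stack([np.ones(80), X])).fit(disp=0)
        assert np.array(list(fit.coefficients.values())) == pytest.approx(ref.params, abs=1e-6)
        assert np.array(list(fit.standard_errors.values())) == pytest.approx(ref.bse, rel=1e-4)
        assert fit.aic == pytest.approx(ref.aic)

    def test_constant_outcome_flagged(self):
        fit = logistic_fit(np.ones((10, 1)) * np.arange(10)[:, None], [1] * 10)
        assert fit.separation_detected and fit.coefficients is None

    def test_complete_separation_detected(self):
        x = np.arange(20, dtype=float)[:, None]
        y = (x[:, 0] >= 10).astype(int)
        fit = logistic_fit(x, y, names=["x"])
        assert fit.separation_detected
        assert not fit.converged

    def test_collinear_columns_named(self, rng):
        x1 = rng.normal(size=30)
        X = np.column_stack([x1, 2 * x1])
        y = (rng.random(30) < 0.5).astype(int)
        with pytest.raises(ValueError, match="dup"):
            logistic_fit(X, y, names=["orig", "dup"])

    def test_aic_identity(self, rng):
        X = rng.normal(size=(60, 1))
        y = (rng.random(60) < 0.4).astype(int)
        fit = logistic_fit(X, y, names=["x"])
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * len(fit.coefficients))


class TestHosmerLemeshow:
    def test_two_group_hand_computation(self):
        p = np.array([0.2, 0.2, 0.3, 0.3, 0.7, 0.7, 0.8, 0.8])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = hosmer_lemeshow(p, y, groups=2)
        # by hand: bin1 = first four (O=0, E=1.0), bin2 = last four (O=4, E=3.0)
        o1, e1, n1 = 0, 1.0, 4
        o2, e2, n2 = 4, 3.0, 4
        stat = (o1 - e1) ** 2 / (e1 * (1 - e1 / n1)) + (o2 - e2) ** 2 / (e2 * (1 - e2 / n2))
        assert res.statistic == pytest.approx(stat)
        # two bins leave zero degrees of freedom: no p-value is defined
        assert res.df == 0 and math.isnan(res.p_value)

    def test_perfect_calibration(self):
        # fitted prob equals each bin's event rate exactly
        p = np.repeat([0.25, 0.5, 0.75], 4)
        y = np.array([0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1])
        res = hosmer_lemeshow(p, y, groups=3)
        assert res.statistic == pytest.approx(0.0)

    def test_well_specified_rejection_rate(self, rng):
        # nominal behaviour under a correctly specified model
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=200)
            prob = 1 / (1 + np.exp(-(0.2 + 0.8 * x)))
            y = (rng.random(200) < prob).astype(int)
            fit = logistic_fit(x[:, None], y, names=["x"])
            if not fit.converged:
                continue
            res = hosmer_lemeshow(fit.fitted_probs, y, groups=10)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_probability_domain_enforced(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5], [0, 1], groups=2)


class TestLrTest:
    def test_identical_models(self, rng):
        X = rng.normal(size=(40, 1))
        y = (rng.random(40) < 0.5).astype(int)
        fit = logistic_fit(X, y, names=["x"])
        res = lr_test(fit, fit)
        assert res.statistic == pytest.approx(0.0) and res.p_value == 1.0

    def test_equals_g_statistic_on_2x2(self):
        # full (O indicator) vs intercept-only on the O/A data equals the
        # likelihood-ratio G computed directly from cell counts
        cells = np.array([[20, 74], [22, 312]], dtype=float)
        y = np.concatenate([np.ones(20), np.zeros(74), np.ones(22), np.zeros(312)])
        x = np.concatenate([np.ones(94), np.zeros(334)])[:, None]
        full = logistic_fit(x, y, names=["O"])
        reduced = logistic_fit(np.zeros((428, 0)), y, names=[])
        res = lr_test(full, reduced)
        exp = np.outer(cells.sum(1), cells.sum(0)) / cells.sum()
        g = 2 * np.sum(cells * np.log(cells / exp))
        assert res.statistic == pytest.approx(g, abs=1e-6)
        assert res.df == 1

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(500):
            x = rng.normal(size=(80, 2))
            y = (rng.random(80) < 1 / (1 + np.exp(-x[:, 0]))).astype(int)
            if y.min() == y.max():
                continue
            full = logistic_fit(x, y, names=["signal", "noise"])
            reduced = logistic_fit(x[:, :1], y, names=["signal"])
            if not (full.converged and reduced.converged):
                continue
            pvals.append(lr_test(full, reduced).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_non_nested_rejected(self, rng):
        X = rng.normal(size=(40, 1))
        y = (rng.random(40) < 0.5).astype(int)
        full = logistic_fit(X, y, names=["x"])
        bigger = logistic_fit(np.column_stack([X, rng.normal(size=40)]), y, names=["x", "z"])
        with pytest.raises(ValueError):
            lr_test(full, bigger)
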