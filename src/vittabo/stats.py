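"""Contingency-table and regression statistics for the case-control analysis.

Odds ratios with Wald intervals (Haldane-Anscombe corrected when a cell
is zero), Pearson chi-square and Fisher exact tests, t-tests from summary
statistics, Mann-Whitney U, logistic regression by iteratively reweighted
least squares (IRLS) with separation detection, the Hosmer-Lemeshow
calibration test, and likelihood-ratio model comparison.

Chi-square, Fisher, t and Mann-Whitney computations are delegated to
scipy.stats; the odds ratio, IRLS fit, Hosmer-Lemeshow and LR test are
implemented here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from vittabo.cohort import ContingencyTable


@dataclass
class OddsRatioResult:
    or_point: float
    ci_lower: float
    ci_upper: float
    level: float
    log_se: float
    correction_applied: bool

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class TestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    method: str
    note: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class LogisticFit:
    coefficients: Optional[dict]
    standard_errors: Optional[dict]
    loglik: float
    aic: float
    n_iter: int
    converged: bool
    separation_detected: bool
    fitted_probs: Optional[np.ndarray] = field(default=None, repr=False)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "fitted_probs"}
        return json.dumps(d)


def _as_2x2(table: ContingencyTable) -> np.ndarray:
    cells = np.asarray(table.cells, dtype=float)
    if cells.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {cells.shape}")
    return cells


def odds_ratio_2x2(table: ContingencyTable, level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with a Wald CI on the log scale.

    The Haldane-Anscombe correction (+0.5 to every cell) is applied, and
    flagged, whenever any cell is zero.  Two zero cells in the same row
    or column leave the odds ratio undefined and raise.
    """
    cells = _as_2x2(table)
    zero = cells == 0
    if (zero.all(axis=1).any() or zero.all(axis=0).any()):
        raise ValueError("odds ratio undefined: a full row or column of the table is zero")
    corrected = bool(zero.any())
    c = cells + 0.5 if corrected else cells
    a, b = c[0]
    cc, d = c[1]
    or_point = (a * d) / (b * cc)
    log_se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        or_point=or_point,
        ci_lower=math.exp(math.log(or_point) - z * log_se),
        ci_upper=math.exp(math.log(or_point) + z * log_se),
        level=level,
        log_se=log_se,
        correction_applied=corrected,
    )


def chisq_test(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    The Yates continuity correction applies only to 2x2 tables and only
    when requested.
    """
    cells = np.asarray(table.cells, dtype=float)
    if (cells.sum(axis=0) == 0).any() or (cells.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total; expected counts undefined")
    correction = bool(yates and cells.shape == (2, 2))
    res = sps.chi2_contingency(cells, correction=correction)
    return TestResult(statistic=float(res.statistic), df=float(res.dof),
                      p_value=float(res.pvalue), method="pearson-chisq")


def fisher_exact_2x2(table: ContingencyTable, tail: str = "two-sided") -> TestResult:
    """Fisher's exact test, conditional on the margins."""
    cells = _as_2x2(table)
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    res = sps.fisher_exact(cells, alternative=alt)
    return TestResult(statistic=float(res.statistic), df=None,
                      p_value=float(res.pvalue), method="fisher-exact")


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> TestResult:
    """Two-sided independent t-test from group summary statistics.

    ``welch`` (default) uses the Satterthwaite df; ``pooled`` is the
    classical equal-variance test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    if variant == "welch":
        v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
        method = "welch-t"
    else:
        df = n1 + n2 - 2
        method = "pooled-t"
    return TestResult(statistic=float(res.statistic), df=float(df),
                      p_value=float(res.pvalue), method=method)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when min(n) <= 8 and there are no ties; otherwise
    the normal approximation with tie correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return TestResult(statistic=float(len(x) * len(y) / 2), df=None,
                          p_value=1.0, method="mann-whitney", note="all-tied")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), df=None,
                      p_value=float(min(res.pvalue, 1.0)), method="mann-whitney", note=method)


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def logistic_fit(
    X: np.ndarray,
    y: Sequence[int],
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Standard errors come from the inverse observed information.
    Complete or quasi-separation (a coefficient diverging past 15 in
    absolute value while the deviance keeps falling) is detected and
    flagged instead of iterating to overflow; a constant outcome is
    flagged immediately with no estimates.  A singular information
    matrix raises, naming the collinear columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names

    if np.all(y == y[0]):
        return LogisticFit(coefficients=None, standard_errors=None,
                           loglik=-math.inf, aic=math.inf, n_iter=0,
                           converged=False, separation_detected=True)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify columns that are linear combinations of earlier ones.
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                collinear.append(names[j])
        raise ValueError(f"singular information matrix; collinear columns: {collinear}")

    beta = np.zeros(X.shape[1])
    ll_prev = _bernoulli_loglik(y, np.full(len(y), y.mean()))
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = X.T @ (w[:, None] * X)
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise ValueError("singular information matrix during IRLS") from None
        beta_new = beta + step
        ll_new = _bernoulli_loglik(y, 1.0 / (1.0 + np.exp(-(X @ beta_new))))
        if np.max(np.abs(beta_new)) > 15 and ll_new > ll_prev:
            beta = beta_new
            separation = True
            break
        delta = np.max(np.abs(beta_new - beta))
        beta, ll_prev = beta_new, ll_new
        if delta < tol:
            converged = True
            break

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = X.T @ (w[:, None] * X)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    ll = _bernoulli_loglik(y, mu)
    return LogisticFit(
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        loglik=ll,
        aic=-2 * ll + 2 * len(beta),
        n_iter=it,
        converged=converged and not separation,
        separation_detected=separation,
        fitted_probs=mu,
    )


def hosmer_lemeshow(fitted_probs: Sequence[float], outcome: Sequence[int], groups: int = 10) -> TestResult:
    """Hosmer-Lemeshow calibration test.

    Subjects are ranked by fitted probability (stable sort, so ties keep
    input order), split into near-equal bins, and the statistic
    ``sum (O - E)^2 / (E (1 - E / n_g))`` is referred to chi-square with
    ``groups - 2`` df.  Bins with zero expected variance are merged into
    their neighbour with a warning.
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, groups)

    obs, exp, sizes = [], [], []
    for b in bins:
        obs.append(y[b].sum())
        exp.append(p[b].sum())
        sizes.append(len(b))
    obs, exp, sizes = np.array(obs), np.array(exp), np.array(sizes, dtype=float)

    # Merge bins whose binomial variance n*pbar*(1-pbar) vanishes.
    while True:
        var = exp * (1 - exp / sizes)
        bad = np.where(var <= 1e-12)[0]
        if len(bad) == 0 or len(obs) <= 2:
            break
        i = bad[0]
        j = i - 1 if i > 0 else i + 1
        warnings.warn(f"merging Hosmer-Lemeshow bin {i} (zero expected variance) into bin {j}")
        keep = np.ones(len(obs), dtype=bool)
        keep[i] = False
        obs[j] += obs[i]
        exp[j] += exp[i]
        sizes[j] += sizes[i]
        obs, exp, sizes = obs[keep], exp[keep], sizes[keep]

    var = exp * (1 - exp / sizes)
    if np.any(var <= 1e-12):
        raise ValueError("too few usable bins for the Hosmer-Lemeshow test")
    stat = float(np.sum((obs - exp) ** 2 / var))
    df = len(obs) - 2
    if df < 1:
        # Two usable bins pin df at zero: the statistic is still the
        # calibration discrepancy, but no chi-square reference exists.
        return TestResult(statistic=stat, df=0.0, p_value=float("nan"),
                          method="hosmer-lemeshow",
                          note="zero degrees of freedom; p-value undefined")
    return TestResult(statistic=stat, df=float(df),
                      p_value=float(sps.chi2.sf(stat, df)), method="hosmer-lemeshow")


def lr_test(fit_full: LogisticFit, fit_reduced: LogisticFit, tol: float = 1e-6) -> TestResult:
    """Likelihood-ratio chi-square test between nested logistic fits."""
    if fit_full.coefficients is None or fit_reduced.coefficients is None:
        raise ValueError("both fits need estimated coefficients")
    k_full, k_red = len(fit_full.coefficients), len(fit_reduced.coefficients)
    if k_full < k_red:
        raise ValueError("full model has fewer coefficients than the reduced model")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -tol:
        raise ValueError("full-model likelihood below reduced-model likelihood; "
                         "models are not nested or a fit did not converge")
    stat = max(stat, 0.0)
    df = k_full - k_red
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=float(df), p_value=p, method="lr-chisq")
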