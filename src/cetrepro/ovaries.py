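"""Ovarian corpora analyses: asymmetry, scar persistence, ovulation rate.

Each ovulation leaves a corpus luteum (CL) that regresses to a persistent
corpus albicans (CA) scar. Assuming corpora persist indefinitely, the total
count (CAs + CL) is a cumulative ovulation index, and the slope of mean
corpora count on age estimates the ovulation rate (corpora/year). Delphinid
ovaries are strongly left-biased, so left/right counts are compared with a
Kruskal-Wallis test (after a Shapiro-Wilk normality check, which these count
data routinely fail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class LinearFitReport:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass
class AsymmetryReport:
    shapiro_stat: float
    shapiro_p: float
    kw_stat: float
    kw_p: float
    total_left: int
    total_right: int
    ratio: float | None   # left:right; None when the right total is zero


@dataclass
class TTestReport:
    t_stat: float
    p_value: float
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    degenerate: bool = False


def _ols(x, y, min_n: int = 3) -> LinearFitReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_n:
        raise ValueError(f"regression needs at least {min_n} points (got {len(x)})")
    if np.ptp(y) == 0:  # constant response: flat line, no explained variance
        return LinearFitReport(0.0, float(y[0]), 0.0, 1.0, len(x))
    fit = stats.linregress(x, y)
    return LinearFitReport(float(fit.slope), float(fit.intercept),
                           float(fit.rvalue ** 2), float(fit.pvalue), len(x))


def asymmetry_test(corpora_left, corpora_right) -> AsymmetryReport:
    """Left-vs-right corpora comparison (Shapiro-Wilk, then Kruskal-Wallis).

    Reports side totals and the left:right ratio alongside the test. With
    identical count vectors the KW statistic is 0 and p = 1; with all-zero
    counts on both sides the ratio is undefined (None) but the test result
    is still reported.
    """
    left = np.asarray(corpora_left, dtype=float)
    right = np.asarray(corpora_right, dtype=float)
    pooled = np.concatenate([left, right])
    if np.ptp(pooled) == 0:
        sh_stat, sh_p = np.nan, np.nan
        kw_stat, kw_p = 0.0, 1.0
    else:
        sh_stat, sh_p = stats.shapiro(pooled)
        kw_stat, kw_p = stats.kruskal(left, right)
    tl, tr = int(left.sum()), int(right.sum())
    ratio = tl / tr if tr > 0 else None
    return AsymmetryReport(float(sh_stat), float(sh_p), float(kw_stat), float(kw_p),
                           tl, tr, ratio)


def persistence_regressions(tbl, age, corpora) -> dict[str, LinearFitReport]:
    """OLS of corpora count on TBL and on age (pairwise deletion per fit)."""
    tbl = np.asarray(tbl, dtype=float)
    age = np.asarray(age, dtype=float)
    corpora = np.asarray(corpora, dtype=float)
    return {"tbl": _ols(tbl, corpora), "age": _ols(age, corpora)}


def ovulation_rate(ages, corpora) -> LinearFitReport:
    """Ovulation rate: slope of mean corpora count per integer age class on age.

    Ages are binned to integer-year classes (half-year best estimates floor);
    at least 3 distinct classes are required. The regression slope is the
    rate at which corpora are formed (corpora/year), assuming scars persist.
    """
    ages = np.asarray(ages, dtype=float)
    corpora = np.asarray(corpora, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(corpora)
    ages, corpora = ages[ok], corpora[ok]
    classes = np.floor(ages).astype(int)
    uniq = np.unique(classes)
    if len(uniq) < 3:
        raise ValueError(f"ovulation rate needs >=3 age classes (got {len(uniq)})")
    means = np.array([corpora[classes == c].mean() for c in uniq])
    return _ols(uniq.astype(float), means, min_n=3)


def cl_vs_foetus(cl_diameters_mm, foetus_tbl_cm) -> LinearFitReport:
    """OLS of CL diameter on foetal TBL among pregnant females (report only)."""
    return _ols(foetus_tbl_cm, cl_diameters_mm)


def ovary_weight_contrast(weights_mature, weights_immature) -> TTestReport:
    """Welch two-sample t-test of combined ovarian weight, mature vs immature."""
    a = np.asarray(weights_mature, dtype=float)
    b = np.asarray(weights_immature, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        degenerate = True
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        degenerate = False
    return TTestReport(float(t), float(p),
                       float(a.mean()), float(a.std(ddof=1) / np.sqrt(len(a))), len(a),
                       float(b.mean()), float(b.std(ddof=1) / np.sqrt(len(b))), len(b),
                       degenerate=degenerate)
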