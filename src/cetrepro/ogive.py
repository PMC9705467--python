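"""Maturity ogives: age/length at sexual maturity (ASM/LSM) and predictor comparison.

Two estimators of the average age (or total body length) at attainment of
sexual maturity:

* a Bayesian logistic regression in HOF parameterisation, whose midpoint
  ``m`` is the median age/length at maturity (the ogive's 50% point);
* the sum-of-fraction-immature (SOFI) estimator, a distribution-free method
  that anchors at the youngest class containing a mature female and adds the
  immature fractions of the overlap classes.

Age and length are compared as maturity predictors by leave-one-out ELPD on
a shared complete-case set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cetrepro.bayes import (
    ElpdComparison,
    HofPosterior,
    McmcConfig,
    PriorSpec,
    compare_elpd,
    exact_loo,
    fit_hof_logistic,
    hof_probability,
    psis_loo,
)
from cetrepro.records import Maturity, NecropsyRecord, classify_maturity

#: default priors: midpoint near the genus-typical maturation scale, slope
#: weakly constrained positive
AGE_PRIORS = PriorSpec(m_mean=8.0, m_sd=2.0, omega_sd=2.0)
TBL_PRIORS = PriorSpec(m_mean=190.0, m_sd=20.0, omega_sd=1.0)
DEFAULT_PRIORS = {"age": AGE_PRIORS, "tbl": TBL_PRIORS}


@dataclass
class MaturityOgive:
    """Fitted ogive for one predictor, with posterior summaries and diagnostics."""

    predictor: str                       # "age" or "tbl"
    posterior: HofPosterior
    n: int = field(init=False)
    n_mature: int = field(init=False)

    def __post_init__(self):
        self.n = len(self.posterior.x)
        self.n_mature = int(self.posterior.y.sum())

    @property
    def m_mean(self) -> float:
        return self.posterior.m_mean

    @property
    def m_median(self) -> float:
        return self.posterior.m_median

    @property
    def m_ci95(self) -> tuple[float, float]:
        return self.posterior.m_ci95

    @property
    def omega_mean(self) -> float:
        return self.posterior.omega_mean

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def predict(self, x) -> np.ndarray:
        """Posterior-mean maturity probability at x."""
        draws = self.posterior.draws
        x = np.atleast_1d(np.asarray(x, dtype=float))
        p = hof_probability(x[None, :], draws[:, 0][:, None], draws[:, 1][:, None])
        return p.mean(axis=0)

    def curve_data(self, x_grid) -> "np.ndarray":
        """(x, posterior-mean P, 2.5%, 97.5%) band for plotting/export."""
        draws = self.posterior.draws
        x_grid = np.asarray(x_grid, dtype=float)
        p = hof_probability(x_grid[None, :], draws[:, 0][:, None], draws[:, 1][:, None])
        lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
        return np.column_stack([x_grid, p.mean(axis=0), lo, hi])


def maturity_data(records: list[NecropsyRecord], predictor: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (x, y) for an ogive fit.

    Censored ages (lower bounds such as "≥9") are excluded — a bound is not a
    point value. Records with undetermined maturity are excluded.
    """
    xs, ys = [], []
    for r in records:
        mat = classify_maturity(r)
        if mat is Maturity.undetermined:
            continue
        if predictor == "age":
            if r.age_years is None or r.age_censored:
                continue
            xs.append(r.age_years)
        elif predictor == "tbl":
            if r.tbl_cm is None:
                continue
            xs.append(r.tbl_cm)
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        ys.append(1.0 if mat is Maturity.mature else 0.0)
    return np.asarray(xs), np.asarray(ys)


def fit_ogive(records: list[NecropsyRecord], predictor: str = "age",
              priors: PriorSpec | None = None,
              mcmc: McmcConfig | None = None) -> MaturityOgive:
    """Fit the Bayesian HOF ogive for ``predictor`` ("age" or "tbl").

    Requires at least one immature and one mature record with a usable
    (non-missing, non-censored) predictor value.
    """
    x, y = maturity_data(records, predictor)
    if len(x) == 0 or y.min() == y.max():
        raise ValueError(
            f"ogive fit needs both immature and mature records with {predictor} values "
            f"(got n={len(x)}, n_mature={int(y.sum()) if len(y) else 0})")
    priors = priors or DEFAULT_PRIORS[predictor]
    post = fit_hof_logistic(x, y, priors, mcmc)
    return MaturityOgive(predictor=predictor, posterior=post)


@dataclass
class SofiResult:
    estimate: float
    ci95: tuple[float, float]
    n: int
    bin_width: float
    degenerate: bool = False  # no immature/mature overlap zone


def _sofi_point(x: np.ndarray, mature: np.ndarray, bin_width: float,
                origin: float, anchor: str) -> float:
    bins = np.floor((x - origin) / bin_width).astype(int)
    mat_bins = bins[mature.astype(bool)]
    imm_bins = bins[~mature.astype(bool)]
    base = origin + (0.5 * bin_width if anchor == "mid" else 0.0)
    if len(mat_bins) == 0:
        raise ValueError("SOFI needs at least one mature record")
    alpha = mat_bins.min()
    if len(imm_bins) == 0 or imm_bins.max() < alpha:
        # perfect separation: the boundary between the classes
        return base + alpha * bin_width
    last = imm_bins.max()
    total = base + alpha * bin_width
    for j in range(alpha, last + 1):
        in_j = bins == j
        if in_j.any():
            total += bin_width * float((~mature.astype(bool))[in_j].mean())
    return total


def sofi_estimate(x, mature, bin_width: float = 1.0, origin: float = 0.0,
                  n_boot: int = 1000, seed: int = 0,
                  anchor: str = "lower") -> SofiResult:
    """Sum-of-fraction-immature estimate of the average age/length at maturity.

    ASM = (lower edge of the youngest class containing a mature female)
    + sum of immature fractions (× bin width) from that class through the
    oldest class containing an immature female. The CI is a seeded
    percentile bootstrap over records. ``anchor="mid"`` shifts the base to
    the class midpoint.
    """
    x = np.asarray(x, dtype=float)
    mature = np.asarray(mature)
    if anchor not in ("lower", "mid"):
        raise ValueError("anchor must be 'lower' or 'mid'")
    est = _sofi_point(x, mature, bin_width, origin, anchor)

    bins = np.floor((x - origin) / bin_width).astype(int)
    m_bins, i_bins = bins[mature.astype(bool)], bins[~mature.astype(bool)]
    degenerate = len(i_bins) == 0 or i_bins.max() < m_bins.min()
    if degenerate:
        warnings.warn("SOFI: no immature/mature overlap zone; estimate is the class "
                      "boundary and the CI is degenerate", RuntimeWarning)
        return SofiResult(est, (est, est), len(x), bin_width, degenerate=True)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(x)
    attempts = 0
    while len(boots) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        if mature[idx].any() and (~mature[idx].astype(bool)).any():
            boots.append(_sofi_point(x[idx], mature[idx], bin_width, origin, anchor))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return SofiResult(est, (float(lo), float(hi)), n, bin_width)


def sofi_from_records(records: list[NecropsyRecord], predictor: str = "age",
                      bin_width: float | None = None, **kw) -> SofiResult:
    """SOFI on records; default bins 1 yr for age, 10 cm for length."""
    x, y = maturity_data(records, predictor)
    if bin_width is None:
        bin_width = 1.0 if predictor == "age" else 10.0
    return sofi_estimate(x, y, bin_width=bin_width, **kw)


def complete_cases(records: list[NecropsyRecord]) -> list[NecropsyRecord]:
    """Records usable by *both* ogives: point age, TBL, determined maturity."""
    return [r for r in records
            if r.age_years is not None and not r.age_censored and r.tbl_cm is not None
            and classify_maturity(r) is not Maturity.undetermined]


def compare_predictors(records: list[NecropsyRecord], ogive_age: MaturityOgive,
                       ogive_tbl: MaturityOgive, mcmc: McmcConfig | None = None,
                       method: str = "auto", exact_threshold: int = 200) -> ElpdComparison:
    """Compare age vs length as maturity predictors by leave-one-out ELPD.

    Both ogives must have been fitted to the same complete-case records
    (checked case-for-case). The age model is the reference (score 0, SE 0);
    a negative ``elpd_diff`` means length predicts maturity worse than age.
    Exact refits are used up to ``exact_threshold`` cases, PSIS beyond.
    """
    xa, ya = maturity_data(records, "age")
    xt, yt = maturity_data(records, "tbl")
    if not (len(xa) == len(xt) == len(records)) or not np.array_equal(ya, yt):
        raise ValueError("compare_predictors requires a shared complete-case record set")
    if not (np.array_equal(ogive_age.posterior.x, xa) and np.array_equal(ogive_tbl.posterior.x, xt)):
        raise ValueError("ogives were not fitted to the supplied complete-case records")

    n = len(records)
    if method == "auto":
        method = "exact_loo" if n <= exact_threshold else "psis_loo"
    if method == "exact_loo":
        mc = mcmc or McmcConfig()
        lpd_age = exact_loo(xa, ya, ogive_age.posterior.priors, mc)
        lpd_tbl = exact_loo(xt, yt, ogive_tbl.posterior.priors, mc)
    elif method == "psis_loo":
        lpd_age, _ = psis_loo(ogive_age.posterior)
        lpd_tbl, _ = psis_loo(ogive_tbl.posterior)
    else:
        raise ValueError(f"unknown method {method!r}")
    return compare_elpd(lpd_age, lpd_tbl, method)
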