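"""Bayesian HOF-parameterised logistic regression and leave-one-out scoring.

The HOF parameterisation writes the logistic as

    P(y = 1 | x) = 1 / (1 + exp(-omega * (x - m)))

so the midpoint ``m`` (the x at which P = 0.5: the median age/length at
maturity, or the median length at birth) is a direct model parameter with an
interpretable prior: m ~ Normal(mu, sd), omega ~ half-Normal(sd) (a Normal
truncated at zero, so the curve is increasing).

Sampling uses an affine-invariant ensemble sampler (emcee). Walkers are
treated as chains for split-R-hat and effective-sample-size diagnostics.
Optional per-case weights multiply the log-likelihood (class-imbalance
weighting); they affect the posterior only, never the predictive density
used for leave-one-out scores.

Two leave-one-out ELPD routes are provided: exact brute-force refits (the
oracle, feasible at necropsy sample sizes) and Pareto-smoothed importance
sampling (PSIS) reusing a single posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from scipy.special import expit, logsumexp


@dataclass
class PriorSpec:
    """Priors for the HOF logistic: m ~ Normal(m_mean, m_sd), omega ~ half-Normal(omega_sd)."""

    m_mean: float
    m_sd: float
    omega_sd: float

    def __post_init__(self):
        if self.m_sd <= 0 or self.omega_sd <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcConfig:
    """Sampler settings. ``n_walkers`` ensemble members (each a diagnostic chain),
    ``n_steps`` post-warmup draws per walker, ``n_burn`` discarded warmup steps.

    Defaults give 16 chains x 1000 draws with differential-evolution moves,
    which on these 2-parameter logistic posteriors keeps split-R-hat well
    under 1.01 at a fraction of a second per fit.
    """

    n_walkers: int = 16
    n_steps: int = 1500
    n_burn: int = 750
    seed: int = 0

    def scaled(self, factor: float) -> "McmcConfig":
        return McmcConfig(self.n_walkers, max(100, int(self.n_steps * factor)),
                          max(100, int(self.n_burn * factor)), self.seed)


@dataclass
class HofPosterior:
    """Posterior draws and summaries for one HOF logistic fit."""

    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None
    priors: PriorSpec
    chain: np.ndarray                      # (n_walkers, n_steps, 2): [m, omega]
    m_mean: float = field(init=False)
    m_median: float = field(init=False)
    m_ci95: tuple[float, float] = field(init=False)
    m_hdi95: tuple[float, float] = field(init=False)
    omega_mean: float = field(init=False)
    rhat: dict = field(init=False)
    ess: dict = field(init=False)
    converged: bool = field(init=False)

    def __post_init__(self):
        m = self.chain[:, :, 0].ravel()
        om = self.chain[:, :, 1].ravel()
        self.m_mean = float(m.mean())
        self.m_median = float(np.median(m))
        self.m_ci95 = tuple(np.percentile(m, [2.5, 97.5]))
        self.m_hdi95 = _hpd_interval(m, 0.95)
        self.omega_mean = float(om.mean())
        idata = az.from_dict(posterior={"m": self.chain[:, :, 0], "omega": self.chain[:, :, 1]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rh, es = az.rhat(idata), az.ess(idata)
        self.rhat = {k: float(rh[k]) for k in ("m", "omega")}
        self.ess = {k: float(es[k]) for k in ("m", "omega")}
        self.converged = max(self.rhat.values()) < 1.01
        if not self.converged:
            warnings.warn(
                f"HOF logistic MCMC may not have converged (split-Rhat {self.rhat}); "
                "result returned and flagged", RuntimeWarning)

    @property
    def draws(self) -> np.ndarray:
        """Flattened (n_draws, 2) posterior draws of (m, omega)."""
        return self.chain.reshape(-1, 2)


def _hpd_interval(draws: np.ndarray, prob: float) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws (highest posterior density)."""
    s = np.sort(draws)
    k = int(np.ceil(prob * len(s)))
    widths = s[k - 1:] - s[:len(s) - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def hof_probability(x, m, omega):
    """P(y=1 | x) = 1/(1+exp(-omega (x - m))), numerically saturating at the extremes."""
    return expit(np.asarray(omega, dtype=float) * (np.asarray(x, dtype=float) - m))


def _log_posterior_factory(x, y, w, priors: PriorSpec):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    s = np.where(y >= 0.5, -1.0, 1.0)  # sign so that loglik_i = -log(1+exp(s*eta))

    def log_post(theta):
        theta = np.atleast_2d(theta)
        m, om = theta[:, 0], theta[:, 1]
        lp = -0.5 * ((m - priors.m_mean) / priors.m_sd) ** 2
        lp = np.where(om > 0, lp - 0.5 * (om / priors.omega_sd) ** 2, -np.inf)
        if x.size:
            ok = om > 0
            eta = om[:, None] * (x[None, :] - m[:, None])
            ll = -(w[None, :] * np.logaddexp(0.0, s[None, :] * eta)).sum(axis=1)
            lp = np.where(ok, lp + np.where(np.isfinite(lp), ll, 0.0), -np.inf)
        return lp

    return log_post


def fit_hof_logistic(x, y, priors: PriorSpec, mcmc: McmcConfig | None = None,
                     weights=None) -> HofPosterior:
    """Sample the HOF logistic posterior.

    ``x`` predictor values, ``y`` binary outcomes (may be empty for
    prior-only sampling), optional per-case ``weights`` multiplying the
    log-likelihood. Complete separation is fine — the priors regularise.
    """
    mcmc = mcmc or McmcConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    log_post = _log_posterior_factory(x, y, weights, priors)

    rng = np.random.default_rng(mcmc.seed)
    p0 = np.column_stack([
        priors.m_mean + 0.5 * priors.m_sd * rng.standard_normal(mcmc.n_walkers),
        np.abs(0.5 * priors.omega_sd * rng.standard_normal(mcmc.n_walkers)) + 0.05 * priors.omega_sd,
    ])
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(mcmc.n_walkers, 2, log_post, vectorize=True, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(mcmc.seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler.run_mcmc(state, mcmc.n_burn + mcmc.n_steps, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=mcmc.n_burn)  # (steps, walkers, 2)
    return HofPosterior(x=x, y=y, weights=None if weights is None else np.asarray(weights, float),
                        priors=priors, chain=np.transpose(chain, (1, 0, 2)))


def pointwise_loglik(draws: np.ndarray, x, y) -> np.ndarray:
    """Unweighted log p(y_i | m, omega) for each draw: shape (n_draws, n_obs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, om = draws[:, 0][:, None], draws[:, 1][:, None]
    s = np.where(y >= 0.5, -1.0, 1.0)
    return -np.logaddexp(0.0, s[None, :] * (om * (x[None, :] - m)))


def psis_loo(fit: HofPosterior) -> tuple[np.ndarray, np.ndarray]:
    """PSIS-LOO pointwise ELPD and Pareto k-hats from a single posterior."""
    ll = pointwise_loglik(fit.draws, fit.x, fit.y)  # (draws, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, khat = az.psislw(-ll.T)  # expects (n_obs, n_draws)
    elpd_i = logsumexp(lw + ll.T, axis=1)
    return elpd_i, np.asarray(khat)


def exact_loo(x, y, priors: PriorSpec, mcmc: McmcConfig | None = None,
              weights_fn=None, refit_factor: float = 0.6) -> np.ndarray:
    """Exact leave-one-out pointwise ELPD by brute-force refits.

    ``weights_fn(y_subset) -> weights`` recomputes case weights on each
    reduced dataset (None for unweighted fits). Refits use ``refit_factor``
    of the configured draws — LOO predictive means are far less demanding
    than posterior tail quantiles.
    """
    mcmc = mcmc or McmcConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    elpd = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sub = mcmc.scaled(refit_factor)
        sub.seed = mcmc.seed + 1 + i
        w = None if weights_fn is None else weights_fn(y[keep])
        fit = fit_hof_logistic(x[keep], y[keep], priors, sub, weights=w)
        ll_i = pointwise_loglik(fit.draws, x[i:i + 1], y[i:i + 1])[:, 0]
        elpd[i] = logsumexp(ll_i) - np.log(ll_i.size)
    return elpd


@dataclass
class ElpdComparison:
    """ELPD difference between a reference model and an alternative.

    Positive per-point values favour the reference; ``elpd_diff`` =
    ELPD(alt) - ELPD(ref), so the reference scores (0, SE 0) and a worse
    alternative scores negative (matching the usual reporting convention).
    """

    elpd_ref: float
    elpd_alt: float
    elpd_diff: float
    se_diff: float
    per_point_lpd: np.ndarray  # lpd_ref_i - lpd_alt_i
    method: str                # "exact_loo" or "psis_loo"


def compare_elpd(lpd_ref: np.ndarray, lpd_alt: np.ndarray, method: str) -> ElpdComparison:
    lpd_ref = np.asarray(lpd_ref, float)
    lpd_alt = np.asarray(lpd_alt, float)
    if lpd_ref.shape != lpd_alt.shape:
        raise ValueError("pointwise ELPD vectors must align case-for-case")
    diff_i = lpd_alt - lpd_ref
    n = len(diff_i)
    se = float(np.sqrt(n * diff_i.var(ddof=1))) if n > 1 else 0.0
    return ElpdComparison(
        elpd_ref=float(lpd_ref.sum()), elpd_alt=float(lpd_alt.sum()),
        elpd_diff=float(diff_i.sum()), se_diff=se,
        per_point_lpd=lpd_ref - lpd_alt, method=method)
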