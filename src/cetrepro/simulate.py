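"""Synthetic stranding/bycatch population generator with a known truth ledger.

Emulates an opportunistically sampled female delphinid necropsy dataset so
every estimator in the pipeline can be validated by parameter recovery:

* ages follow a geometric-like decay (calibrated so ~83% of females are 15
  or younger, the shape typical of stranding samples);
* each female draws a latent maturation-onset age from a logistic
  distribution with location ``true_asm_m`` and scale 1/``true_asm_omega``,
  so P(mature | age) is exactly the HOF ogive;
* growth is linear through the first year (first-year rate = length at one
  year minus length at birth) and then approaches the asymptotic length
  exponentially, calibrated to pass through the length at maturity at the
  age at maturity;
* mature females sit at a uniform phase of a pregnant -> lactating ->
  resting cycle of configurable phase lengths (equal by default, the
  steady-state behind the t_l = t_g x l/p estimators);
* conception days-of-year are von Mises distributed; the default
  concentration makes seasonality weak (~59% of births in Aug-Dec);
* foetal length grows linearly after a nonlinear lag t0, reaching the
  female's own birth length at term;
* corpora accumulate as 1 + Poisson(rate x years since onset) and are
  allocated to the left ovary with probability ``left_bias``.

Identical seed + config give byte-identical record sets.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from cetrepro.gestation import DAYS_PER_MONTH, NONLINEAR_RATIO
from cetrepro.records import Decomposition, EventType, FoetusSex, NecropsyRecord


@dataclass
class SyntheticConfig:
    """True parameter set driving the simulator. Defaults are the study conditions."""

    seed: int = 0
    n_females: int = 106
    true_asm_m: float = 7.5            # ogive midpoint, years
    true_asm_omega: float = 1.5        # ogive slope, /year
    true_lsm_m: float = 183.5          # length at maturity, cm (calibrates growth)
    tg_days: float = 384.0
    lb_cm: float = 87.6
    lb_sd_cm: float = 4.5              # between-female spread in birth length
    nonlinear_ratio: float = NONLINEAR_RATIO
    cycle_months: tuple[float, float, float] = (12.6, 12.6, 12.6)  # pregnant, lactating, resting
    conception_peak_doy: float = 280.0  # early October
    kappa: float = 0.56                # von Mises concentration; 0 = uniform
    corpora_rate_per_year: float = 0.3924
    left_bias: float = 97.0 / 123.0
    max_age: int = 29
    age_frac_le15: float = 0.83        # calibrates the age-decay rate
    asymptotic_length_cm: float = 201.7
    first_year_growth_f: float = 46.0  # cm/yr; length at 1 yr = lb + this
    first_year_growth_m: float = 52.2
    frac_simultaneous: float = 0.07    # pregnant females also lactating
    length_noise_sd: float = 4.0
    bycatch_prob: float = 9.0 / 106.0
    year_range: tuple[int, int] = (1997, 2019)
    p_missing_age: float = 0.05
    p_censored_age: float = 0.01
    p_missing_ovaries: float = 0.05
    p_cl_nonpregnant: float = 0.12     # recent infertile ovulation leaves a CL

    def __post_init__(self):
        if self.n_females < 1:
            raise ValueError("n_females must be positive")
        if not (0 <= self.left_bias <= 1):
            raise ValueError("left_bias must be a probability")
        if self.kappa < 0 or self.corpora_rate_per_year < 0:
            raise ValueError("rates must be non-negative")
        if self.lb_cm >= self.lb_cm + min(self.first_year_growth_f, self.first_year_growth_m):
            raise ValueError("first-year growth must be positive")
        if self.lb_cm + self.first_year_growth_f >= self.asymptotic_length_cm:
            raise ValueError("length at one year must be below the asymptotic length")
        if self.true_lsm_m <= self.lb_cm + self.first_year_growth_f:
            raise ValueError("length at maturity must exceed the length at one year")

    @property
    def t0_days(self) -> float:
        return self.tg_days * self.nonlinear_ratio / (1.0 + self.nonlinear_ratio)

    @property
    def cycle_total_months(self) -> float:
        return sum(self.cycle_months)


def _age_decay_rate(cfg: SyntheticConfig) -> float:
    """Per-year geometric decay r with P(age <= 15) = cfg.age_frac_le15 on 0..max_age."""
    target = cfg.age_frac_le15

    def f(r):
        return (1 - r ** 16) / (1 - r ** (cfg.max_age + 1)) - target

    return brentq(f, 1e-6, 0.999999)


def _growth_k(cfg: SyntheticConfig) -> float:
    """Post-first-year growth constant so the curve passes through (ASM, LSM)."""
    linf = cfg.asymptotic_length_cm
    l1 = cfg.lb_cm + cfg.first_year_growth_f
    return math.log((linf - l1) / (linf - cfg.true_lsm_m)) / (cfg.true_asm_m - 1.0)


def expected_length(age: float, cfg: SyntheticConfig, lb_i: float | None = None) -> float:
    """Noise-free female length at age: linear first year, then exponential approach."""
    lb = cfg.lb_cm if lb_i is None else lb_i
    if age < 1.0:
        return lb + cfg.first_year_growth_f * age
    linf = cfg.asymptotic_length_cm
    l1 = lb + cfg.first_year_growth_f
    return linf - (linf - l1) * math.exp(-_growth_k(cfg) * (age - 1.0))


def _doy_to_date(year: int, doy: float) -> _dt.date:
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(round(doy)) - 1)


def simulate_population(config: SyntheticConfig) -> tuple[list[NecropsyRecord], pd.DataFrame]:
    """Generate necropsy records plus a per-individual truth ledger.

    The ledger records each female's latent truth: exact age, maturation
    onset, cycle phase, conception date of the current/most recent
    pregnancy, and her individual birth length.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    decay = _age_decay_rate(cfg)
    probs = decay ** np.arange(cfg.max_age + 1)
    probs /= probs.sum()
    phase_days = np.array(cfg.cycle_months) * DAYS_PER_MONTH
    cycle_days = phase_days.sum()
    mu = 2 * math.pi * (cfg.conception_peak_doy / 365.0)

    records: list[NecropsyRecord] = []
    truths: list[dict] = []
    for i in range(cfg.n_females):
        rid = f"SIM{i:04d}"
        age_class = int(rng.choice(cfg.max_age + 1, p=probs))
        # neonatal-mortality peak: deaths in the first year concentrate near birth
        frac = float(rng.beta(0.6, 2.5)) if age_class == 0 else float(rng.uniform())
        age = age_class + frac
        onset = float(rng.logistic(cfg.true_asm_m, 1.0 / cfg.true_asm_omega))
        mature = age >= onset
        lb_i = float(rng.normal(cfg.lb_cm, cfg.lb_sd_cm))
        tbl = max(lb_i * 0.9, expected_length(age, cfg, lb_i) + rng.normal(0, cfg.length_noise_sd))

        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        phase_name = "immature"
        foetus_len = None
        foetus_sex = None
        lactating: bool | None = False
        cl = False
        cl_diam = None
        conception_date = None
        foetal_age = None

        # seasonal conception day-of-year: the female's own conception when
        # immature (anchoring her strand date via her age), the conception of
        # her current cycle when mature
        if cfg.kappa > 0:
            theta = float(rng.vonmises(mu, cfg.kappa))
        else:
            theta = float(rng.uniform(-math.pi, math.pi))
        cdoy = (theta / (2 * math.pi)) * 365.0 % 365.0
        conception_date = _doy_to_date(year, cdoy + 1)

        if mature:
            u = float(rng.uniform(0, cycle_days))
            if u < phase_days[0]:
                phase_name = "pregnant"
                foetal_age = u
                slope = lb_i / (cfg.tg_days - cfg.t0_days)  # cm/day, linear phase
                foetus_len = max(0.5, slope * (foetal_age - cfg.t0_days))
                foetus_sex = FoetusSex.F if rng.uniform() < 0.5 else FoetusSex.M
                cl = True
                cl_diam = float(rng.uniform(16, 36))
                lactating = bool(rng.uniform() < cfg.frac_simultaneous)
                strand = conception_date + _dt.timedelta(days=round(foetal_age))
            elif u < phase_days[0] + phase_days[1]:
                phase_name = "lactating"
                lactating = True
                since_birth = u - phase_days[0]
                if rng.uniform() < cfg.p_cl_nonpregnant:
                    cl, cl_diam = True, float(rng.uniform(10, 20))
                strand = conception_date + _dt.timedelta(days=round(cfg.tg_days + since_birth))
            else:
                phase_name = "resting"
                since_wean = u - phase_days[0] - phase_days[1]
                if rng.uniform() < cfg.p_cl_nonpregnant:
                    cl, cl_diam = True, float(rng.uniform(6, 12))
                strand = conception_date + _dt.timedelta(
                    days=round(cfg.tg_days + phase_days[1] + since_wean))
            corpora_total = 1 + int(rng.poisson(cfg.corpora_rate_per_year * max(0.0, age - onset)))
        else:
            # stranded at (own conception) + gestation + age
            strand = conception_date + _dt.timedelta(days=round(cfg.tg_days + age * 365.25))
            corpora_total = 0

        corp_left = int(rng.binomial(corpora_total, cfg.left_bias)) if corpora_total else 0
        corp_right = corpora_total - corp_left

        if mature:
            ow = max(1.0, float(rng.normal(8.7, 4.0)))
        else:
            ow = max(0.3, float(rng.normal(2.5, 1.5)))
        left_share = float(np.clip(rng.normal(0.55, 0.05), 0.35, 0.75))

        rec = NecropsyRecord(
            id=rid,
            event_date=strand,
            event_type=EventType.bycatch if rng.uniform() < cfg.bycatch_prob else EventType.stranding,
            tbl_cm=round(tbl * 2) / 2,  # measured to the nearest 0.5 cm
            age_years=round(age * 4) / 4,
            age_censored=False,
            corpora_left=corp_left,
            corpora_right=corp_right,
            cl_left=cl,
            cl_right=False,
            cl_diameter_mm=round(cl_diam, 1) if cl_diam is not None else None,
            ovary_weight_left_g=round(ow * left_share, 1),
            ovary_weight_right_g=round(ow * (1 - left_share), 1),
            lactating=lactating,
            foetus_tbl_cm=round(foetus_len, 1) if foetus_len is not None else None,
            foetus_sex=foetus_sex,
            largest_follicle_mm=round(float(rng.uniform(1, 7)), 1) if (mature and rng.uniform() < 0.3) else None,
            decomposition=Decomposition(["fresh", "mild", "moderate"][int(rng.integers(3))]),
        )
        # opportunistic missingness
        if rng.uniform() < cfg.p_missing_age:
            rec.age_years = None
        elif mature and rng.uniform() < cfg.p_censored_age:
            rec.age_years = float(math.floor(min(age, 9.0)))
            rec.age_censored = True
        if rng.uniform() < cfg.p_missing_ovaries:
            rec.ovary_weight_left_g = rec.ovary_weight_right_g = None

        records.append(rec)
        truths.append({
            "id": rid, "true_age": age, "onset_age": onset, "mature": mature,
            "phase": phase_name, "true_tbl": tbl, "lb_i": lb_i,
            "conception_date": conception_date, "foetal_age_days": foetal_age,
            "corpora_total": corpora_total,
        })

    return records, pd.DataFrame(truths)


def true_parameters(cfg: SyntheticConfig) -> dict[str, float]:
    """The generator's headline truths, keyed like the pipeline's estimates."""
    tg_months = cfg.tg_days / DAYS_PER_MONTH
    g, l, r = cfg.cycle_months
    p = g / cfg.cycle_total_months
    return {
        "asm_years": cfg.true_asm_m,
        "lsm_cm": cfg.true_lsm_m,
        "lb_cm": cfg.lb_cm,
        "tg_days": cfg.tg_days,
        "apr_per_year": p / (tg_months / 12.0),
        "ovulation_rate_per_year": cfg.corpora_rate_per_year,
    }


def truth_recovery_report(truth: dict[str, float],
                          estimates: dict[str, tuple[float, float, float] | None]) -> pd.DataFrame:
    """Truth vs estimate table with interval-coverage flags.

    ``estimates`` maps parameter name -> (point, lo, hi) or None; a missing
    or None estimate is flagged absent rather than dropped.
    """
    rows = []
    for name, tv in truth.items():
        est = estimates.get(name)
        if est is None:
            rows.append({"parameter": name, "truth": tv, "estimate": np.nan,
                         "lo": np.nan, "hi": np.nan, "covered": False, "absent": True})
        else:
            point, lo, hi = est
            rows.append({"parameter": name, "truth": tv, "estimate": point,
                         "lo": lo, "hi": hi, "covered": bool(lo <= tv <= hi),
                         "absent": False})
    return pd.DataFrame(rows)
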