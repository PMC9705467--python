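"""Life-history rates: lactation/resting periods, weaning length, APR, calving interval.

These estimators compose the gestation period with the observed proportions
of mature females in each reproductive phase, under steady-state sampling:

* lactation period  t_l = t_g x l/p
* resting period    t_r = t_g x r/p
* annual pregnancy rate  APR = p / t_g(years)
* calving interval: 1/APR (reciprocal) or t_g + t_l + t_r (summation), the
  lactation term adjusted downward by the fraction of females simultaneously
  pregnant and lactating (the overlap between the two phases),

where p is the proportion of the mature sample pregnant (including females
simultaneously pregnant and lactating), l the proportion lactating and r the
proportion resting. Length at weaning uses the cross-cetacean allometry
L_w = 1.2399 L_x^0.877 on the female asymptotic length L_x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from cetrepro.gestation import GestationEstimate
from cetrepro.records import NecropsyRecord, ReproductiveClass, classify_records


@dataclass
class MatureSampleProportions:
    """Phase counts for the mature sample and the derived proportions."""

    n_mature: int
    n_pregnant_only: int
    n_lactating_only: int
    n_resting: int
    n_pregnant_and_lactating: int
    p_count_override: int | None = None  # pregnant count to use for p, if the
    # source tabulation groups classes differently from this package

    def __post_init__(self):
        parts = (self.n_pregnant_only + self.n_lactating_only + self.n_resting
                 + self.n_pregnant_and_lactating)
        if self.n_mature < parts:
            raise ValueError("phase counts exceed the mature total")

    @property
    def n_pregnant_incl_pl(self) -> int:
        if self.p_count_override is not None:
            return self.p_count_override
        return self.n_pregnant_only + self.n_pregnant_and_lactating

    @property
    def p(self) -> float:
        """Proportion pregnant, including simultaneously pregnant and lactating."""
        return self.n_pregnant_incl_pl / self.n_mature

    @property
    def l(self) -> float:
        """Proportion lactating (lactating-only plus simultaneous)."""
        return (self.n_lactating_only + self.n_pregnant_and_lactating) / self.n_mature

    @property
    def r(self) -> float:
        return self.n_resting / self.n_mature

    @property
    def frac_simultaneous(self) -> float:
        return self.n_pregnant_and_lactating / self.n_mature

    @classmethod
    def from_records(cls, records: list[NecropsyRecord],
                     p_count_override: int | None = None) -> "MatureSampleProportions":
        counts = classify_records(records)["repro_class"].value_counts()
        get = lambda c: int(counts.get(c.value, 0))
        n_mature = sum(get(c) for c in ReproductiveClass if c is not ReproductiveClass.immature)
        return cls(n_mature=n_mature,
                   n_pregnant_only=get(ReproductiveClass.pregnant),
                   n_lactating_only=get(ReproductiveClass.lactating),
                   n_resting=get(ReproductiveClass.resting_mature),
                   n_pregnant_and_lactating=get(ReproductiveClass.pregnant_lactating),
                   p_count_override=p_count_override)


def lactation_period(tg_months: float, l: float, p: float) -> float:
    """t_l = t_g x l/p (months)."""
    if p <= 0:
        raise ValueError("lactation period is undefined when no females are pregnant")
    return tg_months * l / p


def resting_period(tg_months: float, r: float, p: float) -> float:
    """t_r = t_g x r/p (months)."""
    if p <= 0:
        raise ValueError("resting period is undefined when no females are pregnant")
    return tg_months * r / p


def weaning_length(asymptotic_length_cm: float) -> float:
    """L_w = 1.2399 L_x^0.877 (cm), from the cross-cetacean weaning allometry."""
    if asymptotic_length_cm <= 0:
        raise ValueError("asymptotic length must be positive")
    return 1.2399 * asymptotic_length_cm ** 0.877


def annual_pregnancy_rate(p: float, tg_years: float) -> float:
    """APR = p / t_g with gestation in years; fraction of mature females per year."""
    if tg_years <= 0:
        raise ValueError("gestation must be positive")
    return p / tg_years


@dataclass
class CalvingInterval:
    reciprocal_years: float
    summation_months: float             # lactation adjusted downward by the
    # simultaneous-pregnancy fraction
    summation_unadjusted_months: float  # plain t_g + t_l + t_r

    @property
    def summation_years(self) -> float:
        return self.summation_months / 12.0


def calving_interval(apr: float, tg_months: float, tl_months: float, tr_months: float,
                     frac_simultaneous: float = 0.0) -> CalvingInterval:
    """Both calving-interval estimates.

    Reciprocal: 1/APR (years). Summation: t_g + t_l x (1 - f) + t_r (months),
    where f is the fraction of mature females simultaneously pregnant and
    lactating; the unadjusted sum is also returned for comparison with
    tabulations that skip the adjustment.
    """
    if apr <= 0:
        raise ValueError("reciprocal calving interval is undefined for APR <= 0")
    adj = tg_months + tl_months * (1.0 - frac_simultaneous) + tr_months
    return CalvingInterval(reciprocal_years=1.0 / apr, summation_months=adj,
                           summation_unadjusted_months=tg_months + tl_months + tr_months)


DEFAULT_EXCLUSION_MONTHS = (8, 9, 10, 11)  # austral peak calving, Aug-Nov


def seasonal_exclusion(records: list[NecropsyRecord],
                       months=DEFAULT_EXCLUSION_MONTHS) -> list[NecropsyRecord]:
    """Drop records sampled in the given calendar months (peak-calving filter).

    Used to recompute the pregnant proportion without the season in which
    early pregnancies are most likely to be missed.
    """
    months = set(months)
    return [r for r in records if r.event_date.month not in months]


@dataclass
class LifeHistoryRates:
    """Composed life-history rates for one gestation estimate."""

    gestation: GestationEstimate
    proportions: MatureSampleProportions
    t_l_months: float = field(init=False)
    t_r_months: float = field(init=False)
    apr: float = field(init=False)
    raw_pregnant_proportion: float = field(init=False)
    ci: CalvingInterval = field(init=False)
    weaning_length_cm: float | None = None

    def __post_init__(self):
        g, pr = self.gestation, self.proportions
        self.t_l_months = lactation_period(g.tg_months, pr.l, pr.p)
        self.t_r_months = resting_period(g.tg_months, pr.r, pr.p)
        self.apr = annual_pregnancy_rate(pr.p, g.tg_years)
        self.raw_pregnant_proportion = pr.p
        self.ci = calving_interval(self.apr, g.tg_months, self.t_l_months,
                                   self.t_r_months, pr.frac_simultaneous)

    def as_row(self) -> dict:
        return {
            "gestation_method": self.gestation.method,
            "tg_months": self.gestation.tg_months,
            "p": self.proportions.p,
            "l": self.proportions.l,
            "r": self.proportions.r,
            "frac_simultaneous": self.proportions.frac_simultaneous,
            "lactation_months": self.t_l_months,
            "resting_months": self.t_r_months,
            "apr": self.apr,
            "ci_reciprocal_years": self.ci.reciprocal_years,
            "ci_summation_months": self.ci.summation_months,
            "ci_summation_unadjusted_months": self.ci.summation_unadjusted_months,
            "weaning_length_cm": self.weaning_length_cm,
        }


def compute_life_history_rates(proportions: MatureSampleProportions,
                               gestations: list[GestationEstimate],
                               asymptotic_length_cm: float | None = None) -> pd.DataFrame:
    """Rates table with one row per gestation-method variant."""
    lw = weaning_length(asymptotic_length_cm) if asymptotic_length_cm else None
    rows = []
    for g in gestations:
        lhr = LifeHistoryRates(gestation=g, proportions=proportions, weaning_length_cm=lw)
        rows.append(lhr.as_row())
    return pd.DataFrame(rows)
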