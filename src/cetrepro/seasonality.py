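"""Reproductive seasonality: conception/birth back-calculation and seasonal tallies.

A foetus of length L_t is aged as t = (L_t/u) x 30.5 + t0 days, where u is
the mean foetal growth rate (cm/month) and t0 the brief nonlinear growth
phase. A yearling calf is aged as t = (L_t - L_b) / (u/30.5) days, with L_b
the length at birth and u the sex-specific first-year growth rate converted
to cm/month. (As a growth equation the calf formula only makes sense with
the subtraction grouped before the division; the literature sometimes
prints it with ambiguous bracketing.) Conception and birth dates follow by
subtracting/adding ages and the gestation length on the real calendar;
summaries use austral seasons (spring Sep-Nov, summer Dec-Feb, autumn
Mar-May, winter Jun-Aug).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cetrepro.gestation import DAYS_PER_MONTH, GestationEstimate
from cetrepro.records import NecropsyRecord

AUSTRAL_SEASONS = {
    "spring": (9, 10, 11),
    "summer": (12, 1, 2),
    "autumn": (3, 4, 5),
    "winter": (6, 7, 8),
}


def austral_season(month: int) -> str:
    for name, months in AUSTRAL_SEASONS.items():
        if month in months:
            return name
    raise ValueError(f"invalid month {month}")


@dataclass
class BackCalcParams:
    """Growth constants for conception/birth back-calculation.

    First-year calf growth rates are the sex-specific length-at-one-year
    minus the length at birth (cm/year).
    """

    u_foetal_cm_per_month: float
    t0_days: float
    lb_cm: float
    tg_days: float
    length_at_1yr_female_cm: float = 133.6
    length_at_1yr_male_cm: float = 139.8
    days_per_month: float = DAYS_PER_MONTH

    def __post_init__(self):
        if min(self.u_foetal_cm_per_month, self.lb_cm, self.tg_days) <= 0 or self.t0_days < 0:
            raise ValueError("growth parameters must be positive (t0 non-negative)")
        if self.length_at_1yr_female_cm <= self.lb_cm or self.length_at_1yr_male_cm <= self.lb_cm:
            raise ValueError("length at one year must exceed length at birth")

    @property
    def u_calf_female_cm_per_year(self) -> float:
        return self.length_at_1yr_female_cm - self.lb_cm

    @property
    def u_calf_male_cm_per_year(self) -> float:
        return self.length_at_1yr_male_cm - self.lb_cm

    @classmethod
    def from_gestation(cls, g: GestationEstimate, **kw) -> "BackCalcParams":
        return cls(u_foetal_cm_per_month=g.u_cm_per_month, t0_days=g.t0_days,
                   lb_cm=g.lb_cm, tg_days=g.tg_days, **kw)


def foetal_age_days(L_t: float, params: BackCalcParams) -> float:
    """Foetal age t = (L_t/u) x 30.5 + t0 days."""
    if L_t <= 0:
        raise ValueError("foetal length must be positive")
    return (L_t / params.u_foetal_cm_per_month) * params.days_per_month + params.t0_days


def calf_age_days(L_t: float, sex: str, params: BackCalcParams) -> float:
    """Calf age t = (L_t - L_b) / (u/30.5) days, with the sex-specific monthly rate u."""
    if L_t < params.lb_cm:
        raise ValueError("calf length below the length at birth")
    annual = {"F": params.u_calf_female_cm_per_year,
              "M": params.u_calf_male_cm_per_year}[sex]
    u_monthly = annual / 12.0
    return (L_t - params.lb_cm) / (u_monthly / params.days_per_month)


def is_yearling(rec: NecropsyRecord, params: BackCalcParams, sex: str = "F") -> bool:
    """Yearling: aged < 1 year when an age reading exists, else TBL at or
    below the sex-specific length at one year."""
    if rec.age_years is not None and not rec.age_censored:
        return rec.age_years < 1.0
    limit = (params.length_at_1yr_female_cm if sex == "F"
             else params.length_at_1yr_male_cm)
    return rec.tbl_cm is not None and params.lb_cm <= rec.tbl_cm <= limit


def event_dates(rec: NecropsyRecord, params: BackCalcParams,
                tg_days: float | None = None,
                calf_sex: str = "F") -> tuple[_dt.date, _dt.date]:
    """Back-calculated (conception date, birth date) for one record.

    A record with a foetus dates the foetus: conception = strand date - t,
    birth = conception + t_g. A yearling dates itself: birth = strand date
    - t, conception = birth - t_g. Ages are rounded to whole days and dates
    live on the real calendar (leap years included). The records here are
    necropsied females, so yearlings use the female growth rate unless
    ``calf_sex`` says otherwise.
    """
    if rec.event_date is None:
        raise ValueError("record has no strand/bycatch date")
    tg = params.tg_days if tg_days is None else tg_days
    if rec.foetus_tbl_cm is not None:
        t = foetal_age_days(rec.foetus_tbl_cm, params)
        conception = rec.event_date - _dt.timedelta(days=round(t))
        birth = conception + _dt.timedelta(days=round(tg))
    elif is_yearling(rec, params, calf_sex):
        t = calf_age_days(rec.tbl_cm, calf_sex, params)
        birth = rec.event_date - _dt.timedelta(days=round(t))
        conception = birth - _dt.timedelta(days=round(tg))
    else:
        raise ValueError(f"record {rec.id} is neither pregnant nor a yearling")
    return conception, birth


@dataclass
class SeasonalSummary:
    monthly_counts: np.ndarray                  # 12-vector, Jan..Dec
    seasonal_proportions: dict[str, float]      # austral seasons
    peak_months: list[int]                      # 1-based months at the max count
    n: int = field(init=False)

    def __post_init__(self):
        self.n = int(self.monthly_counts.sum())


def seasonal_summary(dates: list[_dt.date]) -> SeasonalSummary:
    """Monthly histogram and austral-season proportions for dated events."""
    if not dates:
        raise ValueError("at least one dated event is required")
    months = np.array([d.month for d in dates])
    counts = np.bincount(months, minlength=13)[1:]
    props = {s: float(sum(counts[m - 1] for m in ms)) / len(dates)
             for s, ms in AUSTRAL_SEASONS.items()}
    peak = (np.flatnonzero(counts == counts.max()) + 1).tolist()
    return SeasonalSummary(monthly_counts=counts, seasonal_proportions=props,
                           peak_months=peak)


def ovulating_flags(records: list[NecropsyRecord]) -> pd.DataFrame:
    """Likely-ovulating flag (CL present, no detectable foetus) per female.

    Returns id, flag, and the austral season of the strand date, for tallying
    ovulation evidence through the year.
    """
    rows = []
    for r in records:
        flag = bool(r.cl_present) and r.foetus_tbl_cm is None
        rows.append({"id": r.id, "ovulating": flag,
                     "season": austral_season(r.event_date.month)})
    return pd.DataFrame(rows)


def ovulating_seasonal_counts(records: list[NecropsyRecord]) -> dict[str, int]:
    df = ovulating_flags(records)
    out = {s: 0 for s in AUSTRAL_SEASONS}
    for _, row in df[df["ovulating"]].iterrows():
        out[row["season"]] += 1
    return out
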