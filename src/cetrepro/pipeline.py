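"""End-to-end analysis pipeline: classify -> ogives -> gestation -> rates -> seasonality.

One :class:`RunConfig` (a CSV of necropsy records or a synthetic-population
config, method variants, a root seed and an output directory) drives the
whole analysis and produces a report bundle: a classification summary,
ogive posteriors, a gestation table with both methods, a rates table with
one row per gestation variant, seasonal histograms, the ovarian analysis
report, and a machine-readable JSON of the headline numbers. All
randomness flows from the root seed via deterministically derived
per-stage seeds, so re-running a config reproduces the JSON exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import cetrepro
from cetrepro.bayes import McmcConfig
from cetrepro.gestation import (
    assign_cohorts,
    fit_birth_length,
    gestation_huggett_widdas,
    gestation_perrin_regression,
)
from cetrepro.ogive import compare_predictors, complete_cases, fit_ogive, sofi_from_records
from cetrepro.ovaries import (
    asymmetry_test,
    cl_vs_foetus,
    ovary_weight_contrast,
    ovulation_rate,
    persistence_regressions,
)
from cetrepro.rates import (
    DEFAULT_EXCLUSION_MONTHS,
    MatureSampleProportions,
    annual_pregnancy_rate,
    compute_life_history_rates,
    seasonal_exclusion,
)
from cetrepro.records import (
    Maturity,
    NecropsyRecord,
    classify_maturity,
    classify_records,
    read_records,
    summarize_by_class,
)
from cetrepro.seasonality import (
    BackCalcParams,
    event_dates,
    is_yearling,
    ovulating_seasonal_counts,
    seasonal_summary,
)
from cetrepro.simulate import SyntheticConfig, simulate_population

log = logging.getLogger("cetrepro")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Exactly one input source: a records CSV or a synthetic config."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    schema_config: dict | str | None = None
    gestation_method: str = "both"         # "both" | "huggett_widdas" | "perrin_regression"
    weight_scheme: str = "sqrt"            # birth-length case weighting
    exclusion_months: tuple[int, ...] = DEFAULT_EXCLUSION_MONTHS
    asymptotic_length_cm: float = 201.7
    seed: int = 0
    outdir: str | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    compare_ogive_predictors: bool = False  # exact-LOO comparison is the slow stage

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one input source (input_csv or synthetic) is required")


def _stage_seed(root: int, k: int) -> int:
    return int((root * 1000 + k) % (2 ** 31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict.

    Bundle keys: records, classification, ogives, birth_length, gestation,
    rates, ovaries, seasonality, headline. When ``config.outdir`` is set the
    tables are written as CSV and the headline numbers as JSON.
    """
    bundle: dict = {"config": config}
    headline: dict = {"seed": config.seed, "package_version": cetrepro.__version__,
                      "python": platform.python_version()}

    def stage(name):
        log.info("stage: %s", name)

    # ---- records -----------------------------------------------------------
    stage("records")
    try:
        if config.input_csv is not None:
            records = read_records(config.input_csv, config.schema_config)
        else:
            records, truth = simulate_population(config.synthetic)
            bundle["truth"] = truth
    except Exception as exc:  # noqa: BLE001 - rewrap with stage tag
        raise StageError("records", exc) from exc
    bundle["records"] = records

    # ---- classification ----------------------------------------------------
    stage("classification")
    try:
        cls = classify_records(records)
        summary = summarize_by_class(records)
        props = MatureSampleProportions.from_records(records)
    except Exception as exc:
        raise StageError("classification", exc) from exc
    bundle["classification"] = cls
    bundle["class_summary"] = summary
    bundle["proportions"] = props
    headline["n_records"] = len(records)
    headline["n_mature"] = props.n_mature
    headline["p_pregnant"] = props.p
    headline["frac_simultaneous"] = props.frac_simultaneous

    # ---- maturity ogives ---------------------------------------------------
    stage("ogives")
    try:
        mc = dataclasses.replace(config.mcmc, seed=_stage_seed(config.seed, 1))
        ogive_age = fit_ogive(records, "age", mcmc=mc)
        mc = dataclasses.replace(config.mcmc, seed=_stage_seed(config.seed, 2))
        ogive_tbl = fit_ogive(records, "tbl", mcmc=mc)
        sofi_age = sofi_from_records(records, "age", seed=_stage_seed(config.seed, 3))
        sofi_tbl = sofi_from_records(records, "tbl", seed=_stage_seed(config.seed, 4))
        elpd = None
        if config.compare_ogive_predictors:
            cc = complete_cases(records)
            mc = dataclasses.replace(config.mcmc, seed=_stage_seed(config.seed, 5))
            elpd = compare_predictors(cc, fit_ogive(cc, "age", mcmc=mc),
                                      fit_ogive(cc, "tbl", mcmc=mc), mcmc=mc)
    except Exception as exc:
        raise StageError("ogives", exc) from exc
    bundle["ogives"] = {"age": ogive_age, "tbl": ogive_tbl,
                        "sofi_age": sofi_age, "sofi_tbl": sofi_tbl, "elpd": elpd}
    headline["asm_years"] = ogive_age.m_mean
    headline["asm_cri95"] = list(ogive_age.m_ci95)
    headline["lsm_cm"] = ogive_tbl.m_mean
    headline["lsm_cri95"] = list(ogive_tbl.m_ci95)
    headline["sofi_asm_years"] = sofi_age.estimate
    headline["sofi_lsm_cm"] = sofi_tbl.estimate
    if elpd is not None:
        headline["elpd_tbl_vs_age"] = elpd.elpd_diff
        headline["elpd_se"] = elpd.se_diff

    # ---- birth length + gestation ------------------------------------------
    stage("gestation")
    try:
        foet = [(r, r.foetus_tbl_cm) for r in records if r.foetus_tbl_cm is not None]
        lengths = [l for _, l in foet] + [r.tbl_cm for r in records
                                          if r.foetus_tbl_cm is None and r.tbl_cm is not None]
        born = [0] * len(foet) + [1] * (len(lengths) - len(foet))
        mc = dataclasses.replace(config.mcmc, seed=_stage_seed(config.seed, 6))
        blm = fit_birth_length(lengths, born, scheme=config.weight_scheme, mcmc=mc)
        lb = blm.m_mean

        # foetus/neonate cohort regression for the linear growth phase
        neonates = [r for r in records
                    if r.foetus_tbl_cm is None and r.age_years is not None
                    and not r.age_censored and r.age_years < 0.25 and r.tbl_cm is not None]
        days = [r.julian_day for r, _ in foet] + [r.julian_day for r in neonates]
        sizes = [l for _, l in foet] + [r.tbl_cm for r in neonates]
        cohorts = assign_cohorts(days, sizes) if len(days) >= 3 else None
        gestations = []
        if config.gestation_method in ("both", "huggett_widdas") and cohorts is not None:
            linear_days = lb / cohorts.slope  # days for a foetus to grow 0 -> L_b
            gestations.append(gestation_huggett_widdas(linear_days, lb_cm=lb))
        if config.gestation_method in ("both", "perrin_regression"):
            gestations.append(gestation_perrin_regression(lb))
        if not gestations:
            raise ValueError("no gestation estimate available (too few foetuses/neonates?)")
    except Exception as exc:
        raise StageError("gestation", exc) from exc
    bundle["birth_length"] = blm
    bundle["cohorts"] = cohorts
    bundle["gestation"] = gestations
    headline["lb_cm"] = lb
    headline["lb_hdi95"] = list(blm.m_hdi95)
    headline["gestation"] = [g.display() for g in gestations]
    if cohorts is not None:
        headline["cohort_slope_cm_per_day"] = cohorts.slope
        headline["cohort_r2"] = cohorts.r2

    # ---- life-history rates ------------------------------------------------
    stage("rates")
    try:
        rates = compute_life_history_rates(props, gestations, config.asymptotic_length_cm)
        excl = seasonal_exclusion(records, config.exclusion_months)
        props_excl = MatureSampleProportions.from_records(excl)
        rates_excl = (compute_life_history_rates(props_excl, gestations,
                                                 config.asymptotic_length_cm)
                      if props_excl.p > 0 else None)
    except Exception as exc:
        raise StageError("rates", exc) from exc
    bundle["rates"] = rates
    bundle["rates_seasonal_exclusion"] = rates_excl
    headline["apr"] = rates["apr"].tolist()
    headline["ci_summation_months"] = rates["ci_summation_months"].tolist()
    headline["ci_reciprocal_years"] = rates["ci_reciprocal_years"].tolist()
    if rates_excl is not None:
        headline["apr_seasonal_exclusion"] = rates_excl["apr"].tolist()
        headline["p_pregnant_seasonal_exclusion"] = props_excl.p

    # ---- ovarian analysis ---------------------------------------------------
    stage("ovaries")
    try:
        mature = [r for r in records if classify_maturity(r) is Maturity.mature]
        with_corp = [r for r in mature if r.corpora_total is not None]
        asym = asymmetry_test([r.corpora_left or 0 for r in with_corp],
                              [r.corpora_right or 0 for r in with_corp])
        pers = persistence_regressions(
            [r.tbl_cm if r.tbl_cm is not None else np.nan for r in with_corp],
            [r.age_years if (r.age_years is not None and not r.age_censored) else np.nan
             for r in with_corp],
            [r.corpora_total for r in with_corp])
        ages = [r.age_years for r in with_corp
                if r.age_years is not None and not r.age_censored]
        corp = [r.corpora_total for r in with_corp
                if r.age_years is not None and not r.age_censored]
        ovul = ovulation_rate(ages, corp)
        preg_cl = [(r.cl_diameter_mm, r.foetus_tbl_cm) for r in records
                   if r.cl_diameter_mm is not None and r.foetus_tbl_cm is not None]
        clf = (cl_vs_foetus([c for c, _ in preg_cl], [f for _, f in preg_cl])
               if len(preg_cl) >= 3 else None)
        mat_w = [(r.ovary_weight_left_g or 0) + (r.ovary_weight_right_g or 0)
                 for r in mature if r.ovary_weight_left_g is not None]
        imm_w = [(r.ovary_weight_left_g or 0) + (r.ovary_weight_right_g or 0)
                 for r in records if classify_maturity(r) is Maturity.immature
                 and r.ovary_weight_left_g is not None]
        contrast = ovary_weight_contrast(mat_w, imm_w) if len(mat_w) > 1 and len(imm_w) > 1 else None
    except Exception as exc:
        raise StageError("ovaries", exc) from exc
    bundle["ovaries"] = {"asymmetry": asym, "persistence": pers,
                         "ovulation_rate": ovul, "cl_vs_foetus": clf,
                         "weight_contrast": contrast}
    headline["corpora_left_right_ratio"] = asym.ratio
    headline["ovulation_rate_per_year"] = ovul.slope

    # ---- seasonality --------------------------------------------------------
    stage("seasonality")
    try:
        seasonality = {}
        for g in gestations:
            params = BackCalcParams.from_gestation(g)
            conceptions, births = [], []
            for r in records:
                if r.foetus_tbl_cm is not None or is_yearling(r, params):
                    try:
                        c, b = event_dates(r, params)
                    except ValueError:
                        continue
                    conceptions.append(c)
                    births.append(b)
            seasonality[g.method] = {
                "conception": seasonal_summary(conceptions) if conceptions else None,
                "birth": seasonal_summary(births) if births else None,
                "n": len(conceptions),
            }
        ovulating = ovulating_seasonal_counts(records)
    except Exception as exc:
        raise StageError("seasonality", exc) from exc
    bundle["seasonality"] = seasonality
    bundle["ovulating_by_season"] = ovulating
    for method, d in seasonality.items():
        if d["birth"] is not None:
            headline[f"spring_birth_prop_{method}"] = d["birth"].seasonal_proportions["spring"]
            headline[f"spring_conception_prop_{method}"] = d["conception"].seasonal_proportions["spring"]

    bundle["headline"] = headline
    if config.outdir:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    from cetrepro.records import write_records

    write_records(bundle["records"], outdir / "records.csv")
    bundle["classification"].to_csv(outdir / "classification.csv", index=False)
    bundle["class_summary"].to_csv(outdir / "class_summary.csv", index=False)
    bundle["rates"].to_csv(outdir / "rates.csv", index=False)
    if bundle.get("rates_seasonal_exclusion") is not None:
        bundle["rates_seasonal_exclusion"].to_csv(
            outdir / "rates_seasonal_exclusion.csv", index=False)
    og = bundle["ogives"]
    pd.DataFrame([
        {"predictor": p, "m_mean": o.m_mean, "m_lo": o.m_ci95[0], "m_hi": o.m_ci95[1],
         "omega_mean": o.omega_mean, "n": o.n, "converged": o.converged}
        for p, o in (("age", og["age"]), ("tbl", og["tbl"]))
    ]).to_csv(outdir / "ogives.csv", index=False)
    for p in ("age", "tbl"):
        o = og[p]
        lo, hi = o.posterior.x.min(), o.posterior.x.max()
        grid = np.linspace(lo, hi, 101)
        pd.DataFrame(o.curve_data(grid),
                     columns=["x", "p_mature", "lo95", "hi95"]).to_csv(
            outdir / f"ogive_curve_{p}.csv", index=False)
    pd.DataFrame([g.display() for g in bundle["gestation"]]).to_csv(
        outdir / "gestation.csv", index=False)
    months = []
    for method, d in bundle["seasonality"].items():
        for ev in ("conception", "birth"):
            if d[ev] is not None:
                for m, c in enumerate(d[ev].monthly_counts, start=1):
                    months.append({"method": method, "event": ev, "month": m, "count": int(c)})
    pd.DataFrame(months).to_csv(outdir / "seasonality_monthly.csv", index=False)
    with open(outdir / "headline.json", "w") as fh:
        json.dump(bundle["headline"], fh, indent=2, sort_keys=True, default=float)
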