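# cetrepro

Female reproductive life-history estimation for small cetaceans from
stranding and bycatch necropsy records.

Opportunistic carcass collections (strandings, fisheries bycatch) are often
the only source of reproductive data for wild dolphin populations. From a
table of per-female necropsy observations — total body length (TBL), tooth
growth-layer-group age, ovarian corpora counts, corpus luteum (CL)
presence, lactation evidence, foetus length — `cetrepro` estimates the
parameters that population assessments need:

* **Maturity ogives.** Maturity status y (0/1) is modelled against age or
  TBL by Bayesian logistic regression in HOF parameterisation,
  P(y=1 | x, m, ω) = 1 / (1 + exp(−ω(x − m))), so the midpoint m *is* the
  median age (ASM) or length (LSM) at sexual maturity. Priors:
  m ~ N(8, 2), ω ~ N⁺(0, 2) for age; m ~ N(190, 20), ω ~ N⁺(0, 1) for TBL.
  The distribution-free sum-of-fraction-immature (SOFI) estimator is
  provided alongside, and age vs length are compared as predictors by
  leave-one-out ELPD (exact refits at necropsy sample sizes, PSIS beyond).
* **Length at birth.** A weighted HOF logistic of born/unborn status on TBL
  over all foetuses and postnatal animals ≤ 160 cm, with class-imbalance
  case weights w_k = √(0.5/(n_k/n)) (or the fully weighted variant),
  normalised to mean 1.
* **Gestation.** (1) Huggett–Widdas: t_g = t₀ + (t_g − t₀), the linear
  foetal-growth phase regressed from foetal/neonatal length vs day-of-year
  after deterministic year-offset ("cohort") assignment, with
  t₀ = 0.126 × linear phase; (2) the allometric regression
  log₁₀(y) = 0.1659 + 0.4856 log₁₀(L_b) for weakly seasonal breeders.
* **Ovarian analyses.** Left/right corpora asymmetry (Shapiro–Wilk, then
  Kruskal–Wallis), corpora-persistence regressions on TBL and age, and the
  ovulation rate as the slope of mean corpora count per age class on age.
* **Rates.** Lactation period t_l = t_g·l/p, resting period t_r = t_g·r/p,
  annual pregnancy rate APR = p/t_g, and the calving interval by both the
  reciprocal (1/APR) and summation (t_g + t_l + t_r, lactation adjusted by
  the simultaneously-pregnant-and-lactating fraction) methods.
* **Seasonality.** Conception and birth dates back-calculated from foetal
  length (t = (L_t/u)·30.5 + t₀) and yearling length
  (t = (L_t − L_b)/(u/30.5)), tallied by month and austral season.
* **Synthetic populations.** A stranding-population generator with a known
  truth ledger (age ogive, three-phase reproductive cycle, von Mises
  conception seasonality, Poisson corpora accumulation with left-ovary
  bias), so every estimator is testable by parameter recovery — no field
  data required.

## Worked example

```bash
cetrepro simulate --n 106 --seed 1 --out records.csv
cetrepro run-all --input records.csv --seed 1 --out results/
```

which prints (abridged) headline JSON like:

```
"asm_years": 7.39,           # posterior mean age at sexual maturity
"asm_cri95": [6.80, 8.08],   # 95% credible interval
"lsm_cm": 183.2,             # length at sexual maturity
"sofi_asm_years": 7.42,      # distribution-free SOFI check
"lb_cm": 75.0,               # weighted-logistic length at birth
"gestation": [... "perrin_regression", "tg_months": 11.9 ...],
"apr": [..., 0.350],         # pregnant proportion / gestation (per year)
"ci_summation_months": [..., 34.8],
"ovulation_rate_per_year": 0.360,
"corpora_left_right_ratio": 3.81
```

The simulated population was generated with a true ASM of 7.5 yr, a birth
length of 87.6 cm, an ovulation rate of 0.3924 corpora/yr and a 78.9%
left-ovary bias; the run above recovers the ogive midpoint within its
credible interval, the ovulation rate within 0.04, and the corpora ratio
within 0.1. The birth-length and gestation rows illustrate two documented
behaviours of the estimators at opportunistic-sample scale (the weighted
midpoint tracks the foetus/newborn density crossing a few cm below the
mean birth length, and the cohort regression is attenuated when breeding
is weakly seasonal) — see `docs/methods.md`.

Everything is importable as a library, e.g.:

```python
from cetrepro import SyntheticConfig, simulate_population, fit_ogive
records, truth = simulate_population(SyntheticConfig(seed=1, n_females=106))
ogive = fit_ogive(records, predictor="age")
print(ogive.m_mean, ogive.m_ci95)
```

## Layout

```
src/cetrepro/
  records.py      data model, CSV I/O, reproductive-status classification
  bayes.py        HOF logistic MCMC, exact/PSIS leave-one-out ELPD
  ogive.py        ASM/LSM ogives, SOFI, predictor comparison
  gestation.py    case weights, birth length, cohorts, gestation methods
  ovaries.py      corpora asymmetry/persistence/ovulation analyses
  rates.py        lactation/resting, APR, calving intervals, weaning
  seasonality.py  conception/birth back-calculation and seasonal tallies
  simulate.py     synthetic stranding-population generator + truth ledger
  pipeline.py     end-to-end orchestration with reproducible seeding
  cli.py          `cetrepro` command-line interface
```
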