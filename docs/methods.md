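# Methods

This note documents the models behind `cetrepro`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real necropsy data.

## Data model and classification

A record is one necropsied female. Maturity follows the standard gross
criterion: mature iff at least one ovarian corpus (corpus albicans, CA, or
corpus luteum, CL) is present and/or the female is pregnant and/or
lactating. Records with *no* assessable evidence (no ovaries recovered, no
uterus or mammary examination) are classed `undetermined` and excluded from
downstream analyses rather than silently counted immature. Mature females
partition into pregnant / pregnant+lactating / lactating / resting, with
`indeterminate_mature` reserved for corpora-positive females whose mammary
state could not be assessed.

Ages read from tooth growth-layer groups may be lower bounds ("≥9"). These
are parsed into (bound, censored) pairs and excluded from every estimator
that needs a point age (ogives, ovulation rate, SOFI); they remain in the
record set for reporting. A CL is distinguished from a CA by diameter
strictly greater than 9 mm with yellow pigmentation; a 9.0 mm corpus is a CA.

Missing data are handled by per-analysis pairwise deletion: each estimator
uses every record carrying the fields it needs, and reports its own n.
Day-of-year is 1-based; all date arithmetic runs on the real calendar
(leap days included), while the 30.5-day month is used only inside
growth-rate conversions.

## HOF logistic regression and sampling

Maturity ogives and the length-at-birth model share one likelihood: a
Bernoulli GLM with P(y=1|x) = 1/(1+exp(−ω(x−m))). The HOF parameterisation
makes the midpoint m a direct parameter, so priors are set on the scale of
the quantity being estimated:

| model          | m prior      | ω prior   | why |
|----------------|--------------|-----------|-----|
| age ogive      | N(8, 2) yr   | N⁺(0, 2)  | delphinid maturation scale |
| length ogive   | N(190, 20) cm| N⁺(0, 1)  | adult female length scale |
| length at birth| N(90, 20) cm | N⁺(0, 1)  | neonate length scale |

ω's half-Normal prior (a Normal truncated at zero) restricts the curve to
be increasing; complete separation is permitted because the priors
regularise the fit.

Sampling uses the emcee ensemble sampler with a differential-evolution /
snooker move mixture, 16 walkers × 1500 post-warmup draws after 750 warmup
steps, all seeded. Walkers are treated as chains for split-R̂ and effective
sample size (arviz); fits with split-R̂ ≥ 1.01 are returned but flagged and
warned about, never discarded. The point estimate of m is the posterior
mean (the median is also stored); intervals are central 95% percentile for
the ogives and 95% highest-posterior-density for length at birth, whose
posterior can be mildly skew. Prior-only sampling (empty data) reproduces
the prior moments, which the test suite checks.

Per-case weights, when supplied, multiply the pointwise log-likelihood.
They shape the posterior only: leave-one-out predictive densities are
always computed from the unweighted Bernoulli density, so weighting schemes
remain comparable on one scale.

## Leave-one-out model comparison

Two routes to pointwise out-of-sample log predictive density (ELPD):

* **Exact**: refit the model n times, each time leaving one case out
  (class weights recomputed on the reduced set), and score the held-out
  case by its posterior predictive density. Used whenever n ≤ 200 — the
  regime of necropsy datasets — with shorter chains per refit (LOO means
  are far less demanding than tail quantiles).
* **PSIS**: Pareto-smoothed importance sampling re-weighting of a single
  posterior's pointwise log-likelihoods.

Model comparison reports ELPD(alt) − ELPD(ref) with
SE = √(n·Var(pointwise diff)); the reference model scores (0, SE 0). The
test suite requires the two routes to agree within twice that SE on an
83-case synthetic set — the exact refits are the oracle, PSIS the shortcut.

## SOFI

The sum-of-fraction-immature estimator bins the predictor (1-yr age bins,
10-cm length bins by default) and returns

ASM = α + Σⱼ fⱼ·w,

where α is the lower edge of the youngest class containing a mature
female, fⱼ the immature fraction of class j, and the sum runs from α's
class through the oldest class containing an immature female. With no
immature/mature overlap the estimate is the class boundary and the CI is
degenerate (warned). Anchoring at the class lower edge is the default;
mid-point anchoring is available (`anchor="mid"`) since the literature is
not uniform on this. The CI is a seeded percentile bootstrap over records
(1000 resamples); degenerate resamples (single-class) are redrawn.

## Case weights for class imbalance

With n₀ unborn and n₁ born cases, raw class weights are 0.5/(nₖ/n)
(`full`) or its square root (`sqrt`, the default, matching the milder
correction usually preferred); the n-vector is rescaled to mean exactly 1
so the weighted log-likelihood keeps the scale of the data. For 13 unborn
and 90 born, the sqrt scheme gives normalised weights 2.182 / 0.829.

Note a structural property verified during development: on populations
from the synthetic generator the weighted-logistic midpoint estimates the
*density crossing* of foetal and postnatal length distributions, which
sits a few cm below the mean birth length because newborns pile up just
above it. Recovery tests therefore use the direct construction — born
status Bernoulli in length around a true boundary — for which the midpoint
is exactly the boundary.

## Cohort assignment and gestation

**Cohort assignment.** Foetal/neonatal lengths are plotted against
day-of-year; when conceptions are seasonal, replicating the axis across
three nominal years makes parallel growth trajectories visible, and each
specimen belongs to one of them. The reproducible surrogate for that
visual assignment is: (1) scan a grid of candidate slopes; for each, try
every per-point intercept candidate, snapping each specimen to the year
offset (0/365/730 d) closest to the line; (2) from the best few starting
assignments, iterate "snap each specimen to the offset minimising its
absolute residual, refit OLS" to a fixed point (the residual sum cannot
increase and the assignment space is finite); (3) keep the
lowest-residual fixed point, ties toward smaller offsets, offsets
anchored so the smallest is zero. A physiological slope window (0.15–0.6
cm/day by default) excludes artefactual near-flat lines that thread all
three replicated years — without it such lines can out-score the real
cohort structure, exactly as they can fool the eye. The window is a
parameter (`slope_range`) for species with different foetal growth.

**Huggett–Widdas.** Foetal growth is a brief nonlinear phase t₀ followed
by linear growth; t₀ = 0.126 × (linear phase), the ratio taken from the
delphinid literature. The pipeline derives the linear phase as
L_b / slope — the days a foetus needs to grow from 0 to the birth length
along the cohort line — because the cohort regression's slope and span are
the observable quantities. Total gestation t_g = linear + t₀; mean foetal
growth rate u = L_b / t_g(months).

**Allometric regression.** log₁₀(y months) = 0.1659 + 0.4856·log₁₀(L_b cm),
for populations without firm breeding seasonality. Base-10 logs are the
only reading consistent with the regression's published applications
(natural logs give nonsense months). At L_b = 87.6 cm this evaluates to
12.86 months ≈ 392 days; reports that round months to 12.8 first and then
derive days (391) or u (6.84 cm/month) differ from the full-precision
values here by ~0.3% — `GestationEstimate.display()` rounds only at the
reporting boundary.

**Limitation.** The cohort/Huggett–Widdas route assumes seasonal
conceptions. Under weak seasonality the assignment has no real structure
to find: recovered slopes are attenuated (up to ~50% under the generator's
default weak seasonality, ~10–20% when conceptions are strongly seasonal,
part of which is ordinary errors-in-x attenuation from conception-date
spread). The allometric route should be preferred, or both reported, for
weakly seasonal populations — which is why the pipeline computes both.

## Ovarian analyses

Corpora are assumed to persist indefinitely, so a female's total count
(CAs + CL) indexes her cumulative ovulations. Left/right asymmetry is
tested with Kruskal–Wallis on the two sides (equivalent to Mann–Whitney up
to the χ² approximation; tie-corrected), after a Shapiro–Wilk normality
check that count data are expected to fail. The ovulation rate is the OLS
slope of mean corpora count per integer age class on age (half-year best
estimates floor into their year class); requiring ≥3 classes. Welch's
unequal-variance t-test is used for the mature/immature ovarian-weight
contrast; identical-group and zero-variance degenerate inputs return
(t=0, p=1) and a flag rather than NaNs.

## Rates

With p, l, r the proportions of the mature sample pregnant (including
simultaneously pregnant and lactating), lactating, and resting:
t_l = t_g·l/p, t_r = t_g·r/p, APR = p/t_g(years), reciprocal calving
interval 1/APR, summation interval t_g + t_l(1−f) + t_r with f the
simultaneous fraction. The unadjusted sum is reported alongside because
published tabulations sometimes skip the adjustment. Both the pregnant
count convention (pregnant-only + simultaneous, or an explicit override)
and the peak-season exclusion window (default August–November) are
configuration-visible, since tabulations in the literature group these
classes differently. The seasonal-exclusion APR variant recomputes p after
dropping mature females sampled in the excluded months. Length at weaning
uses L_w = 1.2399·L_x^0.877 on the female asymptotic length; at
L_x = 201.7 cm this evaluates to 130.2 cm (reports quoting ~127 cm for
that input are not reproducible from the formula and are not used as
oracles here).

## Seasonality

Foetal age t = (L_t/u)·30.5 + t₀ days; yearling age
t = (L_t − L_b)/(u/30.5) days with the sex-specific first-year growth rate
u/12 (cm/month), where the first-year rate is length-at-one-year minus
length-at-birth (46 cm/yr female, 52.2 cm/yr male for the default
constants). The yearling formula is implemented with the subtraction
grouped before the division — the only dimensionally consistent reading,
and the one that returns ~366 days for a female at her one-year length.
Note that with u defined as L_b/t_g, the foetal formula returns t_g + t₀
(not t_g) at L_t = L_b; the formula is implemented as printed in the
back-calculation literature and round-trips exactly, but its full-term
value carries that t₀ overhang. Conception = strand date − t for foetuses
(birth = conception + t_g); birth = strand date − t for yearlings
(conception = birth − t_g). Ages round to whole days when placed on the
calendar. Austral seasons: spring Sep–Nov, summer Dec–Feb, autumn Mar–May,
winter Jun–Aug. A female is flagged "likely ovulating" when a CL is
present with no detectable foetus.

## Synthetic population generator

The generator emulates an opportunistically sampled stranding/bycatch
dataset with every true parameter known:

* **Ages** 0–29 yr, geometric-like decay calibrated so 83% of females are
  ≤15 yr (the shape of real stranding samples); within-year death times in
  the first year skew toward birth (Beta(0.6, 2.5)), the neonatal
  mortality peak that makes yearlings the modal class.
* **Maturity** via a latent logistic onset age (location 7.5 yr, scale
  1/1.5), so P(mature|age) is exactly the HOF ogive — the ogive fit's
  estimand equals the generator parameter by construction.
* **Growth** linear through year one (46 cm/yr from an 87.6 ± 4.5 cm
  individual birth length), then exponential approach to 201.7 cm
  calibrated to pass through 183.5 cm at 7.5 yr; measurement noise 4 cm;
  lengths recorded to 0.5 cm and ages to 0.25 yr, as in practice.
* **Reproductive cycle**: mature females sit at a uniform phase of a
  pregnant → lactating → resting cycle (12.6 months each by default, so
  expected phase proportions are equal — the steady state the period
  estimators assume). Pregnant females carry a foetus growing linearly
  after a 43-day lag to their own birth length at term (384 d), a CL of
  16–36 mm, and are also lactating with probability 0.07.
* **Seasonality**: conception day-of-year is von Mises; κ = 0.56 (peak
  early October) was chosen once so ≈59% of births fall August–December —
  weak seasonality; κ = 0 gives uniform conceptions. Strand dates follow
  from conception/birth plus the individual's age or cycle position, so
  back-calculation round-trips are exact by construction.
* **Ovaries**: mature females carry 1 + Poisson(0.3924·(age − onset))
  corpora (the +1 is the maturation ovulation that makes the maturity
  criterion self-consistent), allocated left with probability 97/123;
  combined ovarian weight N(8.7, 4²) g mature vs N(2.5, 1.5²) g immature.
* **Sampling process**: ~8.5% bycatch, strand years 1997–2019, a few
  percent missing ages/ovaries and occasional censored ages ("≥9"-style).

What passing recovery tests show: the estimators are consistent with
their own estimands at opportunistic sample sizes, with honest interval
coverage. What they do not show: robustness to features the generator
omits — age-reading error, decomposition-dependent detection of small
embryos, spatially clustered mass strandings, corpora regression over
time, and non-stationary vital rates.

## Reported problem sizes

The validation suite runs at the scale of the data the methods are meant
for: populations of ~106 females (20 seeded replicates for interval
coverage, at n = 1000 as well), n = 500 for SOFI, ~50–65 mature females
for the ovulation rate, 83 complete cases for the exact-vs-PSIS LOO
equivalence, and 22-specimen cohort fixtures. These sizes mirror the
opportunistic datasets the estimators target while keeping the full suite
fast enough to run routinely.
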