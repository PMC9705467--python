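"""Maturity-ogive estimation: HOF logistic, SOFI, and predictor comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetrepro.bayes import McmcConfig, PriorSpec, fit_hof_logistic
from cetrepro.ogive import (
    compare_predictors,
    complete_cases,
    fit_ogive,
    hof_probability,
    maturity_data,
    sofi_estimate,
)
from cetrepro.simulate import SyntheticConfig, simulate_population

FAST = McmcConfig(n_walkers=16, n_steps=800, n_burn=400)


class TestHofProbability:
    def test_midpoint_gives_half(self):
        assert hof_probability(7.5, 7.5, 1.3) == pytest.approx(0.5)

    def test_zero_slope_is_flat_half(self):
        for x in (-50.0, 0.0, 12.0, 400.0):
            assert hof_probability(x, 7.5, 0.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        # x = m + 10, omega = 0.5 -> 1/(1+e^-5)
        assert hof_probability(17.5, 7.5, 0.5) == pytest.approx(0.9933, abs=5e-5)

    def test_saturates_without_overflow(self):
        assert hof_probability(1e6, 0.0, 10.0) == 1.0
        assert hof_probability(-1e6, 0.0, 10.0) == 0.0

    @given(m=st.floats(-100, 300), d=st.floats(0, 200), omega=st.floats(0.001, 10))
    @settings(max_examples=200, deadline=None)
    def test_point_symmetry_about_midpoint(self, m, d, omega):
        p_lo = hof_probability(m - d, m, omega)
        p_hi = hof_probability(m + d, m, omega)
        assert p_lo + p_hi == pytest.approx(1.0, abs=1e-12)

    def test_monotone_increasing_when_omega_positive(self):
        x = np.linspace(150, 230, 200)
        p = hof_probability(x, 183.5, 0.35)
        assert np.all(np.diff(p) > 0)


class TestFitOgive:
    def test_parameter_recovery_paper_scale(self):
        recs, _ = simulate_population(SyntheticConfig(seed=3, n_females=150))
        og = fit_ogive(recs, "age", mcmc=FAST)
        assert abs(og.m_mean - 7.5) < 1.0
        assert og.posterior.omega_mean > 0
        assert og.m_ci95[0] < og.m_ci95[1]

    def test_midpoint_inside_data_range_when_classes_overlap(self):
        recs, _ = simulate_population(SyntheticConfig(seed=9, n_females=400))
        og = fit_ogive(recs, "tbl", mcmc=FAST)
        x = og.posterior.x
        assert x.min() < og.m_mean < x.max()

    def test_all_immature_is_precondition_error(self):
        recs, truth = simulate_population(SyntheticConfig(seed=2, n_females=80))
        ids = set(truth.loc[~truth["mature"], "id"])
        immature = [r for r in recs if r.id in ids]
        with pytest.raises(ValueError):
            fit_ogive(immature, "age")

    def test_censored_ages_never_enter_the_fit(self, sim_default):
        import dataclasses

        records, _ = sim_default
        x0, y0 = maturity_data(records, "age")
        # adding a minimum-age-only female must not change the design matrix
        bounded = dataclasses.replace(records[0], id="CENS", age_years=9.0,
                                      age_censored=True, corpora_left=3,
                                      corpora_right=1)
        x1, y1 = maturity_data(records + [bounded], "age")
        assert np.array_equal(x0, x1) and np.array_equal(y0, y1)

    def test_prior_only_sampling_reproduces_prior_moments(self):
        priors = PriorSpec(8.0, 2.0, 2.0)
        fit = fit_hof_logistic([], [], priors, McmcConfig(seed=4, n_steps=2000, n_burn=500))
        m, om = fit.draws[:, 0], fit.draws[:, 1]
        assert m.mean() == pytest.approx(8.0, abs=0.15)
        assert m.std() == pytest.approx(2.0, abs=0.15)
        # half-Normal(2) mean = 2 sqrt(2/pi)
        assert om.mean() == pytest.approx(2 * np.sqrt(2 / np.pi), abs=0.12)

    def test_seeded_fit_is_deterministic(self):
        recs, _ = simulate_population(SyntheticConfig(seed=5, n_females=100))
        a = fit_ogive(recs, "age", mcmc=McmcConfig(seed=42, n_steps=300, n_burn=200))
        b = fit_ogive(recs, "age", mcmc=McmcConfig(seed=42, n_steps=300, n_burn=200))
        assert np.array_equal(a.posterior.draws, b.posterior.draws)


class TestSofi:
    def test_hand_computed_overlap_example(self):
        # age 6: 4/4 immature; age 7: 2/4 immature; age 8: 0/4 -> 7 + 0.5
        ages = [6.1, 6.5, 6.8, 6.9, 7.1, 7.2, 7.5, 7.9, 8.0, 8.3, 8.5, 8.9]
        mature = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
        res = sofi_estimate(ages, mature, bin_width=1.0, seed=1)
        assert res.estimate == pytest.approx(7.5)

    def test_perfect_separation_returns_boundary(self):
        ages = [5.5, 6.5, 7.5, 8.5, 9.5, 10.5]
        mature = [0, 0, 0, 1, 1, 1]
        with pytest.warns(RuntimeWarning):
            res = sofi_estimate(ages, mature, bin_width=1.0, seed=1)
        assert res.estimate == 8.0
        assert res.degenerate and res.ci95 == (8.0, 8.0)

    def test_single_mixed_class_returns_edge_plus_fraction(self):
        # one class at [7, 8) with 1/4 immature -> 7.25
        ages = [7.1, 7.3, 7.6, 7.9]
        mature = [0, 1, 1, 1]
        res = sofi_estimate(ages, mature, bin_width=1.0, seed=0)
        assert res.estimate == pytest.approx(7.25)

    def test_bin_width_scales_the_fraction(self):
        tbl = [183.0, 185.0, 187.0, 189.0]
        mature = [0, 1, 1, 1]
        res = sofi_estimate(tbl, mature, bin_width=10.0, seed=0)
        assert res.estimate == pytest.approx(180.0 + 10.0 * 0.25)

    def test_recovery_within_three_quarters_of_a_year_at_n500(self):
        cfg = SyntheticConfig(seed=21, n_females=500, true_asm_m=8.39)
        recs, _ = simulate_population(cfg)
        x, y = maturity_data(recs, "age")
        res = sofi_estimate(x, y, bin_width=1.0, seed=21)
        assert abs(res.estimate - 8.39) < 0.75
        assert res.ci95[0] < res.estimate < res.ci95[1]


class TestComparePredictors:
    def test_identical_models_have_zero_difference(self):
        recs, _ = simulate_population(SyntheticConfig(seed=6, n_females=90))
        cc = complete_cases(recs)
        og = fit_ogive(cc, "age", mcmc=FAST)
        from cetrepro.bayes import compare_elpd, psis_loo

        lpd, _ = psis_loo(og.posterior)
        cmp = compare_elpd(lpd, lpd, "psis_loo")
        assert cmp.elpd_diff == 0.0 and cmp.se_diff == 0.0

    def test_mismatched_case_sets_is_contract_error(self):
        recs, _ = simulate_population(SyntheticConfig(seed=6, n_females=90))
        cc = complete_cases(recs)
        og_age = fit_ogive(cc, "age", mcmc=FAST)
        og_tbl = fit_ogive(cc[:-5], "tbl", mcmc=FAST)
        with pytest.raises(ValueError):
            compare_predictors(cc, og_age, og_tbl)

    def test_age_generated_maturity_favours_age_model(self):
        # maturity driven by the age ogive; length is a noisy correlate, so
        # the age model should win the PSIS-LOO comparison on shared cases
        cfg = SyntheticConfig(seed=17, n_females=250, length_noise_sd=12.0)
        recs, _ = simulate_population(cfg)
        cc = complete_cases(recs)
        og_age = fit_ogive(cc, "age", mcmc=FAST)
        og_tbl = fit_ogive(cc, "tbl", mcmc=FAST)
        cmp = compare_predictors(cc, og_age, og_tbl, method="psis_loo")
        assert cmp.elpd_diff < 0  # negative = alternative (length) is worse
        assert cmp.se_diff > 0
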