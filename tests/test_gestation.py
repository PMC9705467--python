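"""Case weights, birth-length model, cohort assignment, gestation arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetrepro.bayes import McmcConfig
from cetrepro.gestation import (
    assign_cohorts,
    case_weight_vector,
    compare_weight_schemes,
    compute_case_weights,
    fit_birth_length,
    gestation_huggett_widdas,
    gestation_perrin_regression,
)


class TestCaseWeights:
    def test_balanced_classes_give_unit_weights(self):
        for scheme in ("full", "sqrt"):
            assert compute_case_weights(40, 40, scheme) == pytest.approx((1.0, 1.0))

    def test_hand_arithmetic_13_unborn_90_born_sqrt(self):
        # raw w0 = sqrt(0.5*103/13) = 1.9904, raw w1 = 0.7565; mean-1
        # normalisation gives 2.182 / 0.829
        w0, w1 = compute_case_weights(13, 90, "sqrt")
        assert w0 == pytest.approx(2.182, abs=1e-3)
        assert w1 == pytest.approx(0.829, abs=1e-3)

    def test_full_scheme_ratio_is_class_size_ratio(self):
        w0, w1 = compute_case_weights(13, 90, "full")
        assert w0 / w1 == pytest.approx(90 / 13, rel=1e-12)

    @given(n0=st.integers(1, 400), n1=st.integers(1, 400),
           scheme=st.sampled_from(["full", "sqrt", "unweighted"]))
    @settings(max_examples=200, deadline=None)
    def test_weight_vector_sums_to_n_under_all_schemes(self, n0, n1, scheme):
        born = np.array([0] * n0 + [1] * n1)
        w = case_weight_vector(born, scheme)
        assert w.sum() == pytest.approx(n0 + n1, rel=1e-9)
        assert w.mean() == pytest.approx(1.0, rel=1e-9)

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            compute_case_weights(0, 10, "sqrt")


class TestHuggettWiddas:
    def test_published_scale_341_day_linear_phase(self):
        g = gestation_huggett_widdas(341.0, 0.126, lb_cm=87.6)
        assert round(g.t0_days) == 43
        assert round(g.tg_days) == 384
        assert g.tg_months == pytest.approx(12.6, abs=0.05)
        assert g.u_cm_per_month == pytest.approx(6.95, abs=0.01)

    def test_zero_ratio_means_no_nonlinear_phase(self):
        g = gestation_huggett_widdas(300.0, 0.0)
        assert g.t0_days == 0.0 and g.tg_days == 300.0

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            gestation_huggett_widdas(300.0, -0.1)

    @given(lp=st.floats(50, 600), c=st.floats(1.1, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_linear_phase(self, lp, c):
        g1 = gestation_huggett_widdas(lp)
        g2 = gestation_huggett_widdas(c * lp)
        assert g2.tg_days == pytest.approx(c * g1.tg_days, rel=1e-9)

    def test_growth_rate_roundtrip_identity(self):
        g = gestation_huggett_widdas(341.0)
        assert g.u_cm_per_month * g.tg_months == pytest.approx(g.lb_cm, rel=1e-12)


class TestPerrinRegression:
    def test_birth_length_87_6_gives_about_12_9_months(self):
        g = gestation_perrin_regression(87.6)
        assert g.tg_months == pytest.approx(12.86, abs=0.01)
        assert g.tg_days == pytest.approx(392, abs=2)  # printed as 391 d / 12.8 mo
        assert round(g.t0_days) == 44
        assert g.u_cm_per_month == pytest.approx(6.84, abs=0.05)

    def test_unit_birth_length(self):
        g = gestation_perrin_regression(1.0)
        assert g.tg_months == pytest.approx(10 ** 0.1659, rel=1e-9)

    def test_monotone_in_birth_length(self):
        months = [gestation_perrin_regression(lb).tg_months for lb in (60, 80, 100, 120)]
        assert months == sorted(months)

    def test_loglog_linearity(self):
        g1, g2 = gestation_perrin_regression(50.0), gestation_perrin_regression(100.0)
        assert np.log10(g2.tg_months) - np.log10(g1.tg_months) == pytest.approx(
            0.4856 * np.log10(2.0), rel=1e-9)

    def test_growth_rate_roundtrip_identity(self):
        g = gestation_perrin_regression(87.6)
        assert g.u_cm_per_month * g.tg_months == pytest.approx(87.6, rel=1e-12)

    def test_gestation_decomposition_identity(self):
        for g in (gestation_perrin_regression(87.6), gestation_huggett_widdas(341.0)):
            assert g.tg_days == pytest.approx(g.t0_days + g.linear_phase_days, rel=1e-12)
            assert g.t0_days == pytest.approx(0.126 * g.linear_phase_days, rel=1e-9)


def _year_split_fixture():
    """Noiseless cohort line (slope 0.3083 cm/day) split across year boundaries."""
    eff = np.array([50.0, 150.0, 300.0, 420.0, 500.0, 640.0, 760.0, 900.0, 1000.0])
    tbl = 0.3083 * eff + 5.0
    day = ((eff - 1) % 365) + 1
    return day, tbl, eff - day


class TestAssignCohorts:
    def test_noiseless_year_split_line_recovered_exactly(self):
        day, tbl, true_off = _year_split_fixture()
        ca = assign_cohorts(day, tbl)
        assert np.array_equal(ca.offsets, true_off)
        assert ca.slope == pytest.approx(0.3083, rel=1e-9)
        assert ca.r2 == pytest.approx(1.0)

    def test_single_cohort_inside_one_year_gets_zero_offsets(self):
        day = np.array([40.0, 120.0, 200.0, 280.0, 350.0])
        tbl = 0.26 * day + 3.0
        ca = assign_cohorts(day, tbl)
        assert np.all(ca.offsets == 0.0)
        assert ca.r2 == pytest.approx(1.0)

    def test_invariant_to_input_permutation(self):
        day, tbl, _ = _year_split_fixture()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(day))
        a = assign_cohorts(day, tbl)
        b = assign_cohorts(day[perm], tbl[perm])
        assert np.array_equal(a.offsets[perm], b.offsets)
        assert a.slope == pytest.approx(b.slope)

    def test_too_few_specimens_rejected(self):
        with pytest.raises(ValueError):
            assign_cohorts([10.0, 20.0], [5.0, 10.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_slope_recovered_within_ten_percent_on_cohort_structured_data(self, seed):
        # seasonal conceptions with visible cohort runs, foetal slope as in
        # a 384-day gestation reaching 87.6 cm after a 43-day lag
        true_s, t0, tg = 0.2569, 43.0, 384.0
        rng = np.random.default_rng(seed)
        n = 22
        con = rng.normal(280, 15, n)
        fa = rng.uniform(t0 + 20, tg + 40, n)
        tbl = np.where(fa <= tg, true_s * (fa - t0),
                       true_s * (tg - t0) + 0.126 * (fa - tg)) + rng.normal(0, 4, n)
        day = ((con + fa - 1) % 365) + 1
        ca = assign_cohorts(day, np.maximum(tbl, 1.0))
        assert abs(ca.slope - true_s) / true_s < 0.10


class TestBirthLength:
    @staticmethod
    def _overlap_set(seed, n0=13, n1=90, omega=0.35):
        """Born status Bernoulli in length around a true 87.6 cm boundary."""
        rng = np.random.default_rng(seed)
        lengths, born = [], []
        while sum(b == 0 for b in born) < n0 or sum(born) < n1:
            L = rng.uniform(15, 160)
            b = int(rng.uniform() < 1 / (1 + np.exp(-omega * (L - 87.6))))
            if b == 0 and sum(b2 == 0 for b2 in born) >= n0:
                continue
            if b == 1 and sum(born) >= n1:
                continue
            lengths.append(L)
            born.append(b)
        return np.array(lengths), np.array(born)

    def test_recovery_within_5_cm_of_true_boundary(self):
        errs = []
        for seed in (0, 1, 2):
            L, born = self._overlap_set(seed)
            blm = fit_birth_length(L, born, scheme="sqrt",
                                   mcmc=McmcConfig(seed=seed, n_steps=800, n_burn=400))
            errs.append(abs(blm.m_mean - 87.6))
        assert max(errs) < 5.0

    def test_perfect_separation_concentrates_near_boundary(self):
        L = np.concatenate([np.linspace(40, 88, 12), np.linspace(92, 150, 25)])
        born = np.array([0] * 12 + [1] * 25)
        blm = fit_birth_length(L, born, mcmc=McmcConfig(seed=0, n_steps=800, n_burn=400))
        assert 85 < blm.m_mean < 95
        assert blm.m_hdi95[0] < blm.m_mean < blm.m_hdi95[1]

    def test_all_born_input_is_precondition_error(self):
        with pytest.raises(ValueError):
            fit_birth_length([100.0, 110.0, 120.0], [1, 1, 1])

    def test_lengths_above_160_are_excluded(self):
        L = [50.0, 80.0, 100.0, 120.0, 200.0, 250.0]
        born = [0, 0, 1, 1, 1, 1]
        blm = fit_birth_length(L, born, mcmc=McmcConfig(seed=0, n_steps=300, n_burn=200))
        assert blm.n == 4

    def test_weight_scheme_comparison_yields_finite_se(self):
        L, born = self._overlap_set(3, n0=8, n1=32)
        cmp = compare_weight_schemes(L, born,
                                     mcmc=McmcConfig(seed=3, n_steps=400, n_burn=250))
        assert cmp.method == "exact_loo"
        assert np.isfinite(cmp.elpd_diff) and np.isfinite(cmp.se_diff)
        assert cmp.se_diff > 0
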