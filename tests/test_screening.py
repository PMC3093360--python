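"""Age-based versus personalised screening eligibility."""

import math

import numpy as np
import pytest

import polyscreen as ps
from polyscreen import (
    ALWAYS_ELIGIBLE,
    NEVER_ELIGIBLE,
    PolygenicModel,
    ScreeningPolicy,
    age_conditional_risk,
    matched_threshold,
    reclassification,
    strategy_summary,
    threshold_rr_for_age,
    threshold_sweep,
    variance_fraction_sweep,
)

from conftest import make_table

PROSTATE_RANGE = (45, 79)


@pytest.fixture(scope="module")
def model():
    return PolygenicModel(0.377)


@pytest.fixture(scope="module")
def age55():
    return ScreeningPolicy.age_based(55, PROSTATE_RANGE)


class TestThresholdRR:
    def test_one_band_closed_form(self):
        lam, t = 0.005, 0.02
        table = make_table([60], [lam], 0.0)
        # with no competing risk, A = 1 - exp(-r lam) so r* has a closed form
        expected = -math.log1p(-t) / lam
        got = threshold_rr_for_age(table, 60, t, window=1)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_fixed_point_at_baseline_risk(self, prostate_rates):
        t = age_conditional_risk(prostate_rates, 55, 65)
        assert threshold_rr_for_age(prostate_rates, 55, t) == pytest.approx(1.0, abs=1e-6)

    def test_near_linearity_for_small_thresholds(self, prostate_rates):
        t = 0.004
        r1 = threshold_rr_for_age(prostate_rates, 50, t)
        r2 = threshold_rr_for_age(prostate_rates, 50, t / 2)
        assert r2 == pytest.approx(r1 / 2, rel=0.02)

    def test_always_and_never_eligible_sentinels(self):
        table = make_table([60], [0.005], 0.0)
        assert threshold_rr_for_age(table, 60, 1e-10, window=1) == ALWAYS_ELIGIBLE
        assert threshold_rr_for_age(table, 60, 0.999, window=1) == NEVER_ELIGIBLE

    def test_solution_reproduces_threshold(self, prostate_rates):
        for age, t in ((48, 0.02), (60, 0.02), (70, 0.05)):
            r_star = threshold_rr_for_age(prostate_rates, age, t)
            end = min(age + 10, prostate_rates.age_max + 1)
            assert age_conditional_risk(prostate_rates, age, end, r_star) == pytest.approx(
                t, abs=1e-10
            )


class TestStrategySummary:
    def test_age_based_fractions_are_count_ratios(self, prostate_rates, model, age55):
        s = strategy_summary(prostate_rates, model, age55)
        lo, hi = PROSTATE_RANGE
        sel = slice(lo - prostate_rates.age_min, hi - prostate_rates.age_min + 1)
        pop = prostate_rates.population[sel]
        cases = prostate_rates.cancer_cases[sel]
        old = prostate_rates.ages[sel] >= 55
        assert s.eligible_fraction == pytest.approx(pop[old].sum() / pop.sum())
        assert s.detectable_case_fraction == pytest.approx(cases[old].sum() / cases.sum())

    def test_degenerate_variance_collapses_to_age_rule(self, prostate_rates, age55):
        flat = PolygenicModel(0.0)
        # nudge below the baseline risk at the cutoff so the boundary band
        # lands on the eligible side of the step
        t = age_conditional_risk(prostate_rates, 55, 65) - 1e-9
        pers = ScreeningPolicy.personalised(t, PROSTATE_RANGE)
        s_age = strategy_summary(prostate_rates, flat, age55)
        s_pers = strategy_summary(prostate_rates, flat, pers)
        assert abs(s_age.eligible_fraction - s_pers.eligible_fraction) < 1e-9
        assert abs(s_age.detectable_case_fraction - s_pers.detectable_case_fraction) < 1e-9

    def test_tiny_threshold_makes_everyone_eligible(self, prostate_rates, model):
        pers = ScreeningPolicy.personalised(1e-6, PROSTATE_RANGE)
        s = strategy_summary(prostate_rates, model, pers)
        assert s.eligible_fraction == pytest.approx(1.0, abs=1e-6)
        assert s.detectable_case_fraction == pytest.approx(1.0, abs=1e-6)

    def test_case_enrichment_dominance(self, prostate_rates, model):
        pers = ScreeningPolicy.personalised(0.02, PROSTATE_RANGE)
        s = strategy_summary(prostate_rates, model, pers)
        assert s.detectable_case_fraction > s.eligible_fraction

    def test_personalised_saves_eligibility_at_small_case_cost(self, prostate_rates, model, age55):
        """Direction of the headline comparison: fewer people eligible,
        with a much smaller deficit in detectable cases."""
        pers = ScreeningPolicy.personalised(0.02, PROSTATE_RANGE)
        s_age = strategy_summary(prostate_rates, model, age55)
        s_pers = strategy_summary(prostate_rates, model, pers)
        elig_deficit = 1 - s_pers.eligible_fraction / s_age.eligible_fraction
        case_deficit = 1 - s_pers.detectable_case_fraction / s_age.detectable_case_fraction
        assert elig_deficit > 0
        assert 0 <= case_deficit < elig_deficit


class TestReclassification:
    def test_cells_conserve_population_and_cases(self, prostate_rates, model, age55):
        pers = ScreeningPolicy.personalised(0.02, PROSTATE_RANGE)
        recl = reclassification(prostate_rates, model, age55, pers)
        assert recl.population_total == pytest.approx(100_000.0, abs=1e-6)
        lo, hi = PROSTATE_RANGE
        sel = slice(lo - prostate_rates.age_min, hi - prostate_rates.age_min + 1)
        expected_cases = (
            prostate_rates.cancer_cases[sel].sum()
            / prostate_rates.population[sel].sum()
            * 100_000.0
        )
        assert recl.cases_total == pytest.approx(expected_cases, rel=1e-12)

    def test_degenerate_model_empties_off_diagonals(self, prostate_rates, age55):
        flat = PolygenicModel(0.0)
        t = age_conditional_risk(prostate_rates, 55, 65) - 1e-9
        pers = ScreeningPolicy.personalised(t, PROSTATE_RANGE)
        recl = reclassification(prostate_rates, flat, age55, pers)
        assert recl.population[0, 1] == pytest.approx(0.0, abs=1e-6)
        assert recl.population[1, 0] == pytest.approx(0.0, abs=1e-6)

    def test_cross_tab_structure_with_real_variance(self, prostate_rates, model, age55):
        pers = ScreeningPolicy.personalised(0.02, PROSTATE_RANGE)
        recl = reclassification(prostate_rates, model, age55, pers)
        # young-but-high-risk and old-but-low-risk cells both populated
        assert recl.population[1, 0] > 0
        assert recl.population[0, 1] > 0
        # case enrichment: the risk-eligible row holds most of the cases
        assert recl.cases[1].sum() / recl.cases_total > recl.population[1].sum() / 100_000.0

    def test_presentation_frame_sums(self, prostate_rates, model, age55):
        pers = ScreeningPolicy.personalised(0.02, PROSTATE_RANGE)
        frame = reclassification(prostate_rates, model, age55, pers).to_frame(
            "population", rounded=False
        )
        assert frame.loc["total", "total"] == pytest.approx(100_000.0)

    def test_mismatched_policies_rejected(self, prostate_rates, model, age55):
        pers = ScreeningPolicy.personalised(0.02, (50, 79))
        with pytest.raises(ValueError, match="age range"):
            reclassification(prostate_rates, model, age55, pers)


class TestThresholdSweep:
    def test_monotone_and_saturating(self, prostate_rates, model):
        ts = [0.001, 0.005, 0.01, 0.02, 0.05]
        frame = threshold_sweep(prostate_rates, model, PROSTATE_RANGE, ts)
        assert np.all(np.diff(frame["eligible_fraction"]) <= 1e-12)
        assert np.all(np.diff(frame["detectable_case_fraction"]) <= 1e-12)
        assert frame["eligible_fraction"].iloc[0] > 0.99
        assert np.all(
            frame["detectable_case_fraction"] >= frame["eligible_fraction"] - 1e-12
        )


class TestMatchedThreshold:
    def test_solver_contract_both_criteria(self, prostate_rates, model, age55):
        for match in ("eligible_population", "detected_cases"):
            t_star = matched_threshold(prostate_rates, model, age55, match=match)
            s = strategy_summary(
                prostate_rates,
                model,
                ScreeningPolicy.personalised(t_star, PROSTATE_RANGE),
            )
            target = strategy_summary(prostate_rates, model, age55)
            got = (
                s.eligible_fraction
                if match == "eligible_population"
                else s.detectable_case_fraction
            )
            want = (
                target.eligible_fraction
                if match == "eligible_population"
                else target.detectable_case_fraction
            )
            assert abs(got - want) < 1e-6

    def test_equal_size_screening_detects_more_cases(self, prostate_rates, model, age55):
        t_star = matched_threshold(prostate_rates, model, age55, match="eligible_population")
        s = strategy_summary(
            prostate_rates, model, ScreeningPolicy.personalised(t_star, PROSTATE_RANGE)
        )
        s_age = strategy_summary(prostate_rates, model, age55)
        assert s.detectable_case_fraction >= s_age.detectable_case_fraction

    def test_degenerate_model_returns_cutoff_baseline_risk(self, prostate_rates, age55):
        flat = PolygenicModel(0.0)
        t_star = matched_threshold(prostate_rates, flat, age55, match="eligible_population")
        below = age_conditional_risk(prostate_rates, 54, 64)
        at = age_conditional_risk(prostate_rates, 55, 65)
        assert below < t_star <= at + 1e-9

    def test_unattainable_target_reported(self):
        # with sigma2=0 the eligible fraction is a step function of t;
        # flat hazards make every 10-year window below 61 identical, so
        # the 5/20 target falls inside the jump from 11/20 to 0
        table = make_table(np.arange(50, 70), 0.01, 0.0)
        policy = ScreeningPolicy.age_based(65, (50, 69))
        with pytest.raises(ValueError, match="attain"):
            matched_threshold(table, PolygenicModel(0.0), policy)


class TestVarianceFractionSweep:
    def test_gain_grows_with_known_variance(self, prostate_rates, age55):
        frame = variance_fraction_sweep(
            prostate_rates, 1.58, [0.05, 0.24, 0.5, 1.0], age55
        )
        red = frame["eligible_reduction"].to_numpy()
        assert np.all(np.diff(red) > 0)
        assert red[0] > -1e-9

    def test_no_information_means_no_reduction(self, prostate_rates, age55):
        frame = variance_fraction_sweep(prostate_rates, 1.58, [0.005], age55)
        assert frame["eligible_reduction"].iloc[0] == pytest.approx(0.0, abs=0.02)

    def test_invalid_fractions_rejected(self, prostate_rates, age55):
        with pytest.raises(ValueError):
            variance_fraction_sweep(prostate_rates, 1.58, [0.0], age55)
        with pytest.raises(ValueError):
            variance_fraction_sweep(prostate_rates, -1.0, [0.5], age55)


class TestPolicyValidation:
    def test_cutoff_outside_range(self):
        with pytest.raises(ValueError):
            ScreeningPolicy.age_based(80, (45, 79))

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.1])
    def test_threshold_outside_unit_interval(self, t):
        with pytest.raises(ValueError):
            ScreeningPolicy.personalised(t, (45, 79))
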