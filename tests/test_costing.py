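"""Annualization, human-capital valuation, cohort aggregation, PPP."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcoi import reference
from hfcoi.cohort import PatientRecord
from hfcoi.config import WageConfig
from hfcoi.costing import (
    AnnualPatientCost,
    aggregate_breakdown,
    annual_patient_cost,
    annualize_direct,
    convert_to_ppp,
    human_capital_indirect,
)
from hfcoi.errors import ConfigurationError, DataValidationError


def make_record(**over) -> PatientRecord:
    base = dict(
        id=0, age=60.0, gender="male", nyha_class=2, basic_insurance=True,
        complementary_insurance=False, comorbidity=False, household_head=True,
        employment_status="employed", follow_up_months=4,
        medicine=0.0, treatment_nonhospital=0.0, diagnostic=0.0,
        non_medical_direct=0.0, hospitalized_last_year=False,
        admission_cost=0.0, absenteeism_days=0.0, presenteeism_days=0.0,
        presenteeism_efficiency=1.0, unpaid_work_hours_lost=0.0,
        changed_job=False, died_in_year=False, age_at_death=None,
    )
    base.update(over)
    return PatientRecord(**base)


class TestAnnualizeDirect:
    def test_zero_monthly_is_zero_annual(self):
        assert annualize_direct(make_record())["direct_medicine"] == 0.0

    @pytest.mark.parametrize("months", [2, 4, 6])
    def test_times_twelve_identity(self, months):
        rec = make_record(diagnostic=10_000.0, follow_up_months=months)
        assert annualize_direct(rec)["direct_diagnostic"] == 120_000.0

    def test_admission_cost_counted_once(self):
        """Hand sum: 1e5 * 12 + 2e6 = 3.2e6 for the annual treatment row."""
        rec = make_record(treatment_nonhospital=1e5, hospitalized_last_year=True,
                          admission_cost=2e6)
        assert annualize_direct(rec)["direct_treatment"] == pytest.approx(3.2e6)

    def test_admission_invariant_to_follow_up(self):
        vals = {m: annualize_direct(make_record(
            hospitalized_last_year=True, admission_cost=5e6, follow_up_months=m))
            for m in (2, 4, 6)}
        assert len({v["direct_treatment"] for v in vals.values()}) == 1

    def test_negative_monthly_cost_rejected(self):
        rec = make_record()
        rec.medicine = -1.0
        with pytest.raises(DataValidationError, match="negative"):
            annualize_direct(rec)


class TestHumanCapitalIndirect:
    wages = WageConfig(monthly_wage=2_200_000.0, working_days_per_month=22.0,
                       unpaid_hourly_value=50_000.0)

    def test_absenteeism_direct_product(self):
        """2 absent days/month at daily wage 100,000 -> 2.4M/year."""
        rec = make_record(absenteeism_days=2.0)
        out = human_capital_indirect(rec, self.wages)
        assert out["indirect_absenteeism"] == pytest.approx(2_400_000.0)

    def test_non_employed_contribute_no_work_loss(self):
        rec = make_record(employment_status="housewife", absenteeism_days=5.0,
                          presenteeism_days=5.0, presenteeism_efficiency=0.5,
                          unpaid_work_hours_lost=30.0)
        out = human_capital_indirect(rec, self.wages)
        assert out["indirect_absenteeism"] == 0.0
        assert out["indirect_presenteeism"] == 0.0
        assert out["indirect_unpaid_work"] == pytest.approx(18_000_000.0)

    def test_presenteeism_scales_with_lost_efficiency(self):
        rec = make_record(presenteeism_days=4.0, presenteeism_efficiency=0.75)
        out = human_capital_indirect(rec, self.wages)
        assert out["indirect_presenteeism"] == pytest.approx(4 * 0.25 * 100_000 * 12)

    def test_premature_death_undiscounted(self):
        wages = WageConfig(monthly_wage=10_000_000.0, retirement_age=65.0)
        rec = make_record(died_in_year=True, age_at_death=60.0)
        out = human_capital_indirect(rec, wages)
        assert out["indirect_premature_death"] == pytest.approx(600_000_000.0)

    def test_premature_death_discounted_matches_explicit_loop(self):
        wages = WageConfig(monthly_wage=10_000_000.0, retirement_age=65.0,
                           productivity_discount_rate=0.03)
        rec = make_record(died_in_year=True, age_at_death=60.0)
        out = human_capital_indirect(rec, wages)
        expected = sum(120_000_000.0 * 1.03**-t for t in range(1, 6))
        assert out["indirect_premature_death"] == pytest.approx(expected, rel=1e-12)

    def test_death_after_retirement_costs_nothing(self):
        rec = make_record(died_in_year=True, age_at_death=70.0)
        assert human_capital_indirect(rec, self.wages)["indirect_premature_death"] == 0.0

    def test_missing_age_at_death_rejected(self):
        rec = make_record()
        rec.died_in_year = True  # leave age_at_death None
        with pytest.raises(DataValidationError, match="age_at_death"):
            human_capital_indirect(rec, self.wages)

    def test_job_change_wage_differential(self):
        wages = dataclasses.replace(self.wages, job_change_monthly_wage_loss=100_000.0)
        rec = make_record(changed_job=True)
        assert human_capital_indirect(rec, wages)["indirect_job_change"] == 1_200_000.0
        assert human_capital_indirect(make_record(), wages)["indirect_job_change"] == 0.0

    def test_wage_scale_equivariance(self):
        rec = make_record(absenteeism_days=3.0, presenteeism_days=2.0,
                          presenteeism_efficiency=0.6, unpaid_work_hours_lost=20.0,
                          died_in_year=True, age_at_death=58.0)
        base = human_capital_indirect(rec, self.wages)
        k = 3.0
        scaled_wages = WageConfig(
            monthly_wage=self.wages.monthly_wage * k,
            working_days_per_month=self.wages.working_days_per_month,
            unpaid_hourly_value=self.wages.unpaid_hourly_value * k,
            retirement_age=self.wages.retirement_age,
            job_change_monthly_wage_loss=self.wages.job_change_monthly_wage_loss * k)
        scaled = human_capital_indirect(rec, scaled_wages)
        for key in base:
            assert scaled[key] == pytest.approx(k * base[key], rel=1e-12)


@given(monthly=st.floats(0, 1e7), factor=st.floats(1.0, 10.0))
@settings(max_examples=50, deadline=None)
def test_annualization_linearity(monthly, factor):
    a = annualize_direct(make_record(medicine=monthly))["direct_medicine"]
    b = annualize_direct(make_record(medicine=monthly * factor))["direct_medicine"]
    assert b == pytest.approx(factor * a)


@given(st.lists(st.floats(0, 1e8), min_size=9, max_size=9))
@settings(max_examples=100, deadline=None)
def test_totals_additivity_exact(vals):
    """grand_total == direct_total + indirect_total, exactly."""
    c = AnnualPatientCost(0, *vals)
    assert c.grand_total == c.direct_total + c.indirect_total
    assert c.direct_total == sum(vals[:4])
    assert c.indirect_total == sum(vals[4:])


class TestAggregateBreakdown:
    def _costs(self, rows):
        return [AnnualPatientCost(i, *r) for i, r in enumerate(rows)]

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataValidationError, match="empty"):
            aggregate_breakdown([], [])

    def test_bad_class_label_rejected(self):
        with pytest.raises(DataValidationError, match="class"):
            aggregate_breakdown(self._costs([[1] * 9]), [5])

    def test_single_patient_degenerate_sd(self):
        with pytest.warns(UserWarning, match="single"):
            b = aggregate_breakdown(self._costs([[10, 0, 0, 0, 0, 0, 0, 0, 0]]), [1])
        assert b.degenerate_sd
        assert all(v == 0.0 for v in b.component_sds.values())
        assert b.component_means["direct_medicine"] == 10.0

    def test_reference_indirect_components_sum(self):
        """Feeding the published indirect means as a one-patient cohort
        reproduces the published indirect total exactly."""
        vec = reference.indirect_component_vector()
        with pytest.warns(UserWarning):
            b = aggregate_breakdown(self._costs([[0, 0, 0, 0, *vec]]), [1])
        assert b.indirect_total == pytest.approx(207_147_805.8, abs=0.05)

    def test_mean_total_commutation(self, default_cohort, default_config):
        costs = [annual_patient_cost(r, default_config.wages) for r in default_cohort]
        b = aggregate_breakdown(costs, [r.nyha_class for r in default_cohort])
        grand_mean = np.mean([c.grand_total for c in costs])
        assert b.grand_total == pytest.approx(grand_mean, rel=1e-12)
        assert b.grand_total == pytest.approx(b.direct_total + b.indirect_total)

    def test_shares_sum_to_100(self, default_cohort, default_config):
        costs = [annual_patient_cost(r, default_config.wages) for r in default_cohort]
        b = aggregate_breakdown(costs, [r.nyha_class for r in default_cohort])
        assert b.share_direct + b.share_indirect == 100
        assert sum(b.direct_medical_shares.values()) == 100
        assert sum(b.class_shares.values()) == 100
        assert 0 <= b.share_direct_raw <= 100


class TestPpp:
    def test_identity_factor(self):
        assert convert_to_ppp(1234.0, 1.0) == 1234.0

    def test_zero_amount(self):
        assert convert_to_ppp(0.0) == 0.0

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            convert_to_ppp(100.0, 0.0)

    def test_implied_factor_consistent_across_published_pairs(self):
        """The three published Toman/PPP$ pairs imply the same factor to
        within 0.01%, recovered as their ratio."""
        ratios = [t / p for t, p in reference.PPP_PAIRS]
        assert (max(ratios) - min(ratios)) / min(ratios) < 1e-4
        assert reference.implied_ppp_factor() == pytest.approx(11_900.0, rel=1e-4)
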