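"""Prevalence-based annual costing from person-month observations.

Direct components observed per person-month are annualized by multiplying the
monthly mean by 12; the inpatient admission cost is the exception — the
last-year hospitalization indicator already refers to a one-year window, so
the admission bill enters the annual treatment cost once, not twelve times.
Indirect costs follow the human-capital approach: absenteeism, presenteeism,
unpaid household work, job change, and the present value of earnings lost to
premature death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import integer_shares, present_value_annuity, round_half_up
from .cohort import PatientRecord
from .config import WageConfig
from .errors import ConfigurationError, DataValidationError

#: Toman per international (PPP) dollar; recovered as the ratio of the
#: study's printed Toman/PPP pairs, which agree to within 0.0002%.
DEFAULT_TOMAN_PER_PPP = 11_900.0

DIRECT_FIELDS = ("direct_medicine", "direct_treatment", "direct_diagnostic",
                 "direct_non_medical")
INDIRECT_FIELDS = ("indirect_premature_death", "indirect_absenteeism",
                   "indirect_presenteeism", "indirect_job_change",
                   "indirect_unpaid_work")


@dataclass
class AnnualPatientCost:
    """One patient's annualized cost decomposition (Toman/year)."""

    id: int
    direct_medicine: float
    direct_treatment: float
    direct_diagnostic: float
    direct_non_medical: float
    indirect_premature_death: float
    indirect_absenteeism: float
    indirect_presenteeism: float
    indirect_job_change: float
    indirect_unpaid_work: float

    @property
    def direct_total(self) -> float:
        return sum(getattr(self, f) for f in DIRECT_FIELDS)

    @property
    def indirect_total(self) -> float:
        return sum(getattr(self, f) for f in INDIRECT_FIELDS)

    @property
    def grand_total(self) -> float:
        return self.direct_total + self.indirect_total


def annualize_direct(record: PatientRecord) -> dict[str, float]:
    """Four annual direct components for one patient.

    Monthly person-month means x 12; the admission cost, when the patient was
    hospitalized in the last year, is added to the treatment component once.
    """
    monthly = {
        "direct_medicine": record.medicine,
        "direct_treatment": record.treatment_nonhospital,
        "direct_diagnostic": record.diagnostic,
        "direct_non_medical": record.non_medical_direct,
    }
    for name, v in monthly.items():
        if v < 0:
            raise DataValidationError(
                f"patient {record.id}: negative monthly cost in {name}")
    if record.follow_up_months <= 0:
        raise DataValidationError(
            f"patient {record.id}: follow_up_months must be positive")
    out = {k: v * 12.0 for k, v in monthly.items()}
    if record.hospitalized_last_year:
        out["direct_treatment"] += record.admission_cost
    return out


def human_capital_indirect(record: PatientRecord, wages: WageConfig) -> dict[str, float]:
    """Five annual indirect components under the human-capital approach.

    Absenteeism and presenteeism are valued at the daily market wage and
    apply only to employed patients; unpaid work is valued at the replacement
    shadow wage for everyone; job change costs the configured monthly wage
    differential for a year; premature death costs the present value of
    annual earnings from death to retirement age (year-end convention).
    """
    employed = record.employment_status == "employed"
    daily = wages.daily_wage
    absenteeism = record.absenteeism_days * daily * 12.0 if employed else 0.0
    presenteeism = (record.presenteeism_days * (1.0 - record.presenteeism_efficiency)
                    * daily * 12.0) if employed else 0.0
    unpaid = record.unpaid_work_hours_lost * wages.unpaid_hourly_value * 12.0
    job_change = wages.job_change_monthly_wage_loss * 12.0 if record.changed_job else 0.0
    if record.died_in_year:
        if record.age_at_death is None:
            raise DataValidationError(
                f"patient {record.id}: died_in_year set but age_at_death missing")
        years_lost = max(0.0, wages.retirement_age - record.age_at_death)
        premature = present_value_annuity(
            wages.monthly_wage * 12.0, years_lost, wages.productivity_discount_rate)
    else:
        premature = 0.0
    return {
        "indirect_premature_death": premature,
        "indirect_absenteeism": absenteeism,
        "indirect_presenteeism": presenteeism,
        "indirect_job_change": job_change,
        "indirect_unpaid_work": unpaid,
    }


def annual_patient_cost(record: PatientRecord, wages: WageConfig) -> AnnualPatientCost:
    return AnnualPatientCost(id=record.id,
                             **annualize_direct(record),
                             **human_capital_indirect(record, wages))


@dataclass
class AnnualCostBreakdown:
    """Cohort-level annual cost table: per-component means/SDs, totals, and
    percentage shares (raw and integer-rounded, reconciled to sum to 100)."""

    n: int
    component_means: dict[str, float]
    component_sds: dict[str, float]
    direct_total: float
    indirect_total: float
    grand_total: float
    grand_total_sd: float
    share_direct_raw: float
    share_indirect_raw: float
    share_direct: int
    share_indirect: int
    direct_medical_shares_raw: dict[str, float]
    direct_medical_shares: dict[str, int]
    class_means: dict[int, float]
    class_shares_raw: dict[int, float]
    class_shares: dict[int, int]
    degenerate_sd: bool = False
    notes: list[str] = field(default_factory=list)


def aggregate_breakdown(costs: list[AnnualPatientCost],
                        classes: list[int] | np.ndarray) -> AnnualCostBreakdown:
    """Aggregate patient-level annual costs into the cohort cost table.

    Means are arithmetic means, SDs are sample SDs (n-1); totals of means are
    formed before any rounding; shares are reported raw and half-up rounded
    with largest-remainder reconciliation.  A single-patient cohort gets SD 0
    with a degenerate-sample warning rather than NaN.
    """
    if len(costs) == 0:
        raise DataValidationError("cannot aggregate an empty cohort")
    classes = np.asarray(classes)
    if len(classes) != len(costs):
        raise DataValidationError("classes must align one-to-one with costs")
    if not np.isin(classes, [1, 2, 3, 4]).all():
        bad = sorted(set(classes.tolist()) - {1, 2, 3, 4})
        raise DataValidationError(f"class labels outside 1-4: {bad}")

    n = len(costs)
    degenerate = n == 1
    if degenerate:
        warnings.warn("single-observation cohort: SDs reported as 0",
                      stacklevel=2)

    def col(name: str) -> np.ndarray:
        return np.array([getattr(c, name) for c in costs])

    names = list(DIRECT_FIELDS) + list(INDIRECT_FIELDS)
    means = {f: float(col(f).mean()) for f in names}
    sds = {f: (0.0 if degenerate else float(col(f).std(ddof=1))) for f in names}
    direct_total = sum(means[f] for f in DIRECT_FIELDS)
    indirect_total = sum(means[f] for f in INDIRECT_FIELDS)
    grand = col("grand_total")
    grand_total = direct_total + indirect_total
    grand_sd = 0.0 if degenerate else float(grand.std(ddof=1))

    notes: list[str] = []

    def safe_shares(vals, label):
        if sum(vals) <= 0:
            notes.append(f"{label} shares undefined: zero total")
            return np.full(len(vals), np.nan), np.zeros(len(vals), dtype=int)
        return integer_shares(vals)

    raw_di, rounded_di = safe_shares([direct_total, indirect_total],
                                     "direct/indirect")
    dm_names = ("direct_medicine", "direct_treatment", "direct_diagnostic")
    raw_dm, rounded_dm = safe_shares([means[f] for f in dm_names],
                                     "direct-medical")

    class_means: dict[int, float] = {}
    for k in (1, 2, 3, 4):
        mask = classes == k
        class_means[k] = float(grand[mask].mean()) if mask.any() else float("nan")
    present = [k for k in (1, 2, 3, 4) if not np.isnan(class_means[k])]
    raw_cls, rounded_cls = safe_shares([class_means[k] for k in present],
                                       "per-class")

    return AnnualCostBreakdown(
        n=n,
        component_means=means,
        component_sds=sds,
        direct_total=direct_total,
        indirect_total=indirect_total,
        grand_total=grand_total,
        grand_total_sd=grand_sd,
        share_direct_raw=float(raw_di[0]),
        share_indirect_raw=float(raw_di[1]),
        share_direct=int(rounded_di[0]),
        share_indirect=int(rounded_di[1]),
        direct_medical_shares_raw=dict(zip(dm_names, map(float, raw_dm))),
        direct_medical_shares=dict(zip(dm_names, map(int, rounded_dm))),
        class_means=class_means,
        class_shares_raw=dict(zip(present, map(float, raw_cls))),
        class_shares=dict(zip(present, map(int, rounded_cls))),
        degenerate_sd=degenerate,
        notes=notes,
    )


def convert_to_ppp(amount: float, toman_per_ppp: float = DEFAULT_TOMAN_PER_PPP) -> float:
    """Convert Toman to international (PPP) dollars, 2-decimal reporting."""
    if toman_per_ppp <= 0:
        raise ConfigurationError(
            f"toman_per_ppp must be positive, got {toman_per_ppp}")
    return round(amount / toman_per_ppp, 2)


def share_percent(component: float, total: float, rounded: bool = False) -> float | int:
    """100 x component / total, optionally half-up integer-rounded."""
    if total <= 0:
        raise DataValidationError("share undefined for non-positive total")
    raw = 100.0 * component / total
    return round_half_up(raw) if rounded else raw
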