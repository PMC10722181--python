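"""Published cost figures of the source 502-patient Iranian heart-failure
cohort study, frozen as a fixture.

These are the study's reported numbers, not outputs of this package: annual
per-patient cost means/SDs by component (Toman), per-class annual means, the
Markov model's lifetime per-state costs, and the Toman/PPP$ pairs.  They let
the arithmetic of the reporting layer (component sums, totals, percentage
shares, PPP conversion) be checked against a published table without any
patient data, and they seed the ``--reference-values`` fixture mode of the
CLI.  The study's printed direct-medical *total* exceeds the sum of its
three printed components by ~42,610 Toman; this module stores the printed
figures verbatim and the consistency report flags the discrepancy rather
than reproducing it.
"""

from __future__ import annotations

import numpy as np

# annual per-patient means and SDs, Toman/year
ANNUAL_COMPONENT_MEANS = {
    "direct_medicine": 5_053_339.627,
    "direct_treatment": 44_979_659.96,
    "direct_diagnostic": 2_184_442.024,
    "direct_non_medical": 2_001_997.923,
    "indirect_premature_death": 29_403_824.7,
    "indirect_absenteeism": 9_390_793.338,
    "indirect_presenteeism": 316_600.2596,
    "indirect_job_change": 0.0,
    "indirect_unpaid_work": 168_036_587.5,
}

ANNUAL_COMPONENT_SDS = {
    "direct_medicine": 31_551_902.47,
    "direct_treatment": 100_769_273.6,
    "direct_diagnostic": 6_206_215.425,
    "direct_non_medical": 5_283_430.999,
    "indirect_premature_death": 158_145_195.4,
    "indirect_absenteeism": 28_323_561.66,
    "indirect_presenteeism": 2_292_269.639,
    "indirect_job_change": 0.0,
    "indirect_unpaid_work": 315_918_806.0,
}

# printed aggregate rows (Toman/year per patient)
PRINTED_DIRECT_MEDICAL_TOTAL = 52_260_051.17
PRINTED_DIRECT_TOTAL = 54_262_049.09
PRINTED_INDIRECT_TOTAL = 207_147_805.8
PRINTED_GRAND_TOTAL = 261_409_854.9
PRINTED_GRAND_TOTAL_SD = 369_357_786.7

# annual mean per NYHA class (Toman/year per patient)
CLASS_ANNUAL_MEANS = {
    1: 284_221_375.3,
    2: 184_586_207.1,
    3: 302_719_797.7,
    4: 332_555_849.0,
}

# lifetime per-state costs from the six-state Markov model (Toman)
LIFETIME_STATE_COSTS = {
    "NYHA1": 471_146_883.0,
    "NYHA2": 88_460_400.0,
    "NYHA3": 51_001_097.0,
    "NYHA4": 517_348_089.0,
    "DeathHF": 1_046_004_708.0,
}
PRINTED_LIFETIME_TOTAL = 2_173_961_178.0

# printed Toman / PPP-dollar pairs (grand, indirect, direct)
PPP_PAIRS = (
    (261_409_854.9, 21_967.21),
    (207_147_805.8, 17_407.38),
    (54_262_049.09, 4_559.84),
)

SAMPLE_SIZE = 502

# two-part regression footer as printed (per-observation AIC convention;
# the BIC follows a deviance-based convention whose inputs are not printed)
PRINTED_LOGLIK = -9538.861943
PRINTED_AIC_PER_OBS = 40.87735
PRINTED_BIC = -1835.199
N_REGRESSION_PARAMS = 6


def indirect_component_vector() -> np.ndarray:
    return np.array([ANNUAL_COMPONENT_MEANS[k] for k in (
        "indirect_premature_death", "indirect_absenteeism",
        "indirect_presenteeism", "indirect_job_change",
        "indirect_unpaid_work")])


def direct_medical_vector() -> np.ndarray:
    return np.array([ANNUAL_COMPONENT_MEANS[k] for k in (
        "direct_medicine", "direct_treatment", "direct_diagnostic")])


def lifetime_state_vector() -> np.ndarray:
    return np.array(list(LIFETIME_STATE_COSTS.values()))


def implied_ppp_factor() -> float:
    """Toman per PPP dollar implied by each printed pair; the three ratios
    must agree closely for the fixture to be internally consistent."""
    ratios = [t / p for t, p in PPP_PAIRS]
    spread = (max(ratios) - min(ratios)) / min(ratios)
    if spread > 1e-4:
        raise ValueError(f"PPP pairs disagree by {spread:.2e} relative")
    return float(np.mean(ratios))


def consistency_report() -> dict[str, float | bool]:
    """Recompute the fixture's internal arithmetic and flag discrepancies."""
    ind_sum = float(indirect_component_vector().sum())
    dm_sum = float(direct_medical_vector().sum())
    direct_sum = dm_sum + ANNUAL_COMPONENT_MEANS["direct_non_medical"]
    return {
        "indirect_sum": ind_sum,
        "indirect_matches_printed": abs(ind_sum - PRINTED_INDIRECT_TOTAL) < 0.05,
        "direct_medical_sum": dm_sum,
        "direct_medical_discrepancy": PRINTED_DIRECT_MEDICAL_TOTAL - dm_sum,
        "direct_sum": direct_sum,
        "direct_discrepancy": PRINTED_DIRECT_TOTAL - direct_sum,
        "grand_from_printed_totals": PRINTED_DIRECT_TOTAL + PRINTED_INDIRECT_TOTAL,
        "lifetime_sum": float(lifetime_state_vector().sum()),
        "lifetime_discrepancy": PRINTED_LIFETIME_TOTAL - float(lifetime_state_vector().sum()),
        "implied_ppp_factor": implied_ppp_factor(),
    }
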