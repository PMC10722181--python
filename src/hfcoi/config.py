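"""Configuration objects: cost-component mixtures, wages, cohort marginals.

All monetary amounts are in Toman (the informal Iranian unit equal to ten
rials).  Cost components are modelled as zero-inflated positive mixtures: a
point mass at zero with probability ``zero_prob`` and a right-skewed positive
part (lognormal or gamma) parameterized by its mean and coefficient of
variation.  This is the standard semicontinuous shape of patient-level
health-expenditure data and is what motivates the two-part regression.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

VALID_FAMILIES = ("lognormal", "gamma")

COST_COMPONENTS = ("medicine", "treatment_nonhospital", "diagnostic", "non_medical_direct")

EMPLOYMENT_STATUSES = ("employed", "housewife", "retired", "unemployed")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass
class CostComponentSpec:
    """Zero-inflated positive cost mixture.

    ``positive_mean`` and ``positive_cv`` describe the positive part only;
    :meth:`marginal_moments` gives the implied mixture mean and SD.
    """

    zero_prob: float
    positive_mean: float
    positive_cv: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        _check_prob("zero_prob", self.zero_prob)
        if self.positive_mean < 0:
            raise ConfigurationError(
                f"positive_mean must be >= 0, got {self.positive_mean}"
            )
        if self.positive_cv <= 0:
            raise ConfigurationError(
                f"positive_cv must be > 0, got {self.positive_cv}"
            )
        if self.family not in VALID_FAMILIES:
            raise ConfigurationError(
                f"unknown cost family {self.family!r}; expected one of {VALID_FAMILIES}"
            )

    def marginal_moments(self) -> tuple[float, float]:
        """Mean and SD of the mixture including the zero mass."""
        q = 1.0 - self.zero_prob
        m = self.positive_mean
        s = self.positive_cv * m
        mean = q * m
        var = q * (s * s + m * m) - mean * mean
        return mean, math.sqrt(max(var, 0.0))


@dataclass
class WageConfig:
    """Valuation parameters for human-capital productivity costing.

    Defaults: the statutory Iranian minimum monthly wage of 2022 for market
    work, a 50,000 Toman/h replacement (shadow) wage for unpaid household
    production, retirement at 65, and no discounting of future lost earnings.
    """

    monthly_wage: float = 4_179_750.0
    working_days_per_month: float = 22.0
    unpaid_hourly_value: float = 50_000.0
    retirement_age: float = 65.0
    productivity_discount_rate: float = 0.0
    job_change_monthly_wage_loss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("monthly_wage", "working_days_per_month", "unpaid_hourly_value",
                     "retirement_age"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 <= self.productivity_discount_rate < 1.0):
            raise ConfigurationError("productivity_discount_rate must be in [0, 1)")
        if self.job_change_monthly_wage_loss < 0:
            raise ConfigurationError("job_change_monthly_wage_loss must be >= 0")

    @property
    def daily_wage(self) -> float:
        return self.monthly_wage / self.working_days_per_month


@dataclass
class CohortConfig:
    """Distributional parameters of the synthetic heart-failure cohort.

    The defaults emulate a 502-patient hospital sample: NYHA class
    frequencies 106/189/88/119, 61.1% male, 91.2% basic insurance, 42.4%
    complementary insurance, 61% comorbidity, 72% household heads, age
    63.46 +/- 14.27 truncated to [8, 95], follow-up of 2, 4 or 6 months.
    Cost components are on the per-month scale; an inpatient admission cost
    is drawn once per year for hospitalized patients.
    """

    n_patients: int = 502
    class_probs: tuple[float, float, float, float] = (
        106 / 502, 189 / 502, 88 / 502, 119 / 502)
    p_male: float = 0.611
    p_basic_insurance: float = 0.912
    p_complementary: float = 0.424
    p_comorbidity: float = 0.61
    p_household_head: float = 0.72
    age_mean: float = 63.46
    age_sd: float = 14.27
    age_min: float = 8.0
    age_max: float = 95.0
    follow_up_choices: tuple[tuple[int, float], ...] = ((2, 1 / 3), (4, 1 / 3), (6, 1 / 3))
    p_hospitalized_year: float = 0.60
    p_death_in_year: float = 0.05
    p_changed_job: float = 0.0
    #: probability a patient incurs no cost of any kind over the year; such
    #: patients are what the probit part of the two-part model explains
    p_zero_cost: float = 35 / 502
    employment_probs: tuple[tuple[str, float], ...] = (
        ("employed", 0.35), ("housewife", 0.40), ("retired", 0.25), ("unemployed", 0.0))
    # monthly-scale cost mixtures, one per direct component
    components: dict[str, CostComponentSpec] = field(default_factory=dict)
    admission_cost: CostComponentSpec | None = None
    absenteeism_days: CostComponentSpec | None = None
    presenteeism_days: CostComponentSpec | None = None
    presenteeism_efficiency_range: tuple[float, float] = (0.4, 0.9)
    unpaid_work_hours: CostComponentSpec | None = None
    # per-class multiplier on direct cost-component means (1.0 = independence)
    class_cost_multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    wages: WageConfig = field(default_factory=WageConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if len(self.class_probs) != 4:
            raise ConfigurationError("class_probs must have exactly 4 entries (NYHA I-IV)")
        for i, p in enumerate(self.class_probs):
            _check_prob(f"class_probs[{i}]", p)
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_probs must sum to 1 within 1e-9, got {sum(self.class_probs)}"
            )
        for name in ("p_male", "p_basic_insurance", "p_complementary", "p_comorbidity",
                     "p_household_head", "p_hospitalized_year", "p_death_in_year",
                     "p_changed_job", "p_zero_cost"):
            _check_prob(name, getattr(self, name))
        if not (self.age_min <= self.age_mean <= self.age_max):
            raise ConfigurationError(
                f"age_min <= age_mean <= age_max required, got "
                f"{self.age_min}/{self.age_mean}/{self.age_max}"
            )
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        months = [m for m, _ in self.follow_up_choices]
        probs = [p for _, p in self.follow_up_choices]
        if any(m not in (2, 4, 6) for m in months):
            raise ConfigurationError(
                f"follow_up_choices months must be in {{2, 4, 6}}, got {months}"
            )
        for p in probs:
            _check_prob("follow_up_choices probability", p)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("follow_up_choices probabilities must sum to 1")
        emp = dict(self.employment_probs)
        if set(emp) - set(EMPLOYMENT_STATUSES):
            raise ConfigurationError(
                f"unknown employment status in employment_probs: "
                f"{sorted(set(emp) - set(EMPLOYMENT_STATUSES))}"
            )
        if abs(sum(emp.values()) - 1.0) > 1e-9:
            raise ConfigurationError("employment_probs must sum to 1")
        lo, hi = self.presenteeism_efficiency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("presenteeism_efficiency_range must satisfy 0 <= lo <= hi <= 1")
        if len(self.class_cost_multipliers) != 4 or any(
                m <= 0 for m in self.class_cost_multipliers):
            raise ConfigurationError("class_cost_multipliers must be 4 positive factors")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: CostComponentSpec) -> dict[str, Any]:
    return dataclasses.asdict(spec)


def _spec_from_dict(d: dict[str, Any], where: str) -> CostComponentSpec:
    try:
        return CostComponentSpec(**d)
    except TypeError as exc:
        raise ConfigurationError(f"bad cost-component spec at {where}: {exc}") from None


def cohort_config_to_dict(cfg: CohortConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    # tuples -> lists handled by asdict; dataclass fields already expanded
    return d


def cohort_config_from_dict(d: dict[str, Any]) -> CohortConfig:
    d = dict(d)
    try:
        if "wages" in d and isinstance(d["wages"], dict):
            d["wages"] = WageConfig(**d["wages"])
        if "components" in d:
            d["components"] = {
                k: (_spec_from_dict(v, f"components[{k}]") if isinstance(v, dict) else v)
                for k, v in d["components"].items()
            }
        for key in ("admission_cost", "absenteeism_days", "presenteeism_days",
                    "unpaid_work_hours"):
            if isinstance(d.get(key), dict):
                d[key] = _spec_from_dict(d[key], key)
        for key in ("class_probs", "class_cost_multipliers",
                    "presenteeism_efficiency_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "follow_up_choices" in d:
            d["follow_up_choices"] = tuple((int(m), float(p)) for m, p in d["follow_up_choices"])
        if "employment_probs" in d:
            ep = d["employment_probs"]
            if isinstance(ep, dict):
                d["employment_probs"] = tuple(ep.items())
            else:
                d["employment_probs"] = tuple((str(s), float(p)) for s, p in ep)
        return CohortConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(f"bad cohort configuration: {exc}") from None


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            return json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"invalid JSON in {path}: {exc}") from None
    try:
        out = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from None
    if not isinstance(out, dict):
        raise ConfigurationError(f"configuration in {path} must be a mapping")
    return out


def save_config(d: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
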