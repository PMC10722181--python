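"""Six-state Markov cohort model for incidence-based lifetime costing.

States: NYHA I-IV (alive, each with an annual cost), death from heart
failure, and death from other causes.  Both death states are absorbing.
Death from heart failure carries a one-time entry cost — the present value of
earnings lost at death — which is how a death state can accumulate a large
share of lifetime cost; death from other causes is costless.  The cohort
recursion propagates a state-occupancy distribution through the transition
matrix for a fixed number of one-year cycles, accruing discounted per-state
costs each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from ._util import integer_shares
from .errors import DataValidationError, SpecValidationError

STATE_LABELS = ("NYHA1", "NYHA2", "NYHA3", "NYHA4", "DeathHF", "DeathOther")
N_STATES = 6
ALIVE = slice(0, 4)
DEATH_HF = 4
DEATH_OTHER = 5
#: states that can be attributed cost: the four alive states plus DeathHF
COSTED_LABELS = STATE_LABELS[:5]

_ROW_TOL = 1e-9


@dataclass
class MarkovSpec:
    """Inputs of the cohort model.

    ``transition_matrix`` holds per-cycle probabilities (rows = from-state in
    the order of :data:`STATE_LABELS`); ``state_annual_cost`` is the annual
    cost of each alive state; ``death_hf_entry_cost`` is charged once on
    entry to the heart-failure death state.  Cycle length is fixed at one
    year.
    """

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    state_annual_cost: np.ndarray  # 4 alive states
    death_hf_entry_cost: float
    horizon_cycles: int = 25
    discount_rate: float = 0.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.state_annual_cost = np.asarray(self.state_annual_cost, dtype=float)

    def to_dict(self) -> dict[str, Any]:
        return {
            "states": list(STATE_LABELS),
            "transition_matrix": self.transition_matrix.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "state_annual_cost": self.state_annual_cost.tolist(),
            "death_hf_entry_cost": float(self.death_hf_entry_cost),
            "horizon_cycles": int(self.horizon_cycles),
            "discount_rate": float(self.discount_rate),
            "half_cycle_correction": bool(self.half_cycle_correction),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MarkovSpec":
        d = {k: v for k, v in d.items() if k != "states"}
        return cls(**d)


def spec_violations(spec: MarkovSpec) -> list[str]:
    """Every structural violation of the spec, not just the first."""
    v: list[str] = []
    P = spec.transition_matrix
    if P.shape != (N_STATES, N_STATES):
        return [f"transition_matrix must be {N_STATES}x{N_STATES}, got {P.shape}"]
    for i, row in enumerate(P):
        if ((row < -1e-12) | (row > 1 + 1e-12)).any():
            v.append(f"row {i} ({STATE_LABELS[i]}): entries outside [0, 1]")
        if abs(row.sum() - 1.0) > _ROW_TOL:
            v.append(f"row {i} ({STATE_LABELS[i]}): sums to {row.sum():.12g}, not 1")
    for s in (DEATH_HF, DEATH_OTHER):
        if abs(P[s, s] - 1.0) > _ROW_TOL or np.abs(np.delete(P[s], s)).max() > _ROW_TOL:
            v.append(f"{STATE_LABELS[s]} must be absorbing (self-transition 1)")
    pi0 = spec.initial_distribution
    if pi0.shape != (N_STATES,):
        v.append(f"initial_distribution must have {N_STATES} entries")
    else:
        if abs(pi0.sum() - 1.0) > _ROW_TOL:
            v.append(f"initial_distribution sums to {pi0.sum():.12g}, not 1")
        if (pi0 < -1e-12).any():
            v.append("initial_distribution has negative entries")
        if pi0[DEATH_HF] > _ROW_TOL or pi0[DEATH_OTHER] > _ROW_TOL:
            v.append("initial_distribution must put zero mass on death states")
    if spec.state_annual_cost.shape != (4,):
        v.append("state_annual_cost must have 4 entries (alive states)")
    elif (spec.state_annual_cost < 0).any():
        v.append("state_annual_cost entries must be >= 0")
    if spec.death_hf_entry_cost < 0:
        v.append("death_hf_entry_cost must be >= 0")
    if spec.horizon_cycles < 1:
        v.append(f"horizon_cycles must be >= 1, got {spec.horizon_cycles}")
    if spec.discount_rate < 0:
        v.append("discount_rate must be >= 0")
    return v


def validate_spec(spec: MarkovSpec) -> MarkovSpec:
    """Return the spec unchanged, or raise with the full violation list."""
    v = spec_violations(spec)
    if v:
        raise SpecValidationError(v)
    return spec


@dataclass
class MarkovResult:
    """Outputs: occupancy trace, lifetime cost and its per-state attribution."""

    occupancy: np.ndarray  # (horizon+1, 6)
    lifetime_cost: float
    state_costs: np.ndarray  # 5: NYHA1-4 + DeathHF
    life_years: float
    hf_death_probability: float
    discount_rate: float
    half_cycle_correction: bool
    shares_raw: np.ndarray = field(default=None)  # type: ignore[assignment]
    shares_rounded: np.ndarray = field(default=None)  # type: ignore[assignment]


def run_cohort(spec: MarkovSpec) -> MarkovResult:
    """Propagate the cohort and accumulate discounted per-state costs.

    Cycle ``t`` (t = 0..horizon-1) accrues each alive state's annual cost
    weighted by its start-of-cycle occupancy (or the average of adjacent
    occupancies under half-cycle correction), plus the entry cost times the
    mass newly absorbed into the heart-failure death state during the cycle;
    everything accrued in cycle ``t`` is discounted by ``(1+r)^-t``.
    """
    validate_spec(spec)
    T = spec.horizon_cycles
    P = spec.transition_matrix
    occ = np.empty((T + 1, N_STATES))
    occ[0] = spec.initial_distribution
    for t in range(T):
        occ[t + 1] = occ[t] @ P

    disc = (1.0 + spec.discount_rate) ** -np.arange(T)
    if spec.half_cycle_correction:
        alive_occ = 0.5 * (occ[:-1, ALIVE] + occ[1:, ALIVE])
    else:
        alive_occ = occ[:-1, ALIVE]
    # per-state occupancy costs: (T,4) * costs, discounted per cycle
    alive_costs = (alive_occ * spec.state_annual_cost) * disc[:, None]
    entry_mass = occ[1:, DEATH_HF] - occ[:-1, DEATH_HF]
    entry_costs = entry_mass * spec.death_hf_entry_cost * disc

    state_costs = np.empty(5)
    state_costs[:4] = alive_costs.sum(axis=0)
    state_costs[4] = entry_costs.sum()
    total = float(state_costs.sum())
    life_years = float(alive_occ.sum())  # cycle length 1 year, undiscounted

    result = MarkovResult(
        occupancy=occ,
        lifetime_cost=total,
        state_costs=state_costs,
        life_years=life_years,
        hf_death_probability=float(occ[-1, DEATH_HF]),
        discount_rate=spec.discount_rate,
        half_cycle_correction=spec.half_cycle_correction,
    )
    if total > 0:
        result.shares_raw, result.shares_rounded = state_shares(state_costs)
    return result


def state_shares(attributed: MarkovResult | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Percent share of each costed state, raw and integer-rounded.

    Accepts a :class:`MarkovResult` or a bare attribution vector (e.g. a
    published per-state cost table).  Scale-invariant; errors on zero total.
    """
    vec = attributed.state_costs if isinstance(attributed, MarkovResult) else np.asarray(attributed, float)
    if vec.sum() <= 0:
        raise DataValidationError("state shares undefined: total lifetime cost is 0")
    return integer_shares(vec)


def life_years(result: MarkovResult) -> float:
    """Expected (undiscounted) life years over the model horizon."""
    return result.life_years


def random_spec(rng: np.random.Generator,
                horizon_cycles: int | None = None,
                discount_rate: float | None = None) -> MarkovSpec:
    """A random valid specification, for engine cross-validation studies.

    Alive rows are Dirichlet draws (so every row is a proper distribution
    with both death exits possible), the initial distribution is a Dirichlet
    over the alive states, and state costs / the entry cost are drawn on a
    realistic Toman scale.
    """
    P = np.zeros((N_STATES, N_STATES))
    for i in range(4):
        P[i] = rng.dirichlet(np.ones(N_STATES))
    P[DEATH_HF, DEATH_HF] = 1.0
    P[DEATH_OTHER, DEATH_OTHER] = 1.0
    pi0 = np.zeros(N_STATES)
    pi0[:4] = rng.dirichlet(np.ones(4))
    return MarkovSpec(
        transition_matrix=P,
        initial_distribution=pi0,
        state_annual_cost=rng.uniform(5e7, 4e8, size=4),
        death_hf_entry_cost=rng.uniform(0, 1.5e9),
        horizon_cycles=horizon_cycles if horizon_cycles is not None
        else int(rng.integers(1, 26)),
        discount_rate=discount_rate if discount_rate is not None
        else float(rng.choice([0.0, 0.03, 0.05])),
    )


# ---------------------------------------------------------------------------
# defaults and calibration


def default_markov_spec(state_annual_cost: np.ndarray | None = None,
                        death_hf_entry_cost: float = 600_000_000.0,
                        horizon_cycles: int = 25,
                        discount_rate: float = 0.0) -> MarkovSpec:
    """A runnable default specification.

    The transition matrix is a synthetic placeholder with plausible
    progression/regression and mortality gradients across NYHA classes — the
    model structure is fixed, but real per-cycle probabilities must come from
    treatment-effectiveness literature and should be supplied via config.
    Default state costs are the study's published per-class annual means;
    the default initial distribution is the sample's class mix.
    """
    P = np.array([
        #  I     II    III   IV    dHF   dOther
        [0.70, 0.17, 0.04, 0.01, 0.03, 0.05],
        [0.10, 0.64, 0.14, 0.03, 0.04, 0.05],
        [0.02, 0.10, 0.60, 0.15, 0.07, 0.06],
        [0.01, 0.02, 0.10, 0.57, 0.22, 0.08],
        [0.00, 0.00, 0.00, 0.00, 1.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 0.00, 1.00],
    ])
    if state_annual_cost is None:
        state_annual_cost = np.array(
            [284_221_375.3, 184_586_207.1, 302_719_797.7, 332_555_849.0])
    pi0 = np.array([106, 189, 88, 119, 0, 0], dtype=float) / 502.0
    return MarkovSpec(
        transition_matrix=P,
        initial_distribution=pi0,
        state_annual_cost=np.asarray(state_annual_cost, float),
        death_hf_entry_cost=death_hf_entry_cost,
        horizon_cycles=horizon_cycles,
        discount_rate=discount_rate,
    )


def calibrate_transition_matrix(target_state_costs: np.ndarray,
                                template: MarkovSpec,
                                max_nfev: int = 200) -> MarkovSpec:
    """Least-squares search for alive-row transition probabilities whose
    cohort run reproduces ``target_state_costs`` (relative residuals).

    A convenience for exploring parameterizations when only the per-state
    cost attribution of a model is known; rows are parameterized by softmax
    logits so every iterate is a valid stochastic matrix.  Not an estimation
    method — there is no claim of a unique solution.
    """
    target = np.asarray(target_state_costs, float)
    base = template.transition_matrix.copy()
    logits0 = np.log(np.clip(base[:4], 1e-6, None)).ravel()

    def build(logits: np.ndarray) -> MarkovSpec:
        rows = logits.reshape(4, N_STATES)
        e = np.exp(rows - rows.max(axis=1, keepdims=True))
        P = base.copy()
        P[:4] = e / e.sum(axis=1, keepdims=True)
        return MarkovSpec(
            transition_matrix=P,
            initial_distribution=template.initial_distribution,
            state_annual_cost=template.state_annual_cost,
            death_hf_entry_cost=template.death_hf_entry_cost,
            horizon_cycles=template.horizon_cycles,
            discount_rate=template.discount_rate,
            half_cycle_correction=template.half_cycle_correction,
        )

    scale = np.where(target > 0, target, 1.0)

    def resid(logits: np.ndarray) -> np.ndarray:
        res = run_cohort(build(logits))
        return (res.state_costs - target) / scale

    sol = least_squares(resid, logits0, max_nfev=max_nfev)
    return build(sol.x)
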