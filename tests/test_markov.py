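"""Six-state Markov engine: validation, closed forms, microsimulation
cross-check, structural invariants."""

import dataclasses

import numpy as np
import pytest

from hfcoi import reference
from hfcoi.errors import DataValidationError, SpecValidationError
from hfcoi.markov import (
    MarkovSpec,
    calibrate_transition_matrix,
    default_markov_spec,
    life_years,
    random_spec,
    run_cohort,
    spec_violations,
    state_shares,
    validate_spec,
)
from hfcoi.microsim import microsimulate


def identity_spec(cost=1e6, horizon=10, discount=0.0, entry_cost=0.0,
                  half_cycle=False) -> MarkovSpec:
    """All mass in NYHA1 with a self-loop: a degenerate but legal model."""
    return MarkovSpec(
        transition_matrix=np.eye(6),
        initial_distribution=np.array([1.0, 0, 0, 0, 0, 0]),
        state_annual_cost=np.array([cost, 2e6, 3e6, 4e6]),
        death_hf_entry_cost=entry_cost,
        horizon_cycles=horizon,
        discount_rate=discount,
        half_cycle_correction=half_cycle,
    )


class TestValidation:
    def test_identity_matrix_is_legal(self):
        assert spec_violations(identity_spec()) == []

    def test_row_sum_violation_names_row(self):
        spec = identity_spec()
        spec.transition_matrix = spec.transition_matrix.copy()
        spec.transition_matrix[1, 1] = 0.9
        msgs = spec_violations(spec)
        assert any("row 1" in m for m in msgs)

    def test_death_exit_is_absorbing_violation(self):
        spec = identity_spec()
        P = spec.transition_matrix.copy()
        P[4, 4] = 0.9
        P[4, 0] = 0.1
        spec.transition_matrix = P
        with pytest.raises(SpecValidationError, match="absorbing"):
            validate_spec(spec)

    def test_all_violations_reported_not_just_first(self):
        spec = identity_spec()
        P = spec.transition_matrix.copy()
        P[0, 0] = 0.5  # row 0 sums to 0.5
        P[4, 4] = 0.0  # DeathHF not absorbing and row sums to 0
        spec.transition_matrix = P
        spec.initial_distribution = np.array([0.5, 0, 0, 0, 0.5, 0])
        msgs = spec_violations(spec)
        assert len(msgs) >= 3

    def test_initial_mass_on_death_states_rejected(self):
        spec = identity_spec()
        spec.initial_distribution = np.array([0, 0, 0, 0, 0, 1.0])
        with pytest.raises(SpecValidationError, match="death"):
            validate_spec(spec)


class TestClosedForms:
    def test_absorbing_self_loop_total_is_T_times_c(self):
        res = run_cohort(identity_spec(cost=1e6, horizon=10))
        assert res.lifetime_cost == pytest.approx(1e7, rel=1e-12)
        assert res.state_costs[0] == pytest.approx(1e7, rel=1e-12)
        assert np.all(res.state_costs[1:] == 0.0)

    def test_zero_costs_zero_total(self, rng):
        spec = random_spec(rng)
        spec.state_annual_cost = np.zeros(4)
        spec.death_hf_entry_cost = 0.0
        assert run_cohort(spec).lifetime_cost == 0.0

    @pytest.mark.parametrize("q", [0.05, 0.3, 0.9])
    def test_geometric_survival_life_years(self, q):
        """Alive/dead two-state chain: life years = sum_{t<T} (1-q)^t."""
        P = np.eye(6)
        P[0, 0] = 1 - q
        P[0, 5] = q
        spec = identity_spec(horizon=25)
        spec.transition_matrix = P
        res = run_cohort(spec)
        expected = sum((1 - q) ** t for t in range(25))
        assert life_years(res) == pytest.approx(expected, abs=1e-9)

    def test_discounted_self_loop_geometric(self):
        r = 0.05
        res = run_cohort(identity_spec(cost=1e6, horizon=25, discount=r))
        expected = 1e6 * sum((1 + r) ** -t for t in range(25))
        assert res.lifetime_cost == pytest.approx(expected, rel=1e-12)


class TestMicrosimulationAgreement:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recursion_matches_independent_microsimulation(self, seed):
        """Matrix recursion within 3 Monte-Carlo SEs of 1e5 sampled paths."""
        rng = np.random.default_rng(seed)
        spec = random_spec(rng)
        cohort = run_cohort(spec)
        micro = microsimulate(spec, 100_000, rng)
        assert abs(cohort.lifetime_cost - micro.mean_cost) < 3 * micro.se_cost

    def test_state_attribution_agrees(self):
        rng = np.random.default_rng(3)
        spec = random_spec(rng, horizon_cycles=10)
        cohort = run_cohort(spec)
        micro = microsimulate(spec, 100_000, rng)
        # per-state SE is at most the total's scale; use a relative band
        np.testing.assert_allclose(cohort.state_costs, micro.mean_state_costs,
                                   rtol=0.05, atol=3 * micro.se_cost)

    def test_half_cycle_unsupported_in_microsim(self, rng):
        spec = random_spec(rng)
        spec.half_cycle_correction = True
        with pytest.raises(ValueError, match="half-cycle"):
            microsimulate(spec, 10, rng)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_probability_conservation_and_absorbing_monotonicity(self, seed):
        spec = random_spec(np.random.default_rng(seed))
        occ = run_cohort(spec).occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(occ[:, 4]) >= -1e-12)
        assert np.all(np.diff(occ[:, 5]) >= -1e-12)

    def test_attribution_completeness(self, rng):
        res = run_cohort(random_spec(rng))
        assert res.state_costs.sum() == pytest.approx(res.lifetime_cost, rel=1e-12)

    def test_cost_monotonicity(self, rng):
        spec = random_spec(rng)
        base = run_cohort(spec).lifetime_cost
        up = dataclasses.replace(spec, state_annual_cost=spec.state_annual_cost * 1.1)
        assert run_cohort(up).lifetime_cost >= base
        up_entry = dataclasses.replace(
            spec, death_hf_entry_cost=spec.death_hf_entry_cost + 1e8)
        assert run_cohort(up_entry).lifetime_cost >= base

    def test_discount_monotonicity(self, rng):
        spec = random_spec(rng, discount_rate=0.0)
        base = run_cohort(spec).lifetime_cost
        for r in (0.03, 0.05, 0.10):
            disc = dataclasses.replace(spec, discount_rate=r)
            assert run_cohort(disc).lifetime_cost <= base + 1e-9

    @pytest.mark.parametrize("seed,t1", [(0, 3), (1, 10), (2, 17)])
    def test_horizon_consistency(self, seed, t1):
        """Cost over T cycles = cost over T1 + discounted continuation from
        the T1 occupancy (death mass accrues nothing further)."""
        spec = random_spec(np.random.default_rng(seed), horizon_cycles=25)
        full = run_cohort(spec).lifetime_cost
        head = run_cohort(dataclasses.replace(spec, horizon_cycles=t1))
        occ_t1 = head.occupancy[-1]
        alive_mass = occ_t1[:4].sum()
        cont_init = np.zeros(6)
        cont_init[:4] = occ_t1[:4] / alive_mass
        cont_spec = dataclasses.replace(spec, horizon_cycles=25 - t1,
                                        initial_distribution=cont_init)
        cont = run_cohort(cont_spec).lifetime_cost
        disc = (1 + spec.discount_rate) ** -t1
        assert full == pytest.approx(head.lifetime_cost + disc * alive_mass * cont,
                                     rel=1e-9)

    def test_half_cycle_telescoping_identity(self, rng):
        """At zero discount, averaging adjacent occupancies telescopes:
        hc_total = plain_total + 0.5 * sum_s (occ_T[s] - occ_0[s]) * c_s."""
        spec = random_spec(rng, discount_rate=0.0)
        plain_res = run_cohort(spec)
        hc = run_cohort(dataclasses.replace(spec, half_cycle_correction=True))
        occ = plain_res.occupancy
        correction = 0.5 * ((occ[-1, :4] - occ[0, :4]) * spec.state_annual_cost).sum()
        assert hc.lifetime_cost == pytest.approx(
            plain_res.lifetime_cost + correction, rel=1e-9)


class TestStateShares:
    def test_single_nonzero_state(self):
        raw, rounded = state_shares(np.array([0, 0, 5.0, 0, 0]))
        assert list(rounded) == [0, 0, 100, 0, 0]

    def test_published_lifetime_costs_round_to_reported_shares(self):
        """The five published per-state lifetime costs give 22/4/2/24/48."""
        raw, rounded = state_shares(reference.lifetime_state_vector())
        assert list(rounded) == [22, 4, 2, 24, 48]

    def test_scale_invariance(self, rng):
        v = rng.uniform(1, 10, size=5)
        raw1, r1 = state_shares(v)
        raw2, r2 = state_shares(v * 17.3)
        np.testing.assert_allclose(raw1, raw2)
        assert list(r1) == list(r2)

    def test_zero_total_errors(self):
        with pytest.raises(DataValidationError, match="undefined"):
            state_shares(np.zeros(5))


def test_calibration_helper_reduces_residuals():
    template = default_markov_spec()
    target = run_cohort(template).state_costs * np.array([1.1, 0.9, 1.0, 1.05, 0.95])
    fitted = calibrate_transition_matrix(target, template, max_nfev=60)
    got = run_cohort(fitted).state_costs
    base_err = np.abs(run_cohort(template).state_costs - target).sum()
    assert np.abs(got - target).sum() < base_err
    assert spec_violations(fitted) == []
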