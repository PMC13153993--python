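"""Cohort engine: matrix assembly, trace propagation, reward accrual."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from startcea.cohort_engine import (
    CohortTrace,
    InfeasibleRowError,
    accumulate_costs,
    accumulate_qalys,
    build_matrix,
    run_trace,
)
from startcea.param_model import HealthState


def _with_transitions(params, arm=None, **overrides):
    out = params.copy()
    for a in [arm] if arm else ("start", "usual_care"):
        out.transitions[a] = dataclasses.replace(out.transitions[a], **overrides)
    out.allow_arm_specific_death = True
    return out


@st.composite
def feasible_transitions(draw):
    """Random feasible per-arm transition probabilities."""
    p_init = draw(st.floats(0, 0.9))
    p_du = draw(st.floats(0, min(0.1, 1 - p_init)))
    p_is = draw(st.floats(0, 0.95))
    p_di = draw(st.floats(0, 1 - p_is))
    p_ss = draw(st.floats(0, 0.95))
    p_ds = draw(st.floats(0, 1 - p_ss))
    p_post = draw(st.floats(0, 1 - p_du))
    return dict(
        p_init_first_cycle=p_init,
        p_init_post_discharge=p_post,
        p_initiated_to_sustained=p_is,
        p_death_initiated=p_di,
        p_sustained_stay=p_ss,
        p_death_sustained=p_ds,
        p_death_untreated=p_du,
    )


class TestBuildMatrix:
    def test_first_cycle_untreated_row_from_trial_rates(self, calibrated_params):
        m = build_matrix(calibrated_params, "start", 1).probs
        expected = [1 - 0.573 - 0.0041, 0.573, 0.0, 0.0041]
        assert m[HealthState.UNTREATED] == pytest.approx(expected)

    def test_post_discharge_cycles_use_shared_rate(self, calibrated_params):
        p = calibrated_params.transitions["start"].p_init_post_discharge
        for arm in ("start", "usual_care"):
            m = build_matrix(calibrated_params, arm, 5).probs
            assert m[HealthState.UNTREATED, HealthState.INITIATED] == pytest.approx(p)

    def test_sustained_row_residual_reverts_to_untreated(self, calibrated_params):
        m = build_matrix(calibrated_params, "start", 3).probs
        assert m[HealthState.SUSTAINED] == pytest.approx(
            [1 - 0.549 - 0.0005, 0.0, 0.549, 0.0005]
        )

    def test_initiated_state_is_transient(self, calibrated_params):
        # residual mass reverts to untreated; no self-loop
        m = build_matrix(calibrated_params, "usual_care", 2).probs
        row = m[HealthState.INITIATED]
        assert row[HealthState.INITIATED] == 0.0
        assert row[HealthState.UNTREATED] == pytest.approx(1 - 0.708 - 0.0012)

    def test_dead_row_absorbing(self, calibrated_params):
        for cycle in (1, 6, 12):
            m = build_matrix(calibrated_params, "usual_care", cycle).probs
            assert m[HealthState.DEAD] == pytest.approx([0, 0, 0, 1])

    def test_infeasible_row_named(self, calibrated_params):
        bad = _with_transitions(
            calibrated_params, p_initiated_to_sustained=0.95, p_death_initiated=0.1
        )
        with pytest.raises(InfeasibleRowError, match="initiated"):
            build_matrix(bad, "start", 1)

    @given(t=feasible_transitions())
    @settings(max_examples=50, deadline=None)
    def test_rows_stochastic_for_random_feasible_inputs(self, t):
        from startcea.param_model import ArmTransitionParams, ParameterSet

        params = ParameterSet(
            transitions={
                "start": ArmTransitionParams(**t),
                "usual_care": ArmTransitionParams(**t),
            },
            values=None,  # not needed for matrix assembly
        )
        for cycle in (1, 2):
            m = build_matrix(params, "start", cycle).probs
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()


class TestRunTrace:
    def test_conservation_with_no_exits(self, base_params):
        frozen = _with_transitions(
            base_params,
            p_init_first_cycle=0.0,
            p_init_post_discharge=0.0,
            p_death_untreated=0.0,
            p_death_initiated=0.0,
            p_death_sustained=0.0,
        )
        trace = run_trace(frozen, "start")
        assert np.allclose(trace.occupancy[:, HealthState.UNTREATED], 1.0)

    def test_forced_first_cycle_transition(self, base_params):
        forced = _with_transitions(
            base_params,
            p_init_first_cycle=1.0,
            p_init_post_discharge=0.0,
            p_death_untreated=0.0,
            p_death_initiated=0.0,
            p_death_sustained=0.0,
        )
        trace = run_trace(forced, "start")
        assert trace.occupancy[1] == pytest.approx([0, 1, 0, 0])

    def test_matches_matrix_power_oracle(self, calibrated_params):
        # independent oracle: explicit left-multiplication chain
        trace = run_trace(calibrated_params, "start")
        state = np.array([1.0, 0, 0, 0])
        for cycle in range(1, 13):
            state = state @ build_matrix(calibrated_params, "start", cycle).probs
            assert np.allclose(trace.occupancy[cycle], state, atol=1e-12)

    @given(t=feasible_transitions())
    @settings(max_examples=30, deadline=None)
    def test_conservation_and_monotone_dead_for_random_inputs(self, t, base_params):
        params = _with_transitions(base_params, **t)
        trace = run_trace(params, "usual_care")
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        dead = trace.occupancy[:, HealthState.DEAD]
        assert (np.diff(dead) >= -1e-12).all()

    def test_uncalibrated_params_rejected(self, base_params):
        with pytest.raises(ValueError, match="uncalibrated"):
            run_trace(base_params, "start")


class TestRewardAccrual:
    """Rewards accrue at all 13 stage boundaries of a 12-cycle run."""

    def _locked_trace(self, state, horizon=12):
        occ = np.zeros((horizon + 1, 4))
        occ[:, state] = 1.0
        return CohortTrace(occupancy=occ)

    def test_locked_untreated_qalys_closed_form(self, base_params):
        trace = self._locked_trace(HealthState.UNTREATED)
        assert accumulate_qalys(trace, base_params.values) == pytest.approx(13 * 0.047)

    def test_locked_sustained_qalys_closed_form(self, base_params):
        trace = self._locked_trace(HealthState.SUSTAINED)
        assert accumulate_qalys(trace, base_params.values) == pytest.approx(13 * 0.064)

    def test_all_dead_accrues_nothing(self, base_params):
        trace = self._locked_trace(HealthState.DEAD)
        assert accumulate_qalys(trace, base_params.values) == 0.0
        assert accumulate_costs(
            trace, base_params.with_post_discharge(0.1), "usual_care", "health_sector"
        ) == 0.0

    def test_locked_untreated_cost_closed_form(self, base_params):
        pset = base_params.with_post_discharge(0.1)
        trace = self._locked_trace(HealthState.UNTREATED)
        uc = accumulate_costs(trace, pset, "usual_care", "health_sector")
        assert uc == pytest.approx(13 * 4184)
        start = accumulate_costs(trace, pset, "start", "health_sector")
        assert start == pytest.approx(13 * 4184 + 640.10, abs=0.01)

    def test_societal_adds_state_mapped_costs(self, base_params):
        pset = base_params.with_post_discharge(0.1)
        v = pset.values
        trace = self._locked_trace(HealthState.SUSTAINED)
        hs = accumulate_costs(trace, pset, "usual_care", "health_sector")
        soc = accumulate_costs(trace, pset, "usual_care", "limited_societal")
        extra = v.patient_time_cost + v.transportation_cost + v.absenteeism_treated
        assert soc - hs == pytest.approx(13 * extra)

    def test_dead_fraction_accrues_lost_earnings(self, base_params):
        pset = base_params.with_post_discharge(0.1)
        trace = self._locked_trace(HealthState.DEAD)
        soc = accumulate_costs(trace, pset, "usual_care", "limited_societal")
        assert soc == pytest.approx(13 * pset.values.mortality_lost_earnings)

    def test_unknown_perspective_rejected(self, base_params):
        trace = self._locked_trace(HealthState.UNTREATED)
        with pytest.raises(ValueError, match="perspective"):
            accumulate_costs(
                trace, base_params.with_post_discharge(0.1), "start", "galactic"
            )


class TestMonotonicity:
    def test_qalys_increase_with_first_cycle_initiation(self, calibrated_params):
        def qalys(p1):
            pset = _with_transitions(calibrated_params, arm="start", p_init_first_cycle=p1)
            return accumulate_qalys(run_trace(pset, "start"), pset.values)

        values = [qalys(p) for p in (0.1, 0.3, 0.573, 0.8)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_qalys_decrease_with_mortality(self, calibrated_params):
        def qalys(pd):
            pset = _with_transitions(calibrated_params, arm="start", p_death_untreated=pd)
            return accumulate_qalys(run_trace(pset, "start"), pset.values)

        values = [qalys(p) for p in (0.0, 0.0041, 0.02, 0.1)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_12_month_qalys_bounded(self, calibrated_params):
        # entry is always untreated, so the ceiling is one untreated accrual
        # plus twelve sustained accruals
        for arm in ("start", "usual_care"):
            q = accumulate_qalys(run_trace(calibrated_params, arm), calibrated_params.values)
            assert 0.0 <= q <= 0.047 + 12 * 0.064
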