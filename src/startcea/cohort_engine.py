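"""Deterministic Markov cohort engine.

Moves a closed cohort through the four health states in monthly cycles and
accumulates quality-adjusted life-years and perspective-specific costs.

Transition structure (canonical order untreated, initiated, sustained, dead):

* untreated  -> initiated with the in-hospital rate in cycle 1 and the
  community (post-discharge) rate in cycles 2+; -> dead with the untreated
  mortality; residual mass stays untreated.
* initiated is transient (it represents the initiation month): mass moves to
  sustained with the continuation probability, to dead with the initiated
  mortality, and ALL remaining mass reverts to untreated.
* sustained persists with the retention probability, dies with the sustained
  mortality, and otherwise reverts to untreated.
* dead is absorbing.

Rewards (utilities and costs) accrue at every stage boundary including model
entry: a 12-cycle run accrues 13 monthly rewards, row 0 valuing the
hospital-admission month in the entry state and row t the state occupied at
the end of cycle t.  This stage-indexed accrual is the convention of
cycle-tree cohort software and is the only reward count consistent with the
published per-arm totals this model reproduces.  No half-cycle correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .param_model import (
    ARMS,
    CALIBRATE,
    HealthState,
    ParameterSet,
    StateValueParams,
)

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "ArmOutcome",
    "InfeasibleRowError",
    "build_matrix",
    "run_trace",
    "accumulate_qalys",
    "accumulate_costs",
    "run_arm",
]

N_STATES = 4
_ROW_TOL = 1e-12


class InfeasibleRowError(ValueError):
    """A row's specified exit probabilities sum beyond 1."""


@dataclass(frozen=True)
class TransitionMatrix:
    """A validated 4x4 row-stochastic matrix for one cycle."""

    probs: np.ndarray
    cycle: int

    def __post_init__(self):
        p = self.probs
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected 4x4 matrix, got {p.shape}")
        if (p < -_ROW_TOL).any() or (p > 1 + _ROW_TOL).any():
            raise InfeasibleRowError("matrix entries outside [0, 1]")
        rowsums = p.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=_ROW_TOL, rtol=0):
            raise InfeasibleRowError(f"rows do not sum to 1: {rowsums}")
        dead = p[HealthState.DEAD]
        if not (dead[HealthState.DEAD] == 1.0 and dead[:3].sum() == 0.0):
            raise InfeasibleRowError("dead state must be absorbing")


@dataclass
class CohortTrace:
    """Cycle-by-cycle state occupancy; row 0 is the initial distribution."""

    occupancy: np.ndarray  # (horizon+1, 4)

    def __post_init__(self):
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError("trace must be (horizon+1) x 4")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10, rtol=0):
            raise ValueError("trace rows must sum to 1")
        if (occ < -1e-12).any():
            raise ValueError("negative occupancy")
        dead = occ[:, HealthState.DEAD]
        if (np.diff(dead) < -1e-12).any():
            raise ValueError("dead fraction must be non-decreasing")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass
class ArmOutcome:
    """Accumulated totals and per-cycle ledgers for one arm."""

    arm: str
    perspective: str
    total_qalys: float
    total_cost: float
    qalys_per_cycle: np.ndarray
    cost_per_cycle: np.ndarray
    trace: CohortTrace


def _first_cycle_init(params: ParameterSet, arm: str) -> float:
    return params.transitions[arm].p_init_first_cycle


def _post_init(params: ParameterSet, arm: str) -> float:
    p = params.transitions[arm].p_init_post_discharge
    if p == CALIBRATE:
        raise ValueError(
            "p_init_post_discharge is uncalibrated; run the calibration first "
            "or supply a numeric value"
        )
    return float(p)


def build_matrix(params: ParameterSet, arm: str, cycle: int) -> TransitionMatrix:
    """Assemble the transition matrix for one arm and cycle (1-based)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    t = params.transitions[arm]
    p_init = _first_cycle_init(params, arm) if cycle == 1 else _post_init(params, arm)

    m = np.zeros((N_STATES, N_STATES))
    U, I, S, D = (
        HealthState.UNTREATED,
        HealthState.INITIATED,
        HealthState.SUSTAINED,
        HealthState.DEAD,
    )

    def residual(origin: str, *exits: float) -> float:
        total = sum(exits)
        if total > 1.0 + _ROW_TOL:
            raise InfeasibleRowError(
                f"{origin} row exit probabilities sum to {total:.6f} > 1 "
                f"(arm={arm}, cycle={cycle})"
            )
        return max(0.0, 1.0 - total)

    m[U, I] = p_init
    m[U, D] = t.p_death_untreated
    m[U, U] = residual("untreated", p_init, t.p_death_untreated)

    m[I, S] = t.p_initiated_to_sustained
    m[I, D] = t.p_death_initiated
    m[I, U] = residual("initiated", t.p_initiated_to_sustained, t.p_death_initiated)

    m[S, S] = t.p_sustained_stay
    m[S, D] = t.p_death_sustained
    m[S, U] = residual("sustained", t.p_sustained_stay, t.p_death_sustained)

    m[D, D] = 1.0
    return TransitionMatrix(probs=m, cycle=cycle)


def run_trace(params: ParameterSet, arm: str) -> CohortTrace:
    """Propagate the whole cohort from the untreated state through the horizon."""
    horizon = params.run.horizon_cycles
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, HealthState.UNTREATED] = 1.0
    for cycle in range(1, horizon + 1):
        m = build_matrix(params, arm, cycle)
        occ[cycle] = occ[cycle - 1] @ m.probs
    return CohortTrace(occupancy=occ)


def accumulate_qalys(trace: CohortTrace, values: StateValueParams) -> float:
    """Occupancy-weighted monthly utilities summed over all stage accruals.

    All ``horizon + 1`` trace rows accrue (entry state included), so a cohort
    locked in one living state for a 12-cycle run collects 13 monthly
    utility increments.  The dead state contributes zero.
    """
    u = np.asarray(values.utilities())
    return float((trace.occupancy @ u).sum())


def qalys_per_cycle(trace: CohortTrace, values: StateValueParams) -> np.ndarray:
    """Per-accrual QALY vector (length horizon + 1, index 0 = model entry)."""
    return trace.occupancy @ np.asarray(values.utilities())


def cost_per_cycle(
    trace: CohortTrace, params: ParameterSet, arm: str, perspective: str
) -> np.ndarray:
    """Per-accrual cost vector for one arm under the given perspective.

    Health sector: occupancy-weighted monthly state health care expenditures
    at every stage accrual (entry state included), plus the one-time
    implementation cost in the intervention arm's first cycle.  Limited
    societal adds treatment-visit costs (patient time and transportation)
    over both medication states, absenteeism by treatment status, and
    monthly lost earnings accruing to the dead fraction.
    """
    if perspective not in ("health_sector", "limited_societal"):
        raise ValueError(f"unknown perspective {perspective!r}")
    v = params.values
    occ = trace.occupancy

    per_cycle = occ @ np.asarray(v.healthcare_costs())
    if arm == "start":
        per_cycle = per_cycle.copy()
        per_cycle[1] += params.run.implementation_cost_per_patient

    if perspective == "limited_societal":
        societal = np.zeros(N_STATES)
        societal[HealthState.UNTREATED] = v.absenteeism_untreated
        moud = v.patient_time_cost + v.transportation_cost + v.absenteeism_treated
        societal[HealthState.INITIATED] = moud
        societal[HealthState.SUSTAINED] = moud
        societal[HealthState.DEAD] = v.mortality_lost_earnings
        per_cycle = per_cycle + occ @ societal
    return per_cycle


def accumulate_costs(
    trace: CohortTrace, params: ParameterSet, arm: str, perspective: str
) -> float:
    """Total per-person cost over the horizon under the given perspective."""
    return float(cost_per_cycle(trace, params, arm, perspective).sum())


def run_arm(params: ParameterSet, arm: str, perspective: str) -> ArmOutcome:
    """Trace one arm and accumulate its QALYs and costs."""
    trace = run_trace(params, arm)
    q = qalys_per_cycle(trace, params.values)
    c = cost_per_cycle(trace, params, arm, perspective)
    return ArmOutcome(
        arm=arm,
        perspective=perspective,
        total_qalys=float(q.sum()),
        total_cost=float(c.sum()),
        qalys_per_cycle=q,
        cost_per_cycle=c,
        trace=trace,
    )
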