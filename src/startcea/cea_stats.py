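"""Incremental cost-effectiveness statistics and model calibration.

The incremental cost-effectiveness ratio (ICER) is the cost difference
between the intervention and usual care divided by the QALY difference;
dominance short-circuits the ratio.  Net monetary benefit (NMB) at a
willingness-to-pay threshold lambda is ``lambda * dQALY - dCost``; for
positive QALY gains, NMB > 0 iff ICER < lambda.

The shared post-discharge initiation probability has no in-model source, so
it is pinned by one-parameter calibration: bisection on the usual-care arm's
total QALYs, which increase monotonically in the initiation probability.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .cohort_engine import run_arm, run_trace, accumulate_qalys
from .param_model import ParameterSet

__all__ = [
    "CEAResult",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "icer",
    "nmb",
    "calibrate_post_discharge_initiation",
    "calibrated",
    "run_cea",
    "InfeasibleTargetError",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

_QALY_TOL = 1e-8


class InfeasibleTargetError(ValueError):
    """Calibration target outside the attainable QALY range."""


@dataclass
class CEAResult:
    """Per-arm totals and incremental statistics for one perspective."""

    perspective: str
    cost_intervention: float
    cost_comparator: float
    qalys_intervention: float
    qalys_comparator: float
    wtp_threshold: float

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qalys(self) -> float:
        return self.qalys_intervention - self.qalys_comparator

    @property
    def icer(self) -> float | str:
        return icer(self.delta_cost, self.delta_qalys)

    @property
    def nmb(self) -> float:
        return nmb(self.delta_cost, self.delta_qalys, self.wtp_threshold)

    def as_dict(self) -> dict:
        return {
            "perspective": self.perspective,
            "cost_intervention": self.cost_intervention,
            "cost_comparator": self.cost_comparator,
            "qalys_intervention": self.qalys_intervention,
            "qalys_comparator": self.qalys_comparator,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "nmb": self.nmb,
            "wtp_threshold": self.wtp_threshold,
        }


def icer(delta_cost: float, delta_qalys: float) -> float | str:
    """Incremental cost per QALY gained, or a dominance flag.

    Returns ``"dominant"`` when the intervention is at least as cheap and
    more effective, ``"dominated"`` when it is at least as costly and less
    effective, and ``"undefined"`` when the QALY difference is zero.  In the
    remaining quadrant (cheaper and less effective) the signed ratio is
    returned and should be read against the comparator.
    """
    if delta_qalys == 0.0:
        return UNDEFINED
    if delta_qalys > 0 and delta_cost <= 0:
        return DOMINANT
    if delta_qalys < 0 and delta_cost >= 0:
        return DOMINATED
    return delta_cost / delta_qalys


def nmb(delta_cost: float, delta_qalys: float, wtp: float) -> float:
    """Incremental net monetary benefit at willingness-to-pay ``wtp``."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay threshold must be positive")
    return wtp * delta_qalys - delta_cost


def _usual_care_qalys_at(params: ParameterSet, p: float) -> float:
    pset = params.with_post_discharge(p)
    trace = run_trace(pset, "usual_care")
    return accumulate_qalys(trace, pset.values)


def calibrate_post_discharge_initiation(
    params: ParameterSet, target_usual_care_qalys: float
) -> float:
    """Solve for the shared post-discharge initiation probability.

    Finds ``p`` in [0, 1] such that the usual-care arm's total QALYs over the
    horizon equal the target within 1e-8, by root bracketing (the objective
    is monotone increasing in ``p``).  Raises
    :class:`InfeasibleTargetError` reporting the attainable range when the
    target lies outside it.
    """
    # the untreated row must keep room for its death probability
    p_max = 1.0 - max(
        params.transitions[a].p_death_untreated for a in params.transitions
    )
    lo = _usual_care_qalys_at(params, 0.0)
    hi = _usual_care_qalys_at(params, p_max)
    t = target_usual_care_qalys
    if not (lo - _QALY_TOL <= t <= hi + _QALY_TOL):
        raise InfeasibleTargetError(
            f"target QALYs {t} outside attainable range [{lo:.6f}, {hi:.6f}]"
        )
    if abs(t - lo) <= _QALY_TOL:
        return 0.0
    if abs(t - hi) <= _QALY_TOL:
        return p_max
    return float(
        brentq(lambda p: _usual_care_qalys_at(params, p) - t, 0.0, p_max, xtol=1e-12)
    )


def calibrated(params: ParameterSet) -> ParameterSet:
    """Return a ParameterSet with a numeric post-discharge probability.

    If calibration is requested, solves against ``calibration_target_qalys``;
    otherwise returns the set unchanged.
    """
    if not params.needs_calibration:
        return params
    if params.calibration_target_qalys is None:
        raise ValueError(
            "p_init_post_discharge is set to 'calibrate' but no "
            "calibration_target_qalys is configured"
        )
    p = calibrate_post_discharge_initiation(params, params.calibration_target_qalys)
    return params.with_post_discharge(p)


def run_cea(params: ParameterSet, perspective: str) -> CEAResult:
    """Run both arms through the cohort engine and assemble the comparison."""
    params = calibrated(params)
    intervention = run_arm(params, "start", perspective)
    comparator = run_arm(params, "usual_care", perspective)
    return CEAResult(
        perspective=perspective,
        cost_intervention=intervention.total_cost,
        cost_comparator=comparator.total_cost,
        qalys_intervention=intervention.total_qalys,
        qalys_comparator=comparator.total_qalys,
        wtp_threshold=params.run.wtp_threshold,
    )
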