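"""Synthetic two-arm trial generator and parameter re-estimation.

Generates individual-level records with the statistical structure the
cost-effectiveness model assumes: a fixed 164:161 randomization, Bernoulli
in-hospital medication initiation at arm-specific rates, Bernoulli 30-day
continuation among initiators, Bernoulli follow-up completion, and
right-skewed per-patient staff time (gamma) for the intervention arm.  The
trial-derived model inputs (first-cycle initiation, initiated-to-sustained
continuation) are then re-estimated from the records with Wilson intervals,
closing the loop from raw data to model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .microcosting import TimeLogTable

__all__ = [
    "PatientRecord",
    "TrialGenConfig",
    "generate_trial",
    "records_to_frame",
    "estimate_transition_inputs",
    "aggregate_time_logs",
]

TRIAL_ARMS = ("intervention", "usual_care")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic trial participant."""

    id: int
    arm: str
    initiated_in_hospital: bool
    continued_at_30d: bool | None  # defined only for initiators
    completed_followup: bool
    ams_hours: float
    cm_hours: float

    def __post_init__(self):
        if self.continued_at_30d and not self.initiated_in_hospital:
            raise ValueError("continuation implies in-hospital initiation")
        if self.ams_hours < 0 or self.cm_hours < 0:
            raise ValueError("staff hours must be nonnegative")
        if self.arm == "usual_care" and (self.ams_hours or self.cm_hours):
            raise ValueError("usual-care records carry no staff time")


@dataclass
class TrialGenConfig:
    """Generator settings; defaults are the trial's design and observed rates."""

    n_intervention: int = 164
    n_usual_care: int = 161
    p_initiate: dict = field(
        default_factory=lambda: {"intervention": 0.573, "usual_care": 0.267}
    )
    p_continue: dict = field(
        default_factory=lambda: {"intervention": 0.714, "usual_care": 0.708}
    )
    p_followup: dict = field(
        default_factory=lambda: {"intervention": 0.762, "usual_care": 0.646}
    )
    staff_hours_mean: dict = field(
        default_factory=lambda: {"AMS": 1.73, "CM": 3.64}
    )
    staff_hours_cv: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_intervention < 1 or self.n_usual_care < 1:
            raise ValueError("each arm needs at least one participant")
        for d in (self.p_initiate, self.p_continue, self.p_followup):
            for arm in TRIAL_ARMS:
                p = d[arm]
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability out of range for {arm}: {p}")
        if self.staff_hours_cv < 0:
            raise ValueError("staff-time coefficient of variation must be >= 0")


def _gamma_hours(mean: float, cv: float, size: int, rng: np.random.Generator):
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, scale=mean / shape, size=size)


def generate_trial(cfg: TrialGenConfig) -> list[PatientRecord]:
    """Draw a full synthetic trial; reproducible for a given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[PatientRecord] = []
    next_id = 0
    for arm, n in (("intervention", cfg.n_intervention), ("usual_care", cfg.n_usual_care)):
        init = rng.random(n) < cfg.p_initiate[arm]
        cont = rng.random(n) < cfg.p_continue[arm]
        fup = rng.random(n) < cfg.p_followup[arm]
        if arm == "intervention":
            ams = _gamma_hours(cfg.staff_hours_mean["AMS"], cfg.staff_hours_cv, n, rng)
            cm = _gamma_hours(cfg.staff_hours_mean["CM"], cfg.staff_hours_cv, n, rng)
        else:
            ams = cm = np.zeros(n)
        for i in range(n):
            records.append(
                PatientRecord(
                    id=next_id,
                    arm=arm,
                    initiated_in_hospital=bool(init[i]),
                    continued_at_30d=bool(cont[i]) if init[i] else None,
                    completed_followup=bool(fup[i]),
                    ams_hours=float(ams[i]),
                    cm_hours=float(cm[i]),
                )
            )
            next_id += 1
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "arm": r.arm,
                "initiated_in_hospital": r.initiated_in_hospital,
                "continued_at_30d": r.continued_at_30d,
                "completed_followup": r.completed_followup,
                "ams_hours": r.ams_hours,
                "cm_hours": r.cm_hours,
            }
            for r in records
        ]
    )


def _wilson(k: int, n: int) -> tuple[float, float, float]:
    """Proportion with a 95% Wilson score interval."""
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, float(lo), float(hi)


def estimate_transition_inputs(records: list[PatientRecord]) -> dict:
    """Re-estimate the trial-derived model inputs, per arm.

    Returns, for each arm, the observed in-hospital initiation proportion
    and the 30-day continuation proportion among initiators, each with a 95%
    Wilson interval.  With zero initiators the continuation estimate is
    flagged undefined rather than fabricated; a degenerate (all-success)
    proportion is flagged.
    """
    out: dict[str, dict] = {}
    frame = records_to_frame(records)
    for arm in TRIAL_ARMS:
        sub = frame[frame["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no records in arm {arm!r}")
        n = len(sub)
        k = int(sub["initiated_in_hospital"].sum())
        p, lo, hi = _wilson(k, n)
        arm_est = {
            "n": n,
            "p_init_first_cycle": {
                "estimate": p,
                "ci95": (lo, hi),
                "degenerate": k in (0, n),
            },
        }
        init = sub[sub["initiated_in_hospital"]]
        if len(init) == 0:
            arm_est["p_initiated_to_sustained"] = {
                "estimate": None,
                "ci95": None,
                "undefined": True,
            }
        else:
            kc = int(init["continued_at_30d"].sum())
            pc, lo_c, hi_c = _wilson(kc, len(init))
            arm_est["p_initiated_to_sustained"] = {
                "estimate": pc,
                "ci95": (lo_c, hi_c),
                "degenerate": kc in (0, len(init)),
            }
        out[arm] = arm_est
    return out


def aggregate_time_logs(
    records: list[PatientRecord], wages: TimeLogTable
) -> TimeLogTable:
    """Mean per-patient delivery hours by role, priced at the pooled wages.

    Produces a time-log table whose delivery rows carry the intervention
    arm's mean logged hours (feeding the micro-costing), with training rows
    passed through from ``wages`` unchanged.
    """
    frame = records_to_frame(records)
    iv = frame[frame["arm"] == "intervention"]
    if len(iv) == 0:
        raise ValueError("no intervention-arm records to aggregate")
    means = {"AMS": float(iv["ams_hours"].mean()), "CM": float(iv["cm_hours"].mean())}

    pooled_wage = {}
    for role in ("AMS", "CM"):
        row = wages.rows[
            (wages.rows["role"] == role)
            & (wages.rows["activity"] == "delivery")
            & (wages.rows["site"].astype(str) == "all")
        ]
        if len(row) == 0:
            raise ValueError(f"no pooled delivery wage for role {role}")
        pooled_wage[role] = float(row["hourly_wage"].iloc[0])

    rows = [r for _, r in wages.training.iterrows()]
    out = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=["role", "site", "activity", "hours", "hourly_wage"]
    )
    delivery = pd.DataFrame(
        [
            {"role": role, "site": "all", "activity": "delivery",
             "hours": means[role], "hourly_wage": pooled_wage[role]}
            for role in ("AMS", "CM")
        ]
    )
    return TimeLogTable(pd.concat([out, delivery], ignore_index=True))
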