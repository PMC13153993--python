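"""Micro-costing of the intervention from personnel time logs.

The intervention's implementation cost per patient is built bottom-up from
staff time-and-wage records: delivery time is logged per patient (so row
cost = hours x wage), while training/onboarding time is a one-time total
spread over every enrolled intervention patient (row cost = hours x wage /
n_enrolled).  Per-site delivery rows describe site-level means of the same
activity, so only the pooled all-site delivery rows enter the per-patient
personnel total; every training row is a distinct one-time cost and all of
them enter the training total.

Full precision is kept internally; rounding to cents happens only in the
display table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "TimeLogTable",
    "ImplementationCostBreakdown",
    "load_time_logs",
    "default_time_logs_path",
    "personnel_cost_per_patient",
    "training_cost_per_patient",
    "implementation_cost",
]

ROLES = ("trainer", "AMS", "CM")
ACTIVITIES = ("training", "delivery")


class TimeLogError(ValueError):
    """Raised on malformed time-log tables."""


@dataclass
class TimeLogTable:
    """Personnel time logs: one row per (role, site, activity).

    ``hours`` is per-patient for delivery rows and a one-time total for
    training rows; ``hourly_wage`` is USD/hour including fringe benefits.
    """

    rows: pd.DataFrame

    def __post_init__(self):
        required = {"role", "site", "activity", "hours", "hourly_wage"}
        missing = required - set(self.rows.columns)
        if missing:
            raise TimeLogError(f"time-log table missing columns: {sorted(missing)}")
        bad_role = set(self.rows["role"]) - set(ROLES)
        bad_act = set(self.rows["activity"]) - set(ACTIVITIES)
        if bad_role or bad_act:
            raise TimeLogError(
                f"unknown role(s) {sorted(bad_role)} or activity(ies) {sorted(bad_act)}"
            )
        if (self.rows["hours"] < 0).any():
            raise TimeLogError("hours must be nonnegative")
        if (self.rows["hourly_wage"] <= 0).any():
            raise TimeLogError("hourly wages must be positive")

    @property
    def training(self) -> pd.DataFrame:
        return self.rows[self.rows["activity"] == "training"]

    @property
    def delivery(self) -> pd.DataFrame:
        return self.rows[self.rows["activity"] == "delivery"]


@dataclass
class ImplementationCostBreakdown:
    """Per-row and total implementation costs per patient, USD 2023."""

    rows: pd.DataFrame  # role, site, activity, hours, hourly_wage, cost_per_patient
    personnel_total_per_patient: float
    training_total_per_patient: float

    @property
    def grand_total_per_patient(self) -> float:
        return self.personnel_total_per_patient + self.training_total_per_patient

    def display_table(self) -> pd.DataFrame:
        """Breakdown with costs rounded to cents, plus total rows."""
        out = self.rows.copy()
        out["cost_per_patient"] = out["cost_per_patient"].round(2)
        totals = pd.DataFrame(
            [
                {"role": "total", "site": "all", "activity": "training",
                 "cost_per_patient": round(self.training_total_per_patient, 2)},
                {"role": "total", "site": "all", "activity": "delivery",
                 "cost_per_patient": round(self.personnel_total_per_patient, 2)},
                {"role": "total", "site": "all", "activity": "all",
                 "cost_per_patient": round(self.grand_total_per_patient, 2)},
            ]
        )
        return pd.concat([out, totals], ignore_index=True)


def personnel_cost_per_patient(hours_per_patient: float, wage: float) -> float:
    """Delivery cost per patient: per-patient hours times the hourly wage."""
    if hours_per_patient < 0 or wage < 0:
        raise ValueError("hours and wage must be nonnegative")
    return hours_per_patient * wage


def training_cost_per_patient(total_hours: float, wage: float, n_enrolled: int) -> float:
    """One-time training cost amortized over all enrolled intervention patients."""
    if total_hours < 0 or wage < 0:
        raise ValueError("hours and wage must be nonnegative")
    if n_enrolled < 1:
        raise ZeroDivisionError("n_enrolled must be at least 1")
    return total_hours * wage / n_enrolled


def implementation_cost(
    logs: TimeLogTable, n_enrolled: int
) -> ImplementationCostBreakdown:
    """Cost every time-log row and total the per-patient implementation cost.

    The personnel (delivery) total uses only the pooled ``site == "all"``
    rows; per-site delivery rows are retained in the breakdown but are
    site-level views of the same time, not additional cost.
    """
    if len(logs.rows) == 0:
        raise TimeLogError("time-log table is empty")

    rows = logs.rows.copy()
    costs = []
    for _, r in rows.iterrows():
        if r["activity"] == "training":
            costs.append(training_cost_per_patient(r["hours"], r["hourly_wage"], n_enrolled))
        else:
            costs.append(personnel_cost_per_patient(r["hours"], r["hourly_wage"]))
    rows["cost_per_patient"] = costs

    training_total = rows.loc[rows["activity"] == "training", "cost_per_patient"].sum()
    delivery = rows["activity"] == "delivery"
    pooled = delivery & (rows["site"].astype(str) == "all")
    personnel_total = rows.loc[pooled, "cost_per_patient"].sum()
    if delivery.any() and not pooled.any():
        # no pooled rows: treat every delivery row as additive
        personnel_total = rows.loc[delivery, "cost_per_patient"].sum()

    return ImplementationCostBreakdown(
        rows=rows,
        personnel_total_per_patient=float(personnel_total),
        training_total_per_patient=float(training_total),
    )


def default_time_logs_path() -> Path:
    return Path(importlib.resources.files("startcea") / "data" / "time_logs.csv")


def load_time_logs(path: str | Path | None = None) -> TimeLogTable:
    """Read a time-log CSV (columns role, site, activity, hours, hourly_wage)."""
    return TimeLogTable(pd.read_csv(path or default_time_logs_path()))
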