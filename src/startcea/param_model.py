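"""Data model for the cost-effectiveness analysis.

Defines the four health states of the cohort model, the per-arm transition
probabilities, the state costs and utilities, the sensitivity-analysis
distribution specifications, and the run configuration, together with
loaders/writers for the tabular configuration files.

Probabilities in the parameter file are stored as printed in the source
tables — per-30-day percentages — and converted to [0, 1] probabilities on
load, so the file remains visually auditable against the published values.
"""

from __future__ import annotations

import copy
import enum
import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "HealthState",
    "Arm",
    "ArmTransitionParams",
    "StateValueParams",
    "DistributionSpec",
    "RunConfig",
    "ParameterSet",
    "ParameterValidationError",
    "CALIBRATE",
    "load_parameters",
    "save_parameters",
    "default_config_path",
    "monthly_utility_from_annual",
]

#: Sentinel accepted in place of a numeric post-discharge initiation
#: probability, meaning "solve for it against a QALY target".
CALIBRATE = "calibrate"

ARMS = ("start", "usual_care")

DIST_FAMILIES = ("pert", "uniform", "beta", "gamma")

#: Parameter-table rows that are probabilities stored as percentages.
_PCT_UNITS = ("pct_per_30d", "pct")


class ParameterValidationError(ValueError):
    """Raised when a parameter file or parameter set violates the schema.

    Carries the list of offending fields in ``fields``.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


class HealthState(enum.IntEnum):
    """The four mutually exclusive health states, in canonical order.

    The integer values fix the index used for every transition matrix and
    cohort trace.  ``DEAD`` is absorbing.
    """

    UNTREATED = 0
    INITIATED = 1
    SUSTAINED = 2
    DEAD = 3

    @property
    def absorbing(self) -> bool:
        return self is HealthState.DEAD


LIVING_STATES = (HealthState.UNTREATED, HealthState.INITIATED, HealthState.SUSTAINED)


def _check_prob(name: str, p: float, bad: list[str]) -> None:
    if not (0.0 <= p <= 1.0):
        bad.append(name)


@dataclass
class ArmTransitionParams:
    """Monthly (per-30-day) transition probabilities for one arm.

    ``p_init_first_cycle`` applies only while the cohort is hospitalized
    (cycle 1) and is arm-specific; ``p_init_post_discharge`` applies from
    cycle 2 onward and is shared across arms in the base case.
    """

    p_init_first_cycle: float
    p_init_post_discharge: float | str  # numeric, or the CALIBRATE token
    p_initiated_to_sustained: float
    p_sustained_stay: float
    p_death_untreated: float
    p_death_initiated: float
    p_death_sustained: float

    def validate(self) -> None:
        bad: list[str] = []
        for name in (
            "p_init_first_cycle",
            "p_initiated_to_sustained",
            "p_sustained_stay",
            "p_death_untreated",
            "p_death_initiated",
            "p_death_sustained",
        ):
            _check_prob(name, getattr(self, name), bad)
        post = self.p_init_post_discharge
        if post != CALIBRATE:
            _check_prob("p_init_post_discharge", float(post), bad)
        if bad:
            raise ParameterValidationError(
                f"transition probabilities outside [0, 1]: {bad}", bad
            )
        # per-origin-state exit mass must leave room for the residual
        post_p = 0.0 if post == CALIBRATE else float(post)
        exits = {
            "untreated(first cycle)": self.p_init_first_cycle + self.p_death_untreated,
            "untreated(post-discharge)": post_p + self.p_death_untreated,
            "initiated": self.p_initiated_to_sustained + self.p_death_initiated,
            "sustained": self.p_sustained_stay + self.p_death_sustained,
        }
        over = [k for k, v in exits.items() if v > 1.0 + 1e-12]
        if over:
            raise ParameterValidationError(
                f"exit probabilities exceed 1 for origin state(s): {over}", over
            )


@dataclass
class StateValueParams:
    """Monthly utilities and costs attached to each state.

    Utilities are QALYs per month (annual utility / 12), so they live in
    [0, 1/12].  All costs are 2023 USD per month.
    """

    utility_untreated: float
    utility_initiated: float
    utility_sustained: float
    cost_untreated: float
    cost_initiated: float
    cost_sustained: float
    patient_time_cost: float
    transportation_cost: float
    absenteeism_untreated: float
    absenteeism_treated: float
    mortality_lost_earnings: float

    def validate(self) -> None:
        bad: list[str] = []
        for name in ("utility_untreated", "utility_initiated", "utility_sustained"):
            u = getattr(self, name)
            if not (0.0 <= u <= 1.0 / 12.0 + 1e-12):
                bad.append(name)
        for name in (
            "cost_untreated",
            "cost_initiated",
            "cost_sustained",
            "patient_time_cost",
            "transportation_cost",
            "absenteeism_untreated",
            "absenteeism_treated",
            "mortality_lost_earnings",
        ):
            if getattr(self, name) < 0.0:
                bad.append(name)
        if bad:
            raise ParameterValidationError(
                f"state values out of range (utilities in [0, 1/12], costs >= 0): {bad}",
                bad,
            )

    def utilities(self) -> tuple[float, float, float, float]:
        """Per-state monthly utility vector in canonical state order."""
        return (
            self.utility_untreated,
            self.utility_initiated,
            self.utility_sustained,
            0.0,
        )

    def healthcare_costs(self) -> tuple[float, float, float, float]:
        """Per-state monthly health care expenditure vector."""
        return (self.cost_untreated, self.cost_initiated, self.cost_sustained, 0.0)


@dataclass(frozen=True)
class DistributionSpec:
    """A (family, base, low, high) uncertainty specification for one parameter."""

    family: str
    base: float
    low: float
    high: float
    kind: str = "cost"  # cost | probability | utility; drives tornado ranges

    def __post_init__(self):
        if self.family not in DIST_FAMILIES:
            raise ParameterValidationError(
                f"unknown distribution family {self.family!r}", ["family"]
            )
        if not (self.low <= self.base <= self.high):
            raise ParameterValidationError(
                f"distribution spec must satisfy low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})",
                ["base", "low", "high"],
            )


@dataclass
class RunConfig:
    """Horizon, threshold, perspective and reproducibility settings."""

    horizon_cycles: int = 12
    cycle_length_days: int = 30
    wtp_threshold: float = 150_000.0
    perspective: str = "health_sector"
    psa_draws: int = 5000
    rng_seed: int = 0
    implementation_cost_per_patient: float = 0.0
    n_enrolled_intervention: int = 164

    def validate(self) -> None:
        bad = []
        if self.horizon_cycles < 1:
            bad.append("horizon_cycles")
        if self.psa_draws < 1:
            bad.append("psa_draws")
        if self.wtp_threshold <= 0:
            bad.append("wtp_threshold")
        if self.perspective not in ("health_sector", "limited_societal"):
            bad.append("perspective")
        if bad:
            raise ParameterValidationError(f"invalid run configuration: {bad}", bad)


@dataclass
class ParameterSet:
    """Every input the model needs, for both arms."""

    transitions: dict[str, ArmTransitionParams]
    values: StateValueParams
    dists: dict[str, DistributionSpec] = field(default_factory=dict)
    run: RunConfig = field(default_factory=RunConfig)
    calibration_target_qalys: float | None = None
    scenario_uplift: float = 1.48
    allow_arm_specific_death: bool = False
    trial: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [a for a in ARMS if a not in self.transitions]
        if missing:
            raise ParameterValidationError(f"missing arm(s): {missing}", missing)
        for arm in ARMS:
            self.transitions[arm].validate()
        self.values.validate()
        self.run.validate()
        if not self.allow_arm_specific_death:
            s, u = self.transitions["start"], self.transitions["usual_care"]
            diff = [
                n
                for n in ("p_death_untreated", "p_death_initiated", "p_death_sustained")
                if getattr(s, n) != getattr(u, n)
            ]
            if diff:
                raise ParameterValidationError(
                    "death probabilities differ between arms without "
                    f"allow_arm_specific_death: {diff}",
                    diff,
                )

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    @property
    def needs_calibration(self) -> bool:
        return any(
            self.transitions[a].p_init_post_discharge == CALIBRATE for a in ARMS
        )

    def with_post_discharge(self, p: float) -> "ParameterSet":
        """Return a copy with the shared post-discharge initiation probability set."""
        out = self.copy()
        for arm in ARMS:
            out.transitions[arm] = replace(
                out.transitions[arm], p_init_post_discharge=float(p)
            )
        return out


def monthly_utility_from_annual(u_annual: float) -> float:
    """Convert an annual utility weight to a monthly QALY weight (divide by 12)."""
    if not (0.0 <= u_annual <= 1.0):
        raise ParameterValidationError(
            f"annual utility must lie in [0, 1], got {u_annual}", ["u_annual"]
        )
    return u_annual / 12.0


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def default_config_path() -> Path:
    """Path of the packaged default configuration (published base case)."""
    return Path(importlib.resources.files("startcea") / "data" / "config.yaml")


def _dist_key(name: str, arm: str) -> str:
    return name if arm == "shared" else f"{name}.{arm}"


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a full :class:`ParameterSet` from a YAML config.

    The config references a parameter table (columns ``name, arm, base, low,
    high, family, units, kind``) and a personnel time-log table; relative
    paths resolve against the config file's directory.  Percent-valued rows
    are divided by 100.  Raises :class:`ParameterValidationError` naming the
    offending fields on any schema or range violation.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    ptable = pd.read_csv(path.parent / cfg["parameters_file"])
    required = {"name", "arm", "base", "low", "high", "family", "units", "kind"}
    if not required.issubset(ptable.columns):
        raise ParameterValidationError(
            f"parameter table missing columns: {sorted(required - set(ptable.columns))}",
            sorted(required - set(ptable.columns)),
        )

    by_arm: dict[str, dict[str, float]] = {a: {} for a in ARMS}
    shared: dict[str, float] = {}
    dists: dict[str, DistributionSpec] = {}
    for _, row in ptable.iterrows():
        name, arm = str(row["name"]), str(row["arm"])
        scale = 100.0 if row["units"] in _PCT_UNITS else 1.0
        value = float(row["base"]) / scale
        if arm == "shared":
            shared[name] = value
        elif arm in ARMS:
            by_arm[arm][name] = value
        else:
            raise ParameterValidationError(
                f"unknown arm {arm!r} for parameter {name!r}", [name]
            )
        dists[_dist_key(name, arm)] = DistributionSpec(
            family=str(row["family"]).lower(),
            base=value,
            low=float(row["low"]) / scale,
            high=float(row["high"]) / scale,
            kind=str(row["kind"]),
        )

    post = cfg.get("p_init_post_discharge", CALIBRATE)
    if post != CALIBRATE:
        post = float(post)

    transitions = {}
    for arm in ARMS:
        src = {**shared, **by_arm[arm]}
        try:
            transitions[arm] = ArmTransitionParams(
                p_init_first_cycle=src["p_init_first_cycle"],
                p_init_post_discharge=post,
                p_initiated_to_sustained=src["p_initiated_to_sustained"],
                p_sustained_stay=src["p_sustained_stay"],
                p_death_untreated=src["p_death_untreated"],
                p_death_initiated=src["p_death_initiated"],
                p_death_sustained=src["p_death_sustained"],
            )
        except KeyError as exc:
            raise ParameterValidationError(
                f"parameter table missing {exc} for arm {arm!r}", [str(exc)]
            ) from exc

    value_names = (
        "utility_untreated",
        "utility_initiated",
        "utility_sustained",
        "cost_untreated",
        "cost_initiated",
        "cost_sustained",
        "patient_time_cost",
        "transportation_cost",
        "absenteeism_untreated",
        "absenteeism_treated",
        "mortality_lost_earnings",
    )
    missing = [n for n in value_names if n not in shared]
    if missing:
        raise ParameterValidationError(
            f"parameter table missing state-value rows: {missing}", missing
        )
    values = StateValueParams(**{n: shared[n] for n in value_names})

    run_cfg = dict(cfg.get("run", {}))
    impl = run_cfg.pop("implementation_cost_per_patient", "from_time_logs")
    run = RunConfig(**run_cfg)
    if impl == "from_time_logs":
        from .microcosting import implementation_cost, load_time_logs

        logs = load_time_logs(path.parent / cfg["time_logs_file"])
        run.implementation_cost_per_patient = implementation_cost(
            logs, run.n_enrolled_intervention
        ).grand_total_per_patient
    else:
        run.implementation_cost_per_patient = float(impl)

    pset = ParameterSet(
        transitions=transitions,
        values=values,
        dists=dists,
        run=run,
        calibration_target_qalys=cfg.get("calibration_target_qalys"),
        scenario_uplift=float(cfg.get("scenario_uplift", 1.48)),
        allow_arm_specific_death=bool(cfg.get("allow_arm_specific_death", False)),
        trial=dict(cfg.get("trial", {})),
    )
    pset.validate()
    return pset


def save_parameters(pset: ParameterSet, directory: str | Path) -> Path:
    """Write a ParameterSet back out as config.yaml + parameters.csv.

    The written files round-trip through :func:`load_parameters` losslessly
    (numeric values are stored at full precision).  Returns the config path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for key, spec in pset.dists.items():
        name, _, arm = key.partition(".")
        arm = arm or "shared"
        scale = 100.0 if spec.kind == "probability" else 1.0
        rows.append(
            {
                "name": name,
                "arm": arm,
                "base": repr(spec.base * scale),
                "low": repr(spec.low * scale),
                "high": repr(spec.high * scale),
                "family": spec.family,
                "units": "pct_per_30d" if scale == 100.0 else "usd_or_qaly",
                "kind": spec.kind,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "parameters.csv", index=False)

    post = pset.transitions["start"].p_init_post_discharge
    cfg = {
        "parameters_file": "parameters.csv",
        "time_logs_file": "time_logs.csv",
        "run": {
            "horizon_cycles": pset.run.horizon_cycles,
            "cycle_length_days": pset.run.cycle_length_days,
            "wtp_threshold": pset.run.wtp_threshold,
            "perspective": pset.run.perspective,
            "psa_draws": pset.run.psa_draws,
            "rng_seed": pset.run.rng_seed,
            "implementation_cost_per_patient": pset.run.implementation_cost_per_patient,
            "n_enrolled_intervention": pset.run.n_enrolled_intervention,
        },
        "p_init_post_discharge": post,
        "calibration_target_qalys": pset.calibration_target_qalys,
        "scenario_uplift": pset.scenario_uplift,
        "trial": pset.trial,
    }
    cfg_path = directory / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)

    # a time-log file must exist next to the config for reloading
    from .microcosting import default_time_logs_path

    target = directory / "time_logs.csv"
    if not target.exists():
        target.write_text(Path(default_time_logs_path()).read_text())
    return cfg_path


def load_default_parameters() -> ParameterSet:
    """Convenience loader for the packaged base-case configuration."""
    return load_parameters(default_config_path())
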