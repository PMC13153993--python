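"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) analysis varies each parameter between low and high bounds
derived from its class — costs +/-50%, transition probabilities +/-15%,
utilities +/-30% — holding everything else at base, and ranks parameters by
the resulting ICER swing.

The probabilistic analysis jointly samples every uncertain parameter from
its assigned family (beta-PERT, uniform, beta, gamma) and propagates each
draw through both arms.  Shared parameters (mortality, utilities, state
costs) receive one draw per iteration applied to both arms; trial-derived
arm-specific parameters are sampled independently per arm.  Parameterization:

* PERT: beta-PERT on [low, high] with mode = base and shape lambda = 4;
* uniform on [low, high];
* beta: method of moments on [0, 1] with mean = base, sd = (high - low)/3.92
  (range read as a central 95% interval);
* gamma: method of moments with mean = base, sd = (high - low)/3.92.

All draws are clipped to [low, high]; a degenerate spec (low == high)
returns the base deterministically.  Each draw uses an independent
substream derived from (seed, draw index), so draw i is invariant to the
total draw count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cea_stats import CEAResult, calibrated, nmb, run_cea
from .cohort_engine import run_arm
from .param_model import ARMS, DistributionSpec, ParameterSet

__all__ = [
    "TornadoEntry",
    "PSAResultSet",
    "dsa_range",
    "run_dsa",
    "sample_parameter",
    "run_psa",
    "ceac",
    "apply_initiation_uplift",
    "IMPLEMENTATION_COST_PARAM",
]

logger = logging.getLogger(__name__)

#: Pseudo-parameter name for the micro-costed implementation cost, included
#: in the one-way sweep as a cost (+/-50%).
IMPLEMENTATION_COST_PARAM = "implementation_cost"

_DSA_FRACTIONS = {"cost": 0.50, "probability": 0.15, "utility": 0.30}


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    error: str | None = None

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def dsa_range(base: float, kind: str) -> tuple[float, float]:
    """Low/high bounds for a one-way sweep: base*(1 -/+ f) by parameter class.

    f is 0.50 for costs, 0.15 for transition probabilities, 0.30 for
    utilities; probabilities are clipped to [0, 1] and monthly utilities to
    [0, 1/12].
    """
    if kind not in _DSA_FRACTIONS:
        raise ValueError(f"unknown parameter kind {kind!r}")
    if base < 0:
        raise ValueError("base must be nonnegative")
    f = _DSA_FRACTIONS[kind]
    lo, hi = base * (1 - f), base * (1 + f)
    if kind == "probability":
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    elif kind == "utility":
        lo, hi = max(lo, 0.0), min(hi, 1.0 / 12.0)
    return lo, hi


def _set_parameter(params: ParameterSet, key: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one named parameter replaced.

    ``key`` is a dists-map key: a bare name for shared parameters or
    ``name.arm`` for arm-specific ones; ``implementation_cost`` targets the
    run configuration.
    """
    out = params.copy()
    _set_inplace(out, key, value)
    return out


def _set_inplace(params: ParameterSet, key: str, value: float) -> None:
    if key == IMPLEMENTATION_COST_PARAM:
        params.run.implementation_cost_per_patient = value
        return
    name, _, arm = key.partition(".")
    if hasattr(params.values, name):
        setattr(params.values, name, value)
        return
    for a in [arm] if arm else list(ARMS):
        if not hasattr(params.transitions[a], name):
            raise KeyError(f"unknown parameter {key!r}")
        params.transitions[a] = replace(params.transitions[a], **{name: value})


def _icer_value(result: CEAResult) -> float:
    """Numeric ICER for tornado spreads (signed ratio; nan when dQ = 0)."""
    if result.delta_qalys == 0.0:
        return float("nan")
    return result.delta_cost / result.delta_qalys


def run_dsa(params: ParameterSet, perspective: str) -> list[TornadoEntry]:
    """One-way sweep over every distributed parameter plus implementation cost.

    Each parameter is set to its low then high bound (others at base), the
    CEA re-run, and entries returned sorted by descending ICER spread.
    Per-parameter failures are recorded on the entry instead of aborting the
    sweep.
    """
    params = calibrated(params)
    sweep: list[tuple[str, float, float]] = []
    for key, spec in params.dists.items():
        lo, hi = dsa_range(spec.base, spec.kind)
        sweep.append((key, lo, hi))
    impl = params.run.implementation_cost_per_patient
    lo, hi = dsa_range(impl, "cost")
    sweep.append((IMPLEMENTATION_COST_PARAM, lo, hi))

    entries = []
    for key, lo, hi in sweep:
        icers = []
        err = None
        for bound in (lo, hi):
            try:
                icers.append(_icer_value(run_cea(_set_parameter(params, key, bound), perspective)))
            except Exception as exc:  # record, keep sweeping
                logger.warning("one-way sweep failed for %s=%s: %s", key, bound, exc)
                icers.append(float("nan"))
                err = str(exc)
        entries.append(TornadoEntry(key, lo, hi, icers[0], icers[1], error=err))
    entries.sort(key=lambda e: (-(e.spread if np.isfinite(e.spread) else -np.inf)))
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "spread": e.spread,
                "error": e.error or "",
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a distribution spec (clipped to [low, high])."""
    if spec.low == spec.high:
        return spec.base
    lo, hi, m = spec.low, spec.high, spec.base
    if spec.family == "pert":
        lam = 4.0
        span = hi - lo
        alpha = 1.0 + lam * (m - lo) / span
        beta = 1.0 + lam * (hi - m) / span
        x = lo + span * rng.beta(alpha, beta)
    elif spec.family == "uniform":
        x = rng.uniform(lo, hi)
    elif spec.family == "beta":
        sd = (hi - lo) / 3.92
        v = sd * sd
        if v >= m * (1 - m) or m <= 0 or m >= 1:
            x = m  # moments infeasible on [0,1]; degenerate at the mean
        else:
            nu = m * (1 - m) / v - 1.0
            x = rng.beta(m * nu, (1 - m) * nu)
    elif spec.family == "gamma":
        sd = (hi - lo) / 3.92
        if m <= 0:
            x = m
        else:
            shape = (m / sd) ** 2
            x = rng.gamma(shape, scale=sd * sd / m)
    else:  # pragma: no cover - family validated upstream
        raise ValueError(f"unknown family {spec.family!r}")
    return float(np.clip(x, lo, hi))


@dataclass
class PSAResultSet:
    """Per-draw outcomes and summaries of a probabilistic analysis."""

    perspective: str
    wtp_threshold: float
    seed: int
    draws: pd.DataFrame = field(repr=False)  # one row per draw
    sampled: pd.DataFrame = field(repr=False)  # sampled parameter values

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.draws["cost_start"] - self.draws["cost_usual_care"]).to_numpy()

    @property
    def delta_qalys(self) -> np.ndarray:
        return (self.draws["qalys_start"] - self.draws["qalys_usual_care"]).to_numpy()

    @property
    def fraction_optimal(self) -> float:
        """Fraction of draws where the intervention has the higher NMB."""
        return float(self.draws["start_optimal"].mean())

    def summary(self) -> dict:
        dc, dq = self.delta_cost, self.delta_qalys
        lo_c, hi_c = np.percentile(dc, [2.5, 97.5])
        lo_q, hi_q = np.percentile(dq, [2.5, 97.5])
        return {
            "perspective": self.perspective,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "wtp_threshold": self.wtp_threshold,
            "fraction_optimal": self.fraction_optimal,
            "mean_delta_cost": float(dc.mean()),
            "mean_delta_qalys": float(dq.mean()),
            "delta_cost_ui95": [float(lo_c), float(hi_c)],
            "delta_qalys_ui95": [float(lo_q), float(hi_q)],
        }


def _draw_parameter_set(
    params: ParameterSet, rng: np.random.Generator
) -> tuple[ParameterSet, dict[str, float]]:
    sampled = {}
    drawn = params.copy()
    for key in sorted(params.dists):
        value = sample_parameter(params.dists[key], rng)
        sampled[key] = value
        _set_inplace(drawn, key, value)
    return drawn, sampled


def run_psa(
    params: ParameterSet,
    perspective: str,
    draws: int | None = None,
    seed: int | None = None,
) -> PSAResultSet:
    """Monte-Carlo propagation of parameter uncertainty through both arms.

    Per draw: every distributed parameter is sampled (shared parameters once,
    arm-specific parameters per arm), both arms are run, and the strategy
    with the higher net monetary benefit at the configured willingness-to-pay
    is flagged optimal.  The post-discharge initiation probability is held at
    its (calibrated) base value — it carries no distribution.  Fully
    reproducible for a given seed; draw i does not depend on the draw count.
    """
    params = calibrated(params)
    n = params.run.psa_draws if draws is None else int(draws)
    if n < 1:
        raise ValueError("draws must be >= 1")
    master = params.run.rng_seed if seed is None else int(seed)
    wtp = params.run.wtp_threshold

    records = []
    sampled_rows = []
    for i in range(n):
        rng = np.random.default_rng([master, i])
        for attempt in range(3):  # bounded resampling on numerical failure
            try:
                drawn, sampled = _draw_parameter_set(params, rng)
                drawn.validate()
                arm_out = {
                    arm: run_arm(drawn, arm, perspective) for arm in ARMS
                }
                break
            except Exception as exc:
                logger.warning("PSA draw %d attempt %d failed: %s", i, attempt, exc)
                if attempt == 2:
                    raise
        dc = arm_out["start"].total_cost - arm_out["usual_care"].total_cost
        dq = arm_out["start"].total_qalys - arm_out["usual_care"].total_qalys
        records.append(
            {
                "draw": i,
                "cost_start": arm_out["start"].total_cost,
                "qalys_start": arm_out["start"].total_qalys,
                "cost_usual_care": arm_out["usual_care"].total_cost,
                "qalys_usual_care": arm_out["usual_care"].total_qalys,
                "start_optimal": nmb(dc, dq, wtp) >= 0,
            }
        )
        sampled_rows.append({"draw": i, **sampled})

    return PSAResultSet(
        perspective=perspective,
        wtp_threshold=wtp,
        seed=master,
        draws=pd.DataFrame.from_records(records).set_index("draw"),
        sampled=pd.DataFrame.from_records(sampled_rows).set_index("draw"),
    )


def ceac(psa: PSAResultSet, wtp_grid: list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    For each threshold, the fraction of draws in which the intervention's
    net monetary benefit is at least the comparator's.
    """
    if psa.n_draws == 0:
        raise ValueError("empty PSA result")
    if len(wtp_grid) == 0:
        raise ValueError("empty willingness-to-pay grid")
    dc, dq = psa.delta_cost, psa.delta_qalys
    rows = [
        {"wtp": float(w), "fraction_optimal": float((w * dq - dc >= 0).mean())}
        for w in wtp_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario analysis
# ---------------------------------------------------------------------------

def apply_initiation_uplift(params: ParameterSet, factor: float) -> ParameterSet:
    """Scale the intervention arm's post-discharge initiation rate.

    Returns a copy in which the intervention arm's community (cycles 2+)
    initiation probability is ``min(1, factor * base)``; the comparator arm
    is unchanged.  Clipping is logged.
    """
    if factor < 0:
        raise ValueError("uplift factor must be nonnegative")
    params = calibrated(params)
    out = params.copy()
    base = float(out.transitions["start"].p_init_post_discharge)
    raised = factor * base
    if raised > 1.0:
        logger.warning("uplifted initiation probability %.4f clipped to 1", raised)
        raised = 1.0
    out.transitions["start"] = replace(
        out.transitions["start"], p_init_post_discharge=raised
    )
    return out
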