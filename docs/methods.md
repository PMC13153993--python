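# Methods

## Model structure

Four mutually exclusive health states in fixed order — untreated OUD,
MOUD-initiated, MOUD-sustained, dead — with a 1-month (30-day) cycle and a
12-cycle horizon. The cohort enters untreated. Death is absorbing. No
discounting is applied at this horizon.

Per-cycle transition matrices are assembled from per-30-day probabilities:

* **untreated row** — to initiated with the arm-specific in-hospital rate in
  cycle 1 and the shared community rate in cycles 2+; to dead with the
  untreated mortality; residual stays untreated.
* **initiated row** — initiated is the transient initiation month: to
  sustained with the arm's 30-day continuation probability, to dead with the
  initiated mortality, all remaining mass reverts to untreated. The
  alternatives (a self-loop on initiated; community initiation routed
  directly to sustained) were examined and rejected: the transient-revert
  routing is the only one whose incremental-cost-per-incremental-QALY slope
  matches the analysis this model re-implements.
* **sustained row** — persists with the monthly retention probability, dies
  with the sustained mortality, residual reverts to untreated.

Rows are validated to sum to one within 1e-12; a row whose specified exit
probabilities exceed one raises an error naming the row rather than being
renormalized.

## Reward accrual

Utilities and costs accrue at **every stage boundary including model
entry**: a 12-cycle run accrues 13 monthly rewards, row 0 valuing the
admission month in the untreated state. This is the convention of
stage-indexed cohort software (a cycle tree terminated after stage 12
accrues stages 0..12) and is the only reward count under which the per-arm
cost and QALY levels this package reproduces are jointly attainable:
back-solving the published per-arm totals for occupancy person-months gives
negative occupancy with 12 accruals and plausible months with 13. No
half-cycle correction is applied on top of this. A cohort locked in the
untreated state therefore accrues 13 × 0.047 = 0.611 QALYs and
13 × $4,184 = $54,392 over the horizon.

The implementation cost enters once, in the intervention arm's first cycle.
Societal costs map to states as: absenteeism-when-untreated to untreated
occupancy; patient time, transportation, and absenteeism-in-treatment to
both medication states; monthly lost earnings to the dead fraction in every
cycle from death onward. The ongoing (per-month) mortality-cost convention
was cross-checked by the same occupancy back-solve: a one-time-at-death
convention is inconsistent with the published societal totals.

## Parameters

All inputs live in a single parameter table (name, arm, base, low, high,
family, units, kind) mirroring the source's layout — probabilities are
stored as printed percentages and divided by 100 on load — plus a YAML run
block (horizon 12 cycles, WTP $150,000/QALY, 5000 PSA draws, seed). Death
probabilities are stored shared across arms; arm-specific overrides require
an explicit flag so the base-case contract cannot be broken silently.

The **community (post-discharge) initiation probability** has no printed
base value; the loader accepts either a number or the token `calibrate`.
Calibration solves, by root bracketing on [0, 1 − p_death_untreated], for
the value making the usual-care arm's total QALYs equal the configured
target (0.636), to 1e-8. The objective is monotone increasing, so the root
is unique; the calibrated value is 0.1252/month.

**Micro-costing**: delivery rows cost hours × wage per patient; training
rows cost hours × wage / 164 (total intervention enrollment — the only
divisor reproducing every published training cell, including site-specific
ones). The personnel per-patient total sums only the pooled all-site
delivery rows; per-site delivery rows are site-level views of the same
time, not additive. Full precision is kept internally; cents rounding is
display-only.

## Sensitivity analyses

**One-way (tornado)**: every distributed parameter plus the implementation
cost is set to base×(1∓f) with f = 0.50 (costs), 0.15 (transition
probabilities), 0.30 (utilities), clipped to the parameter's domain; the
ICER is recomputed with all else at base; entries are ranked by |ICER(high)
− ICER(low)|. Per-parameter failures are recorded on the entry without
aborting the sweep.

**Probabilistic**: each draw samples every distributed parameter
independently — shared parameters once per draw (applied to both arms),
trial-derived arm-specific parameters independently per arm — then runs
both arms and flags the strategy with the higher NMB at the threshold.
Parameterizations, chosen as the common health-economics conventions and
fixed before any comparison:

* beta-PERT(min=low, mode=base, max=high) with shape λ=4;
* uniform(low, high);
* beta and gamma by method of moments with mean=base and
  sd=(high−low)/3.92 (the printed range read as a central 95% interval);
* all draws clipped to [low, high]; degenerate specs return base.

Randomness uses one master seed with per-draw substreams
(`default_rng([seed, draw])`), so draw *i* is invariant to the draw count
and the whole pipeline is bitwise reproducible under a fixed seed. The
post-discharge probability and (by default) the implementation cost carry
no distribution and stay at base in the PSA; the implementation cost *is*
varied in the tornado (as a cost, ±50%).

**Scenario**: the intervention arm's community initiation probability is
multiplied by 1.48 (cycles 2+ only, clipped to 1, clipping logged),
reflecting higher re-initiation among people with prior medication
exposure; the comparator is unchanged.

## Synthetic trial generator

Emulates the randomized trial the model's first-cycle inputs come from: a
fixed 164:161 allocation; Bernoulli in-hospital initiation (0.573 / 0.267);
Bernoulli 30-day continuation among initiators (0.714 / 0.708); Bernoulli
follow-up completion (0.762 / 0.646, generated for realism of the
missing-data structure but not used to re-weight estimates — observed
proportions are used downstream, as in the source analysis); per-patient
staff hours for the intervention arm from gamma distributions with means
1.73 h (specialist) and 3.64 h (care manager). The gamma coefficient of
variation defaults to 0.5 — time-on-task data are nonnegative and
right-skewed, and only the mean propagates into costing — and is
configurable. Re-estimation returns observed proportions with 95% Wilson
intervals; continuation with zero initiators is flagged undefined, never
fabricated.

What the generator does *not* emulate: site-level clustering, covariates,
informative missingness, or any clinical endpoint beyond the four booleans
and the time logs. Tests that pass on synthetic data therefore demonstrate
correctness of the estimation-to-model plumbing, not robustness to the
messiness of real trial data.

## Problem sizes and numerics

The deterministic base case (including calibration, ~40 model evaluations)
runs in well under a second; the 5000-draw PSA in a few seconds on one
core. Parameter-recovery tests use 1e5 synthetic patients per arm; sampler
mean checks use 1e5 draws. Trace conservation is enforced at 1e-10, matrix
row sums at 1e-12, calibration at 1e-8 on the QALY scale. Beta
method-of-moments specs whose variance is infeasible on [0, 1] degenerate
to the mean rather than erroring; gamma draws are clipped to the printed
range, which shifts the realized mean of wide cost parameters by under 2%.

## Known limitations

* The published per-arm totals imply a mean sustained-state sojourn of
  roughly 3.5 months per entrant, which the printed 54.3–54.9% per-30-day
  retention cannot produce (it gives ≈2.2). With the calibration and
  conventions above, this package's base case yields ΔE = 0.00931 QALYs,
  ΔC = $201 (health sector), ICER ≈ $21.6k/QALY — the same decision from
  both perspectives as the published analysis, and matching its societal
  ICER and scenario magnitudes, but not its health-sector increments
  exactly. The unprinted supplementary model details (community initiation
  source value, exact cascade structure) are the likely cause; no unprinted
  parameter was tuned to force agreement.
* Two strategies only; no comparator frontier, no EVPI, no correlation
  structure among PSA parameters, no crime or broader societal costs, no
  discounting machinery.
* Figures are not rendered; every analysis emits the underlying CSV instead.
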