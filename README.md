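# startcea

A cost-effectiveness model of a hospital **addiction consultation service
(ACS)** for opioid use disorder (OUD), comparing an inpatient
consultation-and-linkage team (the START model: an addiction medicine
specialist plus a care manager) against usual care. It is written for health
economists and implementation researchers who want a tested, scriptable
version of this class of analysis: a Markov cohort model with micro-costed
implementation costs, two costing perspectives, deterministic and
probabilistic sensitivity analyses, and a synthetic trial generator so every
stage runs without any external data.

## The model

A closed cohort of hospitalized adults with untreated OUD moves monthly
among four states over a 12-month horizon:

```
untreated OUD  ->  MOUD-initiated  ->  MOUD-sustained
      ^________________|__________________|
                      (death absorbs from every living state)
```

* **Cycle 1** (the hospitalization month) uses the trial's arm-specific
  in-hospital medication-initiation probabilities (57.3% ACS vs 26.7% usual
  care per 30 d); cycles 2–12 use a shared community initiation probability.
* **MOUD-initiated** is the transient initiation month: mass continues to
  *sustained* with the 30-day continuation probability (71.4% / 70.8%), dies,
  or reverts to untreated. *Sustained* persists at 54.9% / 54.3% per month.
* Each state carries a monthly utility weight (annual utility / 12) and
  monthly costs. Rewards accrue at all 13 stage boundaries of a 12-cycle
  run (the entry state is valued), with no discounting.

Outcomes per arm are total QALYs `E = Σ_t occ_t · u` and total costs
`C = Σ_t occ_t · c (+ implementation cost, intervention arm, cycle 1)`; the
comparison reports ΔC, ΔE, the **ICER** = ΔC/ΔE, and **net monetary
benefit** NMB(λ) = λ·ΔE − ΔC at λ = $150,000/QALY. The *health-sector*
perspective counts implementation and health care expenditures; the
*limited-societal* perspective adds patient time, transportation,
absenteeism, and lost earnings accruing monthly to the deceased fraction.

The implementation cost is micro-costed from personnel time logs
(hours × wage; one-time training costs amortized over the 164 enrolled
intervention patients), reproducing the published $601.86 personnel +
$38.24 training = **$640 per patient**.

The shared community initiation probability has no in-model source, so it
is **calibrated** by bisection so that the usual-care arm's 12-month QALYs
equal the published 0.636.

## Worked example

```python
import startcea as sc

params = sc.calibrated(sc.load_default_parameters())   # calibrates p_post
print(params.transitions["start"].p_init_post_discharge)  # 0.1252

cea = sc.run_cea(params, "health_sector")
print(round(cea.delta_cost, 2), round(cea.delta_qalys, 5))  # 201.4 0.00931
print(round(cea.icer))                                      # 21632
print(round(cea.nmb))                                       # 1195

scen = sc.run_cea(sc.apply_initiation_uplift(params, 1.48), "health_sector")
print(round(scen.delta_cost, 2), scen.icer)   # -302.3 dominant
```

Calibration pins the community initiation probability at 0.1252/month. The
consultation service then gains 0.00931 QALYs per person at an extra $201
per patient (ICER ≈ $21.6k/QALY — far below the $150k/QALY threshold, net
monetary benefit ≈ $1,195). If post-discharge initiation among intervention
patients is 48% higher than usual care (the prior-exposure scenario), the
service becomes cost-saving ("dominant": cheaper *and* more effective).

The command-line pipeline writes all tables (base case, trace ledgers,
tornado, PSA draws/scatter/CEAC, scenario) plus a run manifest:

```bash
startcea run --out results/ --seed 20230
startcea psa --draws 5000 --perspective health_sector --out results/
startcea synth --seed 7 --out results/
```

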