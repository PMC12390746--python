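# immunohta

Early health-technology assessment of predictive biomarkers for
immunotherapy response in advanced non-small-cell lung cancer (NSCLC).

Immune checkpoint inhibitors help only a minority of advanced NSCLC
patients yet dominate treatment costs. A test that predicts who will
respond could either *de-escalate* (withhold immunotherapy from predicted
nonresponders in the PD-L1 <1% and 1–49% strata) or *escalate* (add
chemotherapy for predicted nonresponders in the PD-L1 ≥50% stratum). This
package quantifies what such a test would be worth before it exists — for
test developers and HTA analysts deciding where a biomarker is best
positioned.

## Model

For each PD-L1 stratum a decision tree routes a cohort by test result
(sensitivity Se applies among responders, specificity Sp among
nonresponders; *response* = progression-free survival at 12 months) into
(regimen, responder) cells, which then run through a monthly-cycle Markov
model over 5 years: response on treatment → progression → death, with
nonresponders either dying or progressing within the first year (split by
the arm's 12-month PFS/OS gap) and every state exposed to background
mortality. Responder progression is an exponential extrapolation of the
arm's PFS curve, `S(t) = e^{−λt}`. QALYs discount at 1.5%/year, costs at
4.0%/year, and strategies compare by the incremental cost-effectiveness
ratio

ICER = ΔCost / ΔQALY

against a €80,000/QALY threshold, read quadrant-wise: € per QALY gained
(must be below) or € saved per QALY lost (must be above). Response rates
link arms through a nested-responder assumption, e.g.
`P(respond to chemo | respond to immunochemo) = r_mono/r_combo`, and the
≥50% stratum's immunochemotherapy rate derives from the PFS hazard ratio
1.81 by risk scaling, `1 − (1 − 0.375)/1.81 = 65.5%`.

Because the published supplementary input tables are not deposited, the
`synthetic` module generates seeded, internally consistent parameter sets
from documented plausible ranges (see `docs/methods.md`); they reproduce
the qualitative economics, not the published absolute magnitudes.

## Worked example

Generate a synthetic configuration for the PD-L1 <1% stratum and sweep
the test-accuracy scenarios:

```sh
immunohta synth --group LT1 --seed 1 --out lt1.yaml
immunohta analyze --config lt1.yaml --out results/ --no-dsa
```

`results/scenario_table.csv` then contains (rounded):

```
 scenario  sensitivity  specificity  delta_qaly  delta_cost       icer  cost_effective
 headroom         1.00         1.00      -0.089  -43849.538 490965.651            True
se75_sp75         0.75         0.75      -0.118  -48863.891 413625.785            True
se90_sp60         0.90         0.60      -0.074  -32700.418 441610.760            True
se60_sp90         0.60         0.90      -0.162  -65027.364 400851.804            True
```

Reading the headroom row: a perfect test that moves every
immunochemotherapy nonresponder to chemotherapy alone costs the cohort
0.089 QALYs per patient (nonresponders survive the first year better on
the combination) but saves €43,850 — €490,966 saved per QALY lost, far
above the €80,000 willingness-to-accept threshold, so the biomarker
strategy is cost-effective; imperfect tests stay cost-effective with
smaller savings-per-QALY-lost ratios. The same pipeline in the ≥50%
stratum shows the mirror image: a QALY *gain* at a cost *increase* that
exceeds €80,000 per QALY gained, unless both arms share a fixed therapy
duration (`immunohta`'s equal-duration scenario), which roughly halves
the ICER.

The same steps in Python:

```python
from immunohta import PDL1Group, headroom
from immunohta.synthetic import GeneratorConfig, generate_parameter_set

params = generate_parameter_set(GeneratorConfig(seed=1, group=PDL1Group.LT1))
print(headroom(params).describe())
# EUR 490,966 saved per QALY lost; cost-effective at EUR 80,000/QALY
```

## Layout

```
src/immunohta/
  parameters.py     input schema, validation, derived response rates
  decision_tree.py  strategy routing -> initial cohort distribution
  survival.py       anchors -> per-cycle transition schedules
  markov.py         cohort engine, traces, life-years
  economics.py      utilities, costs, discounting, ICER comparison
  analyses.py       headroom, scenario grid, one-way DSA, equal-duration
  synthetic.py      seeded synthetic parameter sets, microsim oracle
  cli.py            synth | tree | run | analyze | dsa
docs/methods.md     model description, assumptions, generator ranges
```
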