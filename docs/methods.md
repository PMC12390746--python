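# Methods

`immunohta` implements an early health-technology-assessment (HTA) model of
predictive biomarkers for immunotherapy response in advanced non-small-cell
lung cancer (NSCLC). It asks: if a test could predict which patients will
respond to immune-checkpoint-inhibitor therapy, what would treating by test
result be worth, in QALYs and euros, relative to treating by PD-L1
expression alone?

## Population, strategies and response definition

The modelled population is stage 3/4 NSCLC without targetable mutations,
stratified by PD-L1 tumor proportion score into three groups: <1%
(`LT1`), 1–49% (`PD1_49`) and ≥50% (`GE50`). *Response* is defined
throughout as being progression-free at 12 months.

Current practice gives immunochemotherapy (pembrolizumab + platinum
doublet) to the two low-expression strata and immunotherapy alone to the
≥50% stratum. The biomarker strategy routes by a binary test for
immunotherapy response:

| stratum | test positive | test negative |
|---|---|---|
| <1%, 1–49% | immunochemotherapy | chemotherapy alone (de-escalation) |
| ≥50% | immunotherapy alone | immunochemotherapy (escalation) |

## Response arithmetic

Arm-level response rates per stratum (12-month PFS): <1% — 32.8%
immunochemo vs 19.3% chemo; 1–49% — 42.9% vs 17.7%; ≥50% — 37.5% on
immunotherapy alone, with the immunochemo rate derived from a PFS hazard
ratio of 1.81 by **risk scaling**: `r_combo = 1 − (1 − r_mono)/HR`
(= 65.5%). The alternative hazard-power convention
`1 − (1 − r_mono)^(1/HR)` is available behind
`response.derivation_mode = HR_HAZARD_POWER` for exploration, but risk
scaling is the model's convention because it is the arithmetic the
stratum-level rates are built on.

A **nested-responder assumption** links the arms: responders to the weaker
arm are a subset of responders to the combination. It yields

* `P(respond to comparator | combo responder) = r_mono / r_combo`
  (58.8% for <1%, 41.3% for 1–49%), and
* `P(respond to combo | mono nonresponder) = 1 − (1−r_combo)/(1−r_mono)`
  (44.8% for ≥50%).

The tree's reference responder status is response to the arm the test
predicts: immunochemotherapy for the low strata, immunotherapy alone for
≥50%. Sensitivity applies among reference responders, specificity among
reference nonresponders; a patient routed off the reference arm carries
the conditional response probability above, so imperfect tests mix
correctly. With Se = Sp = 1 the <1% tree sends all 67.2% combo
nonresponders to chemotherapy (none respond, by nesting), and the ≥50%
tree offers the combination to all IO nonresponders, of whom 44.8% are
rescued — the overall response rate then equals the derived 65.5%.

## State-transition model

Five reporting health states in monthly cycles over a 5-year horizon
(60 cycles): response on treatment, stable without response, progression,
death from disease, death from other causes. Internally the "stable
without response" state is split into two streams, because nonresponders
either die or progress within the first 12 months:

* **Dying stream** (fraction `(1 − os12)/(1 − pfs12)` of nonresponders,
  from the arm's 12-month PFS/OS gap): dies at conditional per-cycle
  probabilities following the exponential shape implied by the arm's
  12-month OS anchor, renormalised so the stream is extinct at cycle 12
  (the final conditional probability is exactly 1). The within-year shape
  is the package's own assumption (an exponential), config-overridable
  through the OS anchor; only the 12-month boundary is fixed by the model
  definition.
* **Progressing stream** (fraction `(os12 − pfs12)/(1 − pfs12)`): moves to
  the progression state deterministically at the start of the cycle after
  the mean time to progression (9 months by default), making the trace
  auditable; a mean-matched geometric alternative was considered and
  rejected as harder to audit for no accuracy gain.

Responders progress at a constant monthly hazard obtained by fitting
`−ln S(t) = λ t` through the origin to the arm's PFS anchors by least
squares (closed form `λ = Σ t·y / Σ t²`; a single anchor gives
`λ = −ln S/t`). By default the hazard applies from cycle 1
(`responder_progression_mode = fitted`); the alternative reading that
responders are immune to progression during the first year
(`delayed12`) is implemented and selectable, since the 12-month response
definition admits both.

Progression carries a constant death hazard `1/mean_pps` per cycle
(geometric, mean-matched to the 5.4-month mean post-progression survival;
a fixed countdown would break the memoryless Markov formalism). Every
alive state also faces other-cause mortality `q_x` (scalar or per-cycle
schedule, e.g. from a national life table; default generator values are
~0.0008–0.002/month, plausible for the age of this population). Within a
cycle the disease event is evaluated first and `q_x` applies to patients
without a disease event that cycle; at a monthly step the ordering effect
is second order.

There is no half-cycle correction by default (`half_cycle_correction`
switch provided): the analysis outputs are *differences* between
strategies, in which the correction largely cancels.

## Rewards and discounting

Cycle `t` (t = 1..T) earns the **start-of-cycle** occupancy one month of
state utility and state cost, discounted by `(1 + r)^(−t/12)` — health at
1.5%/year, costs at 4.0%/year. This convention makes a patient whose
deterministic progression lands at cycle 10 pay exactly 10 months of
medication, which is the model's intended reading of "medication until
progression".

* **Utilities**: `u_response` in the pre-progression states (both
  responder and nonresponder streams — stable disease on treatment),
  `u_progression` after progression. Side-effect disutilities are
  prevalence-weighted per regimen (`Σ p_i d_i`) and subtracted while on
  medication.
* **Costs**: medication per cycle while on medication (gated by the
  regimen's duration rule: until progression, or a fixed number of
  months); per-cycle state costs; the prevalence-weighted side-effect
  management cost (`Σ p_i c_i`) amortised evenly over the first 12
  on-medication cycles (side effects are a first-year phenomenon; the
  amortisation period is the package's choice — the total charged equals
  the aggregate exactly when the patient stays on medication a year);
  one-time costs for biopsy + PD-L1 determination at cycle 0 in every
  strategy and the biomarker test cost (default €0) in the biomarker
  strategy; a discontinuation cost at the medication-stop event
  (progression, or the fixed stop); terminal care on death transitions —
  by default on other-cause deaths too (`terminal_care_on_other_cause`
  switch, since the model text attributes it simply to patients who die).

## Comparison rule

`compare` reports comparator-minus-reference ΔQALY and ΔCost with
quadrant-aware ICER semantics at a €80,000/QALY threshold: QALYs gained
at extra cost → € per QALY gained, cost-effective iff ≤ threshold; QALYs
lost for savings → € saved per QALY lost, cost-effective iff ≥ threshold
(willingness-to-accept rule); dominance decided without division; equal
QALYs → cost minimisation.

## Analyses

* **Headroom**: the comparison at Se = Sp = 100% — the upper bound of a
  test's value per stratum.
* **Scenario grid**: headroom plus Se/Sp = 75/75, 90/60, 60/90; the
  degenerate 0/0 corner is available (`--include-zero-corner`) because it
  anchors the strongest qualitative claim — de-escalation in the low
  strata stays cost-saving even then, since responders (who accrue the
  long expensive treatment durations) are exactly the patients a useless
  test sends to chemotherapy.
* **One-way DSA** at the 75/75 operating point: mean post-progression
  survival ×0.5–×1.5, and the two state utilities varied jointly (×0.5 of
  base up to 1.0 — jointly, so the ordering invariant
  `u_progression ≤ u_response` is preserved). Output is a tornado table
  sorted by ICER swing with verdict flips flagged.
* **Equal-duration scenario** (≥50% stratum only): both arms' medication
  duration fixed to the same number of months (default: expected time on
  treatment under current practice), removing the cost inflation that
  longer survival on the combination otherwise produces; under the
  default synthetic inputs this roughly halves the ICER and makes the
  escalation strategy cost-effective.

## Synthetic inputs

The supplementary tables behind the published analysis (exact utilities,
side-effect profiles, unit costs, within-year survival shapes) are not
publicly deposited. `immunohta.synthetic` generates **labelled synthetic
reconstructions**: complete, internally consistent parameter sets from
documented plausible ranges, with the stratum-level response rates, the
9-month time-to-progression, the 5.4-month post-progression survival, the
discount rates and the €80,000 threshold pinned to their published values
when `fix_printed` is set (default). Sampling ranges:

| quantity | range |
|---|---|
| u_response | 0.70–0.85 |
| u_progression | 0.50–0.70 (and ≤ u_response − 0.02) |
| pembrolizumab-containing medication | €5,000–9,000 /cycle (combo = immuno + 0.8–1.0 × chemo) |
| chemotherapy medication | €500–2,000 /cycle |
| side effects | 3–8 per regimen; prevalence 0.02–0.40; disutility 0.01–0.12; cost €100–3,000 |
| arm pfs12 | the arm's response rate (response *is* 12-month PFS) |
| os12 − pfs12 gap | 0.10–0.18 (chemo), 0.18–0.28 (immunotherapy-containing) |
| responder PFS rate λ | 0.05–0.08 /month (chemo), 0.025–0.045 (immunotherapy-containing) |
| state costs | €200–600 (response), €500–1,500 (progression) /month |
| one-time costs | biopsy €400–900, PD-L1 €100–300, discontinuation €200–800, terminal €5,000–12,000 |
| other-cause mortality | 0.0008–0.0020 /month |

The wider OS–PFS gap on immunotherapy-containing arms encodes the
mechanism behind the published QALY loss of de-escalation: nonresponders
survive the first year better on immunochemotherapy. These ranges
reproduce the qualitative result pattern (cost-saving/QALY-losing
biomarker strategies with savings-per-QALY-lost above €80,000 in the low
strata; QALY-gaining/cost-increasing and not cost-effective in the ≥50%
stratum); they do **not** reproduce, and are not calibrated to, the
published absolute QALY/cost magnitudes, which depend on the unavailable
supplementary inputs. Passing tests therefore validate the machinery and
the qualitative economics, not the published point estimates.

## Verification

* An independent **microsimulation oracle** re-simulates individual
  patients by per-cycle Bernoulli draws from the same transition
  schedules with independently written reward accumulation; the cohort
  engine agrees within 3 standard errors on QALYs and costs at 10⁵
  patients across 20 generated parameter sets per stratum (and exactly,
  to the bit, when all transitions are deterministic).
* Exponential-rate recovery: noiseless anchors recover λ exactly; with 5%
  log-normal anchor noise the mean fitted rate over 200 seeds is unbiased
  within 3 standard errors.
* Exhaustive-enumeration oracle for the decision tree; closed-form
  geometric/annuity checks for the engine and the discounting; mass
  conservation to 1e-10 at every cycle; comparison antisymmetry.

## Numerical choices and limitations

Problem sizes used in the shipped test suite (10⁵ simulated patients per
oracle comparison, 20 generator seeds per stratum, 200 noise seeds for
rate recovery) were chosen as the smallest sizes at which the 3-SE bands
are meaningfully tight. Transition-matrix rows are validated to sum to 1
(1e-12); cohort traces to conserve mass (1e-10). ΔQALY below 1e-12 is
treated as zero (cost minimisation). The model ignores death from causes
other than progression among responders who leave PFS (progression is
assumed first), test turnaround time and tissue logistics, probabilistic
sensitivity analysis, and currency re-indexing; configurations are
assumed pre-indexed EUR.
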