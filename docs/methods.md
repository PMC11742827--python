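# Methods

## Model structure

The engine (`hfcea.cohort`) is a deterministic Markov cohort model with three
states — stable HFrEF, post-hospitalization, dead — advanced in quarterly
cycles from age 66 until age 110 or cohort extinction (alive fraction below
1e-9). Within a cycle, events resolve in a fixed order:

1. **Background all-cause death** is applied first to both alive states. The
   probability is the age-interpolated life-table rate times the
   excess-mortality rate ratio (4.6) and the arm's mortality hazard ratio,
   converted with `p = 1 − e^(−r·Δt)` and capped at 1.
2. **Hospitalization** strikes the surviving stable patients. The baseline
   quarterly probability (0.024) escalates on the rate scale by
   1.16^(years elapsed) before the arm's hospitalization hazard ratio is
   applied; 9% of admissions die in hospital (identically in both arms), the
   rest move to post-hospitalization.
3. **Urgent care visits** hit the surviving, non-hospitalized stable
   patients (probability 0.002 × arm hazard ratio, constant over time); they
   carry cost and disutility but no state change.
4. From **post-hospitalization**, survivors are readmitted with probability
   0.246 — a readmission carries the full admission cost, disutility and 9%
   case fatality and leaves the patient in post-hospitalization — otherwise
   they return to stable.

Death-first ordering keeps every flow a product of conditional
probabilities, so occupancy conservation holds to machine precision without
renormalization (the engine enforces |Σ occupancy − 1| ≤ 1e-12 per cycle and
raises on any intermediate probability outside [0, 1]).

Accrual uses **end-of-cycle occupancy**: a patient contributes the cycle's
0.25 life-years, utility-weighted QALYs and medication cost only if alive
after the cycle's transitions. This makes undiscounted life expectancy under
constant mortality exactly the geometric series Σ (1−p)^(k+1)·0.25, which
the tests exploit as a closed-form oracle. A half-cycle correction
(averaging start- and end-of-cycle occupancy) is available as a switch but
off by default, matching common cohort-engine practice. Event costs and
disutilities attach to expected event counts in the cycle they occur.
Discounting multiplies cycle k by (1 + r)^(−0.25·k) with r = 0.05/year for
both costs and effects.

Post-hospitalization uses the same utility and recurring costs as stable
disease; the state exists to carry the elevated readmission risk. Treatment
persists to death with full adherence, and dapagliflozin is assumed to have
no effect on in-hospital mortality.

## Parameters

All inputs live in `ParameterSet` (quarterly probabilities, hazard ratios
with 95% CIs, EQ-5D-anchored utilities, 2023-US$ costs) with the base case
as defaults, so an empty YAML config reproduces it. Key defaults: urgent
visit 0.002/cycle, hospitalization 0.024/cycle (cycle 1), all-cause death
0.021 (cycle 1, the mortality calibration anchor), in-hospital death 0.09,
readmission 0.246; hazard ratios 0.83 (death), 0.70 (hospitalization), 0.43
(urgent visit); utility 0.78 with 0.174%/cycle relative decline, one-off
disutilities −0.100 and −0.036; per-cycle costs US$ 82.71 (standard therapy
and monitoring) and US$ 74.97 (dapagliflozin add-on); per-event costs
US$ 611.09 (admission) and US$ 18.53 (urgent visit); discount 5%/yr; cohort
1,000; threshold US$ 8,000/QALY.

## Background mortality and the synthetic life table

`hfcea.life_table` supplies annual all-cause mortality by exact age with
linear interpolation between integer rows and log-linear (Gompertz)
continuation beyond the last row. The DEALE device treats HFrEF excess
mortality as a constant rate ratio applied to the background rate at every
age; the ratio is held at 4.6 for life.

The synthetic generator emulates a national adult life table as a Gompertz
law `μ(a) = α·e^(β(a−66))` with α = 0.01846/year and β = 0.095/year. α is
back-solved so that 4.6·μ(66) converts to the model's first-cycle quarterly
death probability of 0.021 (`4·(−ln(1−0.021))/4.6 ≈ 0.01846`); β = 0.095 is
a typical adult log-slope, giving a background remaining life expectancy at
66 of ≈15.9 years. The generator therefore reproduces the *level* of
old-age-entry mortality and a realistic exponential age gradient, but not
the exact age profile of any national table — late-old-age plateaus,
period-table irregularities and cause composition are not emulated. Results
that integrate the full age profile (incremental life-years, and everything
downstream of them) therefore depend on which table is supplied; a real
table can be dropped in as a CSV at any point, and tests that compare
against published cohort results document this dependence. A known source
inconsistency is retained deliberately: the trial's control-arm mortality
(9.5/100 person-years ≈ 0.0235/quarter) does not equal the 0.021 cycle-1
value used as the calibration anchor; the anchor wins because it is the
value the published parameter table defines for the first cycle.

## Distribution fitting and sensitivity analysis

Ranges are treated as 95% intervals (σ = width/3.92). Probabilities and
utilities get method-of-moments **beta** fits, costs **gamma**, hazard
ratios **log-normal** with the median anchored on the point estimate
(μ = ln HR, σ = CI log-width/3.92). Disutilities are fitted as beta on their
absolute value and negated at sampling time (beta support is [0, 1]).
Zero-width ranges, and beta fits whose implied variance is infeasible
(σ² ≥ m(1−m)), degenerate to point masses — the infeasible case with a
logged warning rather than a hard failure. Parameters with no stated range
vary ±10% (probabilities/utilities) or ±20% (costs).

The tornado analysis re-runs both arms at each parameter's low and high
bound, everything else at base, and sorts by ICER bandwidth; variations that
destroy the QALY gain are flagged, never dropped. The PSA samples all 15
varied parameters **independently** (the trial's joint distribution of the
three hazard ratios is not modelled — a known limitation) from one
`numpy` Generator stream in a fixed, documented order
(`SENSITIVITY_PARAMETERS`), one vectorized draw block per parameter, so a
seed fully determines the run and adding a parameter changes downstream
draws. The sampled first-cycle death probability is translated into a
multiplier on the background mortality *rate*, shifting the whole age
profile coherently. Sampled probabilities at 1 are clipped just below and
counted. The CEAC is computed pointwise from the same draw set (default
grid 0–20,000 US$/QALY in steps of 500), with no re-simulation.

## Scenarios

Scenario overrides are validated by name (unknown keys raise). Discounting
and horizon scenarios change one setting; horizon truncation simply stops
accrual with no terminal-state valuation. The adverse-event scenario
attaches volume depletion and serious acute kidney injury as transient
per-cycle events: cumulative trial incidences over the 18.2-month follow-up
(2.7% vs 1.6% for serious renal injury) are converted to constant quarterly
probabilities by the same rate machinery. Their per-event costs and
disutilities are **synthetic placeholders** (US$ 500, −0.05) because the
source reimbursement values are not published in the main analysis; the
scenario's direction (control-arm excess lowers the ICER) is meaningful, its
magnitude is not, until real values are configured. Diabetes subgroups swap
in the subgroup hazard ratios (diabetic: 0.76 hospitalization / 0.78 death;
non-diabetic: 0.63 / 0.88) on shared baselines, with a configurable
diabetic background-cost increment defaulting to zero.

The breakeven search exploits the fact that per-cycle accruals are
horizon-independent: cumulative sums of one lifetime run per arm give the
truncated-horizon ICER at every quarterly horizon, and the smallest horizon
with ICER ≤ WTP is returned (ICER is monotone non-increasing in horizon in
this model).

## Numerical choices

- Probability caps at 1 after any rate-scale scaling; `expm1`/`log1p` used
  throughout to keep small-probability algebra accurate.
- Lifetime cap at age 110 with occupancy epsilon 1e-9; tail mass is
  negligible at that point under any plausible mortality input.
- ICERs are computed from unrounded totals and reported `None` (or flagged
  "dominant") rather than as negative/infinite ratios when the effect
  increment is non-positive.
- Problem sizes: the shipped analyses use the 1,000-patient cohort over a
  lifetime (≈176 cycles), 10,000 PSA draws, and a 10,000-patient
  individual-level simulation as the test oracle — enough for Monte Carlo
  standard errors well inside the tolerances the tests assert.

## What the tests show — and what they don't

Unit tests pin every algebraic primitive to independently evaluated values;
property tests (hypothesis, derandomized) cover conversion inverses,
monotonicities and occupancy conservation; an individual-level Monte Carlo
simulator with the same event ordering must agree with the cohort
expectations within 3 standard errors; a zero-variance PSA must reproduce
the base-case ICER bit-for-bit. End-to-end tests compare against the
published cohort results, which were produced with the national census life
table: on the synthetic table the first-cycle calibration, the PSA
cost-effectiveness fraction and the qualitative orderings reproduce, while
quantities that integrate the full mortality age profile (incremental
life-years and their downstream ratios) deviate — passing those requires
supplying the real table at `data/brazil_2022_lifetable.csv`.

## Limitations

No treatment-effect waning, discontinuation or adherence dynamics; no
parameter correlations in the PSA; no sex or NYHA-class stratification; no
multi-strategy frontier (exactly two comparators); no budget-impact or
currency machinery. The 16%/yr hospitalization escalation is interpreted as
continuous rate-scale compounding; the source model's exact functional form
is not published.
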