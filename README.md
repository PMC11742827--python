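# hfcea

Cost-utility modelling of add-on **dapagliflozin** for **heart failure with
reduced ejection fraction (HFrEF)** from the perspective of the Brazilian
public healthcare system (SUS), in 2023 US$.

SGLT2 inhibitors reduce mortality and heart-failure hospitalizations when
added to standard HFrEF therapy, but they add a lifelong drug cost. This
package implements the decision-analytic machinery needed to ask whether the
trade-off is worth paying for: a three-state Markov cohort model (*stable
disease* → *post-hospitalization* → *death*) advanced in 3-month cycles, with
the treatment effect expressed as hazard ratios from the DAPA-HF trial, cost
and utility accounting per cycle, and full deterministic/probabilistic
uncertainty analysis. It is a library first: the intended users are health
economists and HTA analysts scripting analyses in Python (an `hfcea` command
wraps the same functions for quick runs).

## The model

Each quarter, a patient in *stable disease* may die of any cause, be
hospitalized for heart failure (dying in hospital with probability 0.09, else
moving to *post-hospitalization*), or have an urgent HF care visit (a
within-cycle event). From *post-hospitalization*, patients face an elevated
readmission probability (0.246) and otherwise return to *stable*.

Background mortality comes from an age-specific life table scaled by a
constant excess-mortality rate ratio (DEALE device):

```
p_death(a) = 1 − exp(−μ(a) · RR · HR_death · Δt),   Δt = 0.25 y, RR = 4.6
```

Event rates and probabilities interconvert through the standard exponential
relationship `p = 1 − e^(−r·t)`; hazard ratios act on the rate scale,
`p′ = 1 − (1−p)^HR`. The hospitalization rate escalates by 16% per year of
age; utility (0.78 at baseline) declines by 0.174% per cycle, with one-off
disutilities of −0.100 per (re)admission and −0.036 per urgent visit. Costs
and QALYs are discounted at 5%/year. The headline statistic is the
incremental cost-effectiveness ratio,

```
ICER = ΔCost / ΔQALY,
```

judged against the Brazilian willingness-to-pay threshold of US$ 8,000/QALY,
plus ICERs per life-year saved and per hospitalization avoided, and the net
monetary benefit `NMB = WTP·ΔQALY − ΔCost`.

Because the national 2022 census life table is not redistributable, the
package ships a **synthetic Gompertz life table**
(`synthesize_life_table()`), calibrated so the age-66 annual rate is
0.01846/person-year — which reproduces the model's first-cycle quarterly
death probability of 0.021 after the 4.6 rate-ratio adjustment — with a
log-slope of 0.095/year of age. Any real life table can be supplied as a
2-column CSV (`age,annual_mortality_rate`) via `load_life_table`.

## Worked example

```python
from hfcea import (ArmSpec, ParameterSet, incremental_analysis,
                   run_cohort, synthesize_life_table)

params = ParameterSet()                 # base case: 1,000 patients, age 66
table = synthesize_life_table()         # calibrated Gompertz stand-in
dapa = run_cohort(ArmSpec.dapagliflozin(params), params, table)
std = run_cohort(ArmSpec.standard(params), params, table)
res = incremental_analysis(dapa, std, wtp=params.wtp)
print(f"dQALY {res.delta_qaly:,.1f}  dCost {res.delta_cost:,.0f} US$  "
      f"ICER {res.icer_per_qaly:,.0f} US$/QALY")
```

prints

```
dQALY 453.6  dCost 1,773,061 US$  ICER 3,909 US$/QALY
```

i.e. over a lifetime, treating 1,000 patients with add-on dapagliflozin
buys ≈454 extra QALYs for ≈US$ 1.77 million — about US$ 3,909 per QALY,
well below the US$ 8,000 threshold, so the strategy is cost-effective under
the base-case inputs. The `examples/` directory holds one short script per
capability (base case, life-table calibration, tornado, PSA + CEAC,
scenarios and breakeven horizon); each prints its results with a note on
what they mean. The same analyses are available from the shell:

```bash
hfcea run --outdir out/            # traces, table2.csv, results.json
hfcea psa --n 10000 --seed 1       # PSA draws + acceptability curve
hfcea scenarios --which all
hfcea breakeven --wtp 8000
```

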