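"""One-way deterministic sensitivity analysis (tornado diagram data).

Varies each model parameter across its 95% range, one at a time, and ranks
parameters by the width of the resulting ICER band.  Wide bands mark the
inputs whose uncertainty matters most for the cost-effectiveness conclusion.
"""

from hfcea import ParameterSet, base_case_icer, synthesize_life_table, tornado

params = ParameterSet()
table = synthesize_life_table()

print(f"base-case ICER: {base_case_icer(params, table):,.0f} US$/QALY\n")
print(f"{'parameter':<16}{'low':>10}{'high':>10}{'ICER low':>12}{'ICER high':>12}{'band':>10}")
for e in tornado(params, table):
    print(f"{e.parameter:<16}{e.low:>10.4g}{e.high:>10.4g}"
          f"{e.icer_low:>12,.0f}{e.icer_high:>12,.0f}{e.bandwidth:>10,.0f}")
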