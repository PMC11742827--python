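"""Background mortality and its HFrEF calibration.

Builds the synthetic Gompertz life table, shows the DEALE-style excess
mortality adjustment (population rate x rate ratio 4.6 -> quarterly death
probability), and writes the table as CSV for inspection or reuse via
``load_life_table``.
"""

from hfcea import adjusted_quarterly_death_prob, deale_rate_ratio, synthesize_life_table

table = synthesize_life_table()
print(f"annual mortality rate at 66: {table.rate(66):.5f} per person-year")
print(f"remaining life expectancy at 66 (background only): "
      f"{table.life_expectancy(66):.1f} years")

# the HFrEF cohort dies at 4.6x the population rate (DEALE rate ratio)
print(f"rate ratio from equal rates: {deale_rate_ratio(0.095, 0.095):.1f}")
for age in (66, 76, 86):
    p = adjusted_quarterly_death_prob(table, age, 4.6)
    print(f"quarterly death probability at age {age} (ratio 4.6): {p:.4f}")

table.to_csv("synthetic_lifetable.csv")
print("table written to synthetic_lifetable.csv")
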