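"""The 40% limit on synthetic partition tables.

Draws 10,000 partition ledgers from the calibrated generator, computes
the intra-to-inter ratio r = |E_intra-global / E_inter| for each, and
shows that the upper envelope of the scatter recovers the 0.4 bound
while the bulk of structures sit far below it.
"""

from lattpart import (EnergyTableSpec, cumulative_fractions, envelope_fit,
                      gen_energy_table, intra_linear_fit, ratio)

parts = gen_energy_table(EnergyTableSpec(n=10_000, seed=1))
records = [ratio(p) for p in parts]

env = envelope_fit(records, "max-ratio")
q99 = envelope_fit(records, "upper-quantile", 0.99)
fit = intra_linear_fit(parts)
fracs = cumulative_fractions(records, [0.10, 0.15, 0.40])

print(f"n = {env.n} structures")
print(f"max-ratio envelope slope : {env.slope:.3f}")
print(f"0.99-quantile slope      : {q99.slope:.3f}")
print(f"OLS E_intra vs E_inter   : slope {fit.slope:.3f}, R2 {fit.r_squared:.2f}")
print(f"fraction with r <= 0.10  : {fracs[0]:.2f}")
print(f"fraction with r <= 0.15  : {fracs[1]:.2f}")
print(f"fraction with r <= 0.40  : {fracs[2]:.2f}")
print("""
The envelope slope sits just under 0.40: no structure's conformational
penalty exceeds 40% of its intermolecular stabilization. The OLS slope
(~ -0.17, the mean of the triangular ratio density) lies far below the
envelope: the bound is an extreme-value statement, not a trend line.""")
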