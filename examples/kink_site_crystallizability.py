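"""Kink-site energetics and crystallizability of high-ratio forms.

At a kink (half-crystal) site a molecule engages about half of its
lattice neighbours, so a conformation is only incorporated with a net
energy gain while its intramolecular penalty stays below f = 0.5 of
|E_inter|.  The report places each structure's ratio within a reference
distribution; the two worked-example stable forms (r = 0.35 and 0.30)
are exactly the ones reported as hard to crystallize.
"""

from lattpart import crystallizability_report, load_worked_partitions

parts = list(load_worked_partitions().values())
rep = crystallizability_report(parts)

cols = ["structure_id", "r", "r_adj", "kink_score", "percentile", "high_ratio"]
print(rep[cols].to_string(index=False,
                          float_format=lambda v: f"{v:.2f}"))

print("""
kink_score = 0.5|E_inter| - E_intra-global (kJ/mol): still positive for
every form, but the r = 0.35 and 0.30 forms sit above the 90th
percentile of the reference ratio distribution -- the regime where
nucleation has historically been difficult.""")
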