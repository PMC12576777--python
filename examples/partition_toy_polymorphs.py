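"""Partition the lattice energies of a toy conformational-polymorph pair.

Form A packs the relaxed anti conformer loosely; form B packs a strained
gauche conformer more densely.  The pipeline relaxes each crystal,
extracts the molecular conformation, and splits the lattice energy into
its intermolecular and intramolecular (adjustment + change) parts.
"""

from lattpart import (ForceFieldConfig, gen_toy_polymorph_pair,
                      run_partition_pipeline)

cfg = ForceFieldConfig(cutoff=9.0)
form_a, form_b = gen_toy_polymorph_pair()

print(f"{'form':<6}{'E_inter':>9}{'E_adj':>8}{'dE_chg':>8}"
      f"{'E_intra':>9}{'E_latt':>9}   (kJ/mol)")
for xtal in (form_a, form_b):
    p = run_partition_pipeline(xtal, cfg=cfg).partition
    print(f"{xtal.structure_id[-1]:<6}{p.E_inter:>9.2f}"
          f"{p.E_adjustment:>8.2f}{p.dE_change_global:>8.2f}"
          f"{p.E_intra_global:>9.2f}{p.E_latt_global:>9.2f}")

print("""
Form B pays a ~9 kJ/mol conformational penalty (the gauche-anti gap of
the torsion potential) but gains more intermolecular stabilization from
its denser cell, ending up the more stable polymorph overall -- the
classic trade-off of conformational polymorphism.""")
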