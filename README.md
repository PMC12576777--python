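# lattpart

Lattice-energy partitioning for crystals of flexible molecules:
how much intramolecular strain can improved packing buy?

Flexible molecules often crystallize in conformations well above their
gas-phase minimum because the distorted shape packs better.  `lattpart`
makes that trade-off quantitative.  It decomposes the lattice energy of
a molecular crystal as

```
E_latt-global = E_inter + E_intra-global
              = E_inter + (E_adjustment + ΔE_change-global)
```

where `E_inter` is the molecule–molecule interaction energy per molecule
(crystal energy minus the gas-phase single point of the crystal
conformation), `E_adjustment ≥ 0` is the strain of distorting the
nearest gas-phase conformer into the crystal conformation, and
`ΔE_change-global ≥ 0` is the gap between that conformer and the
global-minimum conformer.  On top of the partition it provides:

* a **polymorph-stability benchmark**: mean absolute deviation (MAD)
  between computed relative lattice energies and experimental enthalpy
  differences over polymorph pairs, with model-grid ranking — the
  bundled 17-pair reference table scores 2.3 kJ/mol in every subset;
* the **40%-limit analysis**: the ratio `r = |E_intra-global/E_inter|`,
  its adjustment/change decomposition, upper-envelope estimators for the
  empirical bound `E_intra-global ≤ 0.4·|E_inter|`, cumulative
  distributions, and a kink-site growth score
  `f·|E_inter| − E_intra-global` (f ≈ 0.5 at the half-crystal position)
  that rationalizes why conformations beyond the bound stop
  crystallizing;
* a **built-in classical energy backend** (periodic LJ + Coulomb over
  bonded chains, analytic gradients, L-BFGS optimizers) and a
  **torsion-grid conformer search**, so the entire pipeline — relax
  crystal, extract conformation, compute the four reference-state
  energies, assemble the ledger — runs end to end on toy crystals in
  seconds, with every stage swappable for a real electronic-structure
  backend via the `EnergyBackend` protocol;
* **synthetic-data generators** for partition tables with calibrated
  ratio distributions and for toy conformational-polymorph pairs where
  a strained conformer buys denser packing.

It is primarily a library (see `examples/`); a thin `lattpart` CLI
(`partition`, `conformers`, `benchmark`, `limit-analysis`, `simulate`)
wraps the same functions for shell use.

## Worked example

```python
from lattpart import ForceFieldConfig, gen_toy_polymorph_pair, \
    run_partition_pipeline

cfg = ForceFieldConfig(cutoff=9.0)
form_a, form_b = gen_toy_polymorph_pair()
for xtal in (form_a, form_b):
    p = run_partition_pipeline(xtal, cfg=cfg).partition
    print(xtal.structure_id, round(p.E_inter, 2), round(p.E_intra_global, 2),
          round(p.E_latt_global, 2))
```

prints (kJ/mol):

```
toy-pair-A -13.95 0.0 -13.95
toy-pair-B -23.87 9.04 -14.83
```

Form B pays a 9 kJ/mol conformational penalty (its chain sits in the
gauche basin, ~9 kJ/mol above the anti global minimum) yet is the more
stable crystal: its denser cell recovers almost 10 kJ/mol of extra
intermolecular stabilization.  Its ratio r = 9.04/23.87 ≈ 0.38 sits
just inside the 40% limit.  The same ledger arithmetic applied to the
bundled reference components of the two classic conformational
polymorphs gives r = 0.35 and 0.30 for the famously hard-to-nucleate
stable forms (`examples/kink_site_crystallizability.py`).

Each script in `examples/` exercises one capability (benchmarking,
conformer search, the 40% analysis, kink scores) and prints a short
interpretation of its numbers.

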