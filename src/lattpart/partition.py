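"""Lattice-energy partitioning.

The lattice energy of a crystal of a flexible molecule, referenced to its
global-minimum gas-phase conformer, splits into an intermolecular part
and an intramolecular penalty,

    E_latt-global = E_inter + E_intra-global
                  = E_inter + (E_adjustment + ΔE_change-global),

where E_inter is the crystal energy per molecule minus the gas-phase
single point of the crystal conformation, E_adjustment is the (always
non-negative) cost of distorting the nearest gas-phase conformer into
the crystal conformation, and ΔE_change-global is the gap between that
conformer and the global-minimum conformer.  This module assembles the
ledger from any backend's reference-state energies and runs the whole
pipeline (crystal relaxation → conformation extraction → conformer
search → ledger) on toy crystals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers import ConformerSearchSettings, generate_conformers, global_min_energy
from .errors import InputError, PartitionError
from .forcefield import (BackendEnergies, EnergyBackend, ForceFieldConfig,
                         ToyForceField)
from .model import CrystalStructure, rewrap_molecule

__all__ = [
    "EnergyPartition",
    "PartitionRun",
    "extract_crystal_conformation",
    "compute_inter",
    "compute_adjustment",
    "compute_change_global",
    "assemble_partition",
    "run_partition_pipeline",
    "SIGN_TOL",
]

#: optimizer noise floor for the >= 0 contracts, kJ/mol
SIGN_TOL = 1e-6


@dataclass(frozen=True)
class EnergyPartition:
    """One structure's partition ledger (all energies kJ·mol⁻¹).

    The derived fields ``E_intra_global`` and ``E_latt_global`` are
    computed, not stored, so the additivity identities hold exactly by
    construction.
    """

    structure_id: str
    compound_id: str
    E_inter: float
    E_adjustment: float
    dE_change_global: float
    inter_model: str = ""
    intra_model: str = ""

    @property
    def E_intra_global(self) -> float:
        return self.E_adjustment + self.dE_change_global

    @property
    def E_latt_global(self) -> float:
        return self.E_inter + self.E_intra_global

    def validate(self, tol: float = SIGN_TOL) -> None:
        if not np.isfinite([self.E_inter, self.E_adjustment,
                            self.dE_change_global]).all():
            raise PartitionError(f"{self.structure_id}: non-finite component")
        if self.E_adjustment < -tol:
            raise PartitionError(
                f"{self.structure_id}: adjustment energy "
                f"{self.E_adjustment:.3g} < 0 (must be a penalty)"
            )
        if self.dE_change_global < -tol:
            raise PartitionError(
                f"{self.structure_id}: global change energy "
                f"{self.dE_change_global:.3g} < 0 "
                "(conformer search missed the global minimum?)"
            )


@dataclass
class PartitionRun:
    """Pipeline output: the ledger plus every logged intermediate."""

    partition: EnergyPartition
    backend_energies: BackendEnergies
    intermediates: dict = field(default_factory=dict)


def extract_crystal_conformation(xtal: CrystalStructure,
                                 molecule_index: int = 0) -> np.ndarray:
    """One whole molecular geometry from the (optimized) crystal.

    The molecule is re-wrapped by bond connectivity so atoms split across
    periodic boundaries are restored to a single image.
    """
    if not 0 <= molecule_index < xtal.z:
        raise InputError(
            f"molecule index {molecule_index} out of range for Z = {xtal.z}")
    mol = xtal.molecules[molecule_index]
    return rewrap_molecule(mol.coords, mol.bonds, xtal.lattice)


def compute_inter(xtal: CrystalStructure, backend: EnergyBackend,
                  cfg: ForceFieldConfig | None = None) -> float:
    """E_inter: crystal energy per molecule minus the gas single point.

    The gas reference is the single-point energy of the extracted crystal
    conformation itself (same geometry, open boundaries), averaged over
    the Z molecules in the cell.  Negative for bound crystals.
    """
    cfg = cfg or ForceFieldConfig()
    e_crystal = backend.crystal_energy_per_molecule(xtal, cfg)
    gas_sps = [
        backend.molecule_energy(
            xtal.molecules[i].with_coords(extract_crystal_conformation(xtal, i)))
        for i in range(xtal.z)
    ]
    return e_crystal - float(np.mean(gas_sps))


def compute_adjustment(mol, conformation: np.ndarray,
                       backend: EnergyBackend,
                       cfg: ForceFieldConfig | None = None):
    """E_adjustment = gas SP − energy of the nearest gas-phase minimum.

    Returns ``(E_adjustment, opt_result)`` so the relaxed conformer can
    feed the change-energy step.  Always ≥ 0 up to optimizer noise.
    """
    cfg = cfg or ForceFieldConfig()
    gas_sp = backend.molecule_energy(mol, conformation)
    res = backend.optimize_molecule(mol, conformation, cfg)
    adj = gas_sp - res.energy
    if adj < -SIGN_TOL:
        raise PartitionError(
            f"adjustment energy {adj:.3g} < 0: gas relaxation raised the energy")
    return adj, res


def compute_change_global(gas_opt_energy: float, global_min_energy_: float,
                          tol: float = SIGN_TOL) -> float:
    """ΔE_change-global = E(gas conformer) − E(global-minimum conformer)."""
    d = gas_opt_energy - global_min_energy_
    if d < -tol:
        raise PartitionError(
            f"change energy {d:.3g} < 0: the conformer search returned a "
            "higher energy than a locally optimized crystal conformer"
        )
    return d


def assemble_partition(structure_id: str, compound_id: str, E_inter: float,
                       E_adjustment: float, dE_change_global: float = 0.0,
                       inter_model: str = "", intra_model: str = "",
                       tol: float = SIGN_TOL) -> EnergyPartition:
    """Build and validate a partition ledger from its three components."""
    p = EnergyPartition(structure_id, compound_id, float(E_inter),
                        float(E_adjustment), float(dE_change_global),
                        inter_model, intra_model)
    p.validate(tol)
    return p


def run_partition_pipeline(
    xtal: CrystalStructure,
    backend: EnergyBackend | None = None,
    cfg: ForceFieldConfig | None = None,
    conformer_settings: ConformerSearchSettings | None = None,
    backend_intra: EnergyBackend | None = None,
    optimize: bool = True,
) -> PartitionRun:
    """End-to-end partition of one crystal.

    Stages: relax the crystal, extract each molecule's conformation,
    compute E_inter, relax each conformation in the gas phase
    (adjustment), search for the global-minimum conformer seeded with the
    crystal torsions (change), assemble the ledger.  For Z > 1 the
    intramolecular terms are averaged over the symmetry-independent
    conformations.  ``backend_intra`` lets a different model supply the
    intramolecular terms (mixed-model partitions); E_inter is unaffected
    by that choice.
    """
    backend = backend or ToyForceField()
    backend_intra = backend_intra or backend
    cfg = cfg or ForceFieldConfig()
    inter = {}

    if optimize:
        xtal, opt_res = backend.optimize_crystal(xtal, cfg)
        inter["crystal_opt"] = opt_res
    e_crystal = backend.crystal_energy_per_molecule(xtal, cfg)

    E_inter = compute_inter(xtal, backend, cfg)

    adjustments, changes, gas_sps, gas_opts = [], [], [], []
    for i in range(xtal.z):
        conf = extract_crystal_conformation(xtal, i)
        mol = xtal.molecules[i]
        gas_sp = backend_intra.molecule_energy(mol, conf)
        adj, opt_res = compute_adjustment(mol, conf, backend_intra, cfg)
        cset = generate_conformers(
            mol, conformer_settings, backend_intra, cfg,
            seed_torsions=[mol.torsion_values(opt_res.coords)],
        )
        gmin = global_min_energy(cset)
        chg = compute_change_global(opt_res.energy, gmin)
        adjustments.append(adj)
        changes.append(chg)
        gas_sps.append(gas_sp)
        gas_opts.append(opt_res.energy)
        inter[f"molecule_{i}"] = {
            "gas_sp": gas_sp, "gas_opt": opt_res.energy,
            "gas_global_min": gmin, "adjustment": adj, "change": chg,
            "n_conformers": len(cset),
        }

    energies = BackendEnergies(
        crystal_per_molecule=e_crystal,
        gas_sp=float(np.mean(gas_sps)),
        gas_opt=float(np.mean(gas_opts)),
        gas_global_min=float(np.mean(gas_opts) - np.mean(changes)),
        backend=backend.label,
    )
    energies.validate()
    part = assemble_partition(
        xtal.structure_id, xtal.compound_id, E_inter,
        float(np.mean(adjustments)), float(np.mean(changes)),
        inter_model=backend.label, intra_model=backend_intra.label,
    )
    inter["optimized_crystal"] = xtal
    return PartitionRun(part, energies, inter)


def backend_energies_to_partition(
    energies: BackendEnergies, structure_id: str, compound_id: str,
    inter_model: str = "", intra_model: str = "",
) -> EnergyPartition:
    """Ledger directly from the four reference-state energies of one backend."""
    return assemble_partition(
        structure_id, compound_id,
        E_inter=energies.crystal_per_molecule - energies.gas_sp,
        E_adjustment=energies.gas_sp - energies.gas_opt,
        dE_change_global=energies.gas_opt - energies.gas_global_min,
        inter_model=inter_model or energies.backend,
        intra_model=intra_model or energies.backend,
    )
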