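"""File formats.

Crystals travel as extended XYZ (comment line carrying ``Lattice="..."``
and a per-atom molecule-membership column) with the classical topology
in a JSON sidecar per compound; partition ledgers, pairing tables and
backend energy tables are CSV with fixed schemas.  All writers emit full
double precision; round-trips are identity to float precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .forcefield import BackendEnergies
from .model import CrystalStructure, Molecule
from .partition import EnergyPartition

__all__ = [
    "write_topology", "read_topology",
    "write_crystal", "read_crystal",
    "write_conformers",
    "write_ledger", "read_ledger",
    "write_pairs", "read_pairs",
    "write_backend_energies", "read_backend_energies",
]

LEDGER_COLUMNS = ["structure_id", "compound_id", "inter_model", "intra_model",
                  "E_inter", "E_adjustment", "dE_change_global",
                  "E_intra_global", "E_latt_global"]
PAIR_COLUMNS = ["compound", "refcode_ref", "refcode_alt", "dH_exp"]
ENERGY_COLUMNS = ["structure_id", "compound_id", "backend",
                  "crystal_per_molecule", "gas_sp", "gas_opt", "gas_global_min"]


# ---------------------------------------------------------------------------
# topology sidecar (JSON)
# ---------------------------------------------------------------------------

def write_topology(mol: Molecule, path) -> None:
    doc = {
        "compound_id": mol.compound_id,
        "elements": list(mol.elements),
        "charges": mol.charges.tolist(),
        "bonds": [list(b) for b in mol.bonds],
        "bond_params": [list(p) for p in mol.bond_params],
        "angles": [list(a) for a in mol.angles],
        "angle_params": [list(p) for p in mol.angle_params],
        "torsions": [list(t) for t in mol.torsions],
        "torsion_params": [[list(term) for term in series]
                           for series in mol.torsion_params],
        "rotatable": [list(t) for t in mol.rotatable],
        "sigma": mol.sigma.tolist(),
        "epsilon": mol.epsilon.tolist(),
        "reference_coords": mol.coords.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_topology(path) -> Molecule:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid topology JSON: {exc}", str(path)) from exc
    try:
        return Molecule(
            elements=tuple(doc["elements"]),
            coords=np.array(doc["reference_coords"], float),
            charges=np.array(doc["charges"], float),
            bonds=tuple(map(tuple, doc["bonds"])),
            bond_params=tuple(map(tuple, doc["bond_params"])),
            angles=tuple(map(tuple, doc["angles"])),
            angle_params=tuple(map(tuple, doc["angle_params"])),
            torsions=tuple(map(tuple, doc["torsions"])),
            torsion_params=tuple(tuple(map(tuple, s))
                                 for s in doc["torsion_params"]),
            rotatable=tuple(map(tuple, doc["rotatable"])),
            sigma=np.array(doc["sigma"], float),
            epsilon=np.array(doc["epsilon"], float),
            compound_id=doc.get("compound_id", ""),
        )
    except KeyError as exc:
        raise ParseError(f"topology missing field {exc}", str(path)) from exc


def _default_topology_path(path: Path) -> Path:
    return path.with_suffix(".topo.json")


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _xyz_frame(comment: str, elements, coords) -> str:
    lines = [str(len(elements)), comment]
    for el, (x, y, z) in zip(elements, coords):
        lines.append(f"{el} {float(x)!r} {float(y)!r} {float(z)!r}")
    return "\n".join(lines) + "\n"


def write_crystal(xtal: CrystalStructure, path, topology_path=None) -> None:
    """Extended XYZ with Lattice header + topology sidecar for the compound."""
    path = Path(path)
    lat = " ".join(repr(float(v)) for v in xtal.lattice.ravel())
    mol_ids, elements, coords = [], [], []
    for m, mol in enumerate(xtal.molecules):
        mol_ids += [m] * mol.n_atoms
        elements += list(mol.elements)
        coords.append(mol.coords)
    comment = (f'Lattice="{lat}" Properties=species:S:1:pos:R:3 '
               f'structure_id={xtal.structure_id or "-"} '
               f'compound_id={xtal.compound_id or "-"} '
               f'mol_id={",".join(map(str, mol_ids))}')
    path.write_text(_xyz_frame(comment, elements, np.concatenate(coords)))
    write_topology(xtal.molecules[0],
                   topology_path or _default_topology_path(path))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_KEY_RE = re.compile(r'(\w+)=([^\s"]+)')


def read_crystal(path, topology_path=None) -> CrystalStructure:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty file", str(path), 1)
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must be the atom count", str(path), 1)
    if len(lines) < natoms + 2:
        raise ParseError(f"expected {natoms} atom lines", str(path), len(lines))
    comment = lines[1]
    m = _LATTICE_RE.search(comment)
    if m is None:
        raise ParseError('missing Lattice="..." entry in the comment line',
                         str(path), 2)
    cell = np.fromstring(m.group(1), sep=" ")
    if cell.size != 9:
        raise ParseError("Lattice must contain 9 numbers", str(path), 2)
    keys = dict(_KEY_RE.findall(_LATTICE_RE.sub("", comment)))
    structure_id = keys.get("structure_id", "")
    if structure_id == "-":
        structure_id = ""
    compound_id = keys.get("compound_id", "")
    if compound_id == "-":
        compound_id = ""
    if "mol_id" in keys:
        mol_ids = [int(x) for x in keys["mol_id"].split(",")]
        if len(mol_ids) != natoms:
            raise ParseError("mol_id column length != atom count", str(path), 2)
    else:
        mol_ids = [0] * natoms

    elements, coords = [], np.empty((natoms, 3))
    for i in range(natoms):
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise ParseError("atom line needs: element x y z", str(path), 3 + i)
        elements.append(parts[0])
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError("non-numeric coordinate", str(path), 3 + i)

    template = read_topology(topology_path or _default_topology_path(path))
    mols = []
    for m_id in sorted(set(mol_ids)):
        idx = [i for i, x in enumerate(mol_ids) if x == m_id]
        if len(idx) != template.n_atoms:
            raise ParseError(
                f"molecule {m_id} has {len(idx)} atoms; topology describes "
                f"{template.n_atoms}", str(path), 2)
        if [elements[i] for i in idx] != list(template.elements):
            raise ParseError(f"molecule {m_id}: element order does not match "
                             "the topology", str(path), 2)
        mols.append(template.with_coords(coords[idx]))
    return CrystalStructure(cell.reshape(3, 3), mols, structure_id,
                            compound_id or template.compound_id)


def write_conformers(cs, path, ranking_path=None) -> None:
    """Multi-frame XYZ of a conformer set plus an optional CSV ranking."""
    frames = []
    for rank, c in enumerate(cs.conformers):
        tors = ",".join(f"{t:.3f}" for t in c.torsions_deg)
        comment = (f"Properties=species:S:1:pos:R:3 rank={rank} "
                   f"energy={float(c.energy)!r} torsions_deg={tors or '-'}")
        frames.append(_xyz_frame(comment, ["C"] * len(c.coords), c.coords))
    Path(path).write_text("".join(frames))
    if ranking_path is not None:
        pd.DataFrame({
            "rank": range(len(cs.conformers)),
            "energy": [c.energy for c in cs.conformers],
            "torsions_deg": [";".join(f"{t:.3f}" for t in c.torsions_deg)
                             for c in cs.conformers],
            "converged": [c.converged for c in cs.conformers],
        }).to_csv(ranking_path, index=False)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}",
                         str(path))


def write_ledger(partitions: Iterable[EnergyPartition], path) -> None:
    rows = [{
        "structure_id": p.structure_id, "compound_id": p.compound_id,
        "inter_model": p.inter_model, "intra_model": p.intra_model,
        "E_inter": p.E_inter, "E_adjustment": p.E_adjustment,
        "dE_change_global": p.dE_change_global,
        "E_intra_global": p.E_intra_global, "E_latt_global": p.E_latt_global,
    } for p in partitions]
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, index=False)


def read_ledger(path) -> list[EnergyPartition]:
    """Partition rows from CSV; derived columns are checked, not trusted."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    _require_columns(df, LEDGER_COLUMNS[:7], path)
    out = []
    for row in df.itertuples(index=False):
        p = EnergyPartition(
            structure_id=str(row.structure_id), compound_id=str(row.compound_id),
            E_inter=float(row.E_inter), E_adjustment=float(row.E_adjustment),
            dE_change_global=float(row.dE_change_global),
            inter_model="" if pd.isna(row.inter_model) else str(row.inter_model),
            intra_model="" if pd.isna(row.intra_model) else str(row.intra_model),
        )
        if hasattr(row, "E_latt_global") and not pd.isna(row.E_latt_global):
            if abs(p.E_latt_global - float(row.E_latt_global)) > 1e-8:
                raise ParseError(
                    f"{p.structure_id}: stored E_latt_global is inconsistent "
                    "with its components", str(path))
        p.validate()
        out.append(p)
    return out


def write_pairs(pairs, path) -> None:
    from .benchmark import PolymorphPair  # noqa: F401  (type of elements)
    pd.DataFrame([{
        "compound": p.compound, "refcode_ref": p.refcode_ref,
        "refcode_alt": p.refcode_alt, "dH_exp": p.dH_exp,
        "dE_latt": p.dE_latt, "subset": p.subset, "model": p.model,
    } for p in pairs]).to_csv(path, index=False)


def read_pairs(path, model: str = ""):
    """Polymorph pairs from a pairing-table CSV.

    Requires compound, refcode_ref, refcode_alt, dH_exp; reads dE_latt
    and subset when present (precomputed tables).  Extra columns are
    ignored, not rejected.
    """
    from .benchmark import PolymorphPair
    df = pd.read_csv(path)
    _require_columns(df, PAIR_COLUMNS, path)
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(PolymorphPair(
            compound=str(row.compound), refcode_ref=str(row.refcode_ref),
            refcode_alt=str(row.refcode_alt), dH_exp=float(row.dH_exp),
            dE_latt=float(getattr(row, "dE_latt", np.nan)),
            subset=str(getattr(row, "subset", "all")),
            model=model,
        ))
    return pairs


def write_backend_energies(
    table: Mapping[str, tuple[str, BackendEnergies]] | Iterable, path,
) -> None:
    """Energy table CSV: one row of the four reference-state energies each.

    Accepts ``{structure_id: (compound_id, BackendEnergies)}`` or an
    iterable of ``(structure_id, compound_id, BackendEnergies)``.
    """
    if isinstance(table, Mapping):
        items = [(sid, cid, be) for sid, (cid, be) in table.items()]
    else:
        items = list(table)
    pd.DataFrame([{
        "structure_id": sid, "compound_id": cid, "backend": be.backend,
        "crystal_per_molecule": be.crystal_per_molecule, "gas_sp": be.gas_sp,
        "gas_opt": be.gas_opt, "gas_global_min": be.gas_global_min,
    } for sid, cid, be in items], columns=ENERGY_COLUMNS).to_csv(path, index=False)


def read_backend_energies(path) -> dict[str, tuple[str, BackendEnergies]]:
    df = pd.read_csv(path)
    if df.empty:
        return {}
    _require_columns(df, ENERGY_COLUMNS, path)
    out = {}
    for row in df.itertuples(index=False):
        be = BackendEnergies(
            crystal_per_molecule=float(row.crystal_per_molecule),
            gas_sp=float(row.gas_sp), gas_opt=float(row.gas_opt),
            gas_global_min=float(row.gas_global_min), backend=str(row.backend),
        )
        be.validate()
        out[str(row.structure_id)] = (str(row.compound_id), be)
    return out
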