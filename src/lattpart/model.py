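"""Containers for flexible molecules and molecular crystals.

A :class:`Molecule` couples a Cartesian geometry (Å) to a classical
topology: harmonic bond and angle terms, cosine-series torsions, per-atom
Lennard-Jones parameters and partial charges.  A :class:`CrystalStructure`
is a periodic arrangement of whole molecules with explicit lattice
vectors (one row per vector, Å).

Geometry helpers (valence angle, dihedral, torsion driving, re-wrapping a
molecule split across periodic boundaries) live here too, since both the
force field and the conformer search need them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import InputError

__all__ = [
    "Molecule",
    "CrystalStructure",
    "angle_value",
    "dihedral_value",
    "set_torsions",
    "rewrap_molecule",
    "make_supercell",
]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def angle_value(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Valence angle i-j-k in radians."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral_value(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral i-j-k-l in radians, in (-pi, pi] (IUPAC convention)."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def set_torsions(
    mol: "Molecule",
    targets_deg: Sequence[float],
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Drive the molecule's rotatable torsions to the given values (degrees).

    Each torsion (i, j, k, l) is set by rigidly rotating the connected
    component containing *k* (with the j-k bond removed) about the j->k
    axis.  Works exactly for acyclic molecules; a torsion whose central
    bond lies in a ring raises :class:`InputError`.
    """
    if coords is None:
        coords = mol.coords
    coords = np.array(coords, dtype=float)
    if len(targets_deg) != len(mol.rotatable):
        raise InputError(
            f"expected {len(mol.rotatable)} torsion targets, got {len(targets_deg)}"
        )
    for (i, j, k, l), target in zip(mol.rotatable, targets_deg):
        g = mol.graph.copy()
        g.remove_edge(j, k)
        moving = nx.node_connected_component(g, k)
        if j in moving:
            raise InputError(f"central bond {j}-{k} lies in a ring; cannot drive torsion")
        current = np.degrees(dihedral_value(coords, i, j, k, l))
        # a positive rotation of the k-side about the j->k axis decreases phi
        delta = np.radians(current - target)
        rot = _rotation_matrix(coords[k] - coords[j], delta)
        idx = sorted(moving)
        coords[idx] = (coords[idx] - coords[j]) @ rot.T + coords[j]
    # sequential driving must have landed every torsion on target
    achieved = [np.degrees(dihedral_value(coords, *q)) for q in mol.rotatable]
    for got, want in zip(achieved, targets_deg):
        if abs((got - want + 180.0) % 360.0 - 180.0) > 1e-6:
            raise InputError("torsion driving failed (interdependent torsions?)")
    return coords


def rewrap_molecule(
    coords: np.ndarray, bonds: Sequence[tuple[int, int]], lattice: np.ndarray
) -> np.ndarray:
    """Make a periodically wrapped molecule whole again.

    Walks the bond graph breadth-first from atom 0 and places every atom at
    the minimum-image position relative to its already-placed neighbour.
    """
    coords = np.array(coords, dtype=float)
    inv = np.linalg.inv(lattice)
    g = nx.Graph(list(bonds))
    g.add_nodes_from(range(len(coords)))
    placed = {0}
    for u, v in nx.bfs_edges(g, 0):
        d = coords[v] - coords[u]
        shift = np.round(d @ inv)
        coords[v] -= shift @ lattice
        placed.add(v)
    if len(placed) != len(coords):
        raise InputError("bond graph is disconnected; cannot re-wrap")
    return coords


# ---------------------------------------------------------------------------
# molecule
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Molecule:
    """A flexible molecule: geometry plus classical topology.

    Units: coordinates Å, charges e, k_bond kJ·mol⁻¹·Å⁻², k_angle
    kJ·mol⁻¹·rad⁻², torsion amplitudes kJ·mol⁻¹ (cosine series
    ``V·(1 + cos(n·φ − γ))``), σ Å, ε kJ·mol⁻¹.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    charges: np.ndarray
    bonds: tuple[tuple[int, int], ...]
    bond_params: tuple[tuple[float, float], ...]          # (k_b, r0)
    angles: tuple[tuple[int, int, int], ...] = ()
    angle_params: tuple[tuple[float, float], ...] = ()    # (k_a, theta0 rad)
    torsions: tuple[tuple[int, int, int, int], ...] = ()
    torsion_params: tuple[tuple[tuple[float, float, float], ...], ...] = ()  # ((V, n, gamma),...)
    rotatable: tuple[tuple[int, int, int, int], ...] = ()
    sigma: np.ndarray = field(default=None)  # type: ignore[assignment]
    epsilon: np.ndarray = field(default=None)  # type: ignore[assignment]
    compound_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.elements)
        if self.sigma is None:
            self.sigma = np.full(n, 3.4)
        if self.epsilon is None:
            self.epsilon = np.full(n, 0.5)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.bonds = tuple(tuple(int(x) for x in b) for b in self.bonds)
        self.bond_params = tuple(tuple(map(float, p)) for p in self.bond_params)
        self.angles = tuple(tuple(int(x) for x in a) for a in self.angles)
        self.angle_params = tuple(tuple(map(float, p)) for p in self.angle_params)
        self.torsions = tuple(tuple(int(x) for x in t) for t in self.torsions)
        self.torsion_params = tuple(
            tuple(tuple(map(float, term)) for term in series)
            for series in self.torsion_params
        )
        self.rotatable = tuple(tuple(int(x) for x in t) for t in self.rotatable)
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_rotatable_bonds(self) -> int:
        return len(self.rotatable)

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph(list(self.bonds))
        g.add_nodes_from(range(self.n_atoms))
        return g

    @cached_property
    def nonbonded_scale(self) -> np.ndarray:
        """Pairwise scale matrix: 0 for 1-2/1-3 (and self), 0.5 for 1-4, 1 else."""
        n = self.n_atoms
        scale = np.ones((n, n))
        np.fill_diagonal(scale, 0.0)
        spl = dict(nx.all_pairs_shortest_path_length(self.graph, cutoff=3))
        for i, dists in spl.items():
            for j, d in dists.items():
                if i == j:
                    continue
                if d <= 2:
                    scale[i, j] = 0.0
                elif d == 3:
                    scale[i, j] = 0.5
        return scale

    # -- operations ---------------------------------------------------------

    def validate(self) -> None:
        n = self.n_atoms
        if self.coords.shape != (n, 3):
            raise InputError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")
        for name, arr in (("charges", self.charges), ("sigma", self.sigma),
                          ("epsilon", self.epsilon)):
            if arr.shape != (n,):
                raise InputError(f"{name} length {arr.shape} != {n}")
        if len(self.bond_params) != len(self.bonds):
            raise InputError("bond_params length mismatch")
        if len(self.angle_params) != len(self.angles):
            raise InputError("angle_params length mismatch")
        if len(self.torsion_params) != len(self.torsions):
            raise InputError("torsion_params length mismatch")
        if n > 1 and not nx.is_connected(self.graph):
            raise InputError("bond graph is not connected")
        edges = {frozenset(b) for b in self.bonds}
        for (i, j, k, l) in self.torsions:
            path = [(i, j), (j, k), (k, l)]
            if any(frozenset(p) not in edges for p in path):
                raise InputError(f"torsion {(i, j, k, l)} is not a bonded path")
        if not set(map(tuple, self.rotatable)) <= set(map(tuple, self.torsions)):
            raise InputError("rotatable torsions must be a subset of torsions")

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of this molecule with replaced coordinates."""
        new = copy.copy(self)
        new.coords = np.array(coords, dtype=float)
        if new.coords.shape != (self.n_atoms, 3):
            raise InputError("coords shape mismatch")
        return new

    def torsion_values(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Rotatable-torsion values in degrees for the given (or own) geometry."""
        c = self.coords if coords is None else np.asarray(coords, float)
        return np.array([np.degrees(dihedral_value(c, *q)) for q in self.rotatable])


# ---------------------------------------------------------------------------
# crystal
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class CrystalStructure:
    """A molecular crystal: lattice vectors plus Z whole molecules."""

    lattice: np.ndarray                    # (3, 3), row per vector, Å
    molecules: list[Molecule]
    structure_id: str = ""
    compound_id: str = ""
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.lattice = np.asarray(self.lattice, dtype=float)
        if self.lattice.shape != (3, 3):
            raise InputError("lattice must be 3x3 (row per vector)")
        if self.validate_on_init:
            self.validate()

    @property
    def z(self) -> int:
        """Molecules per cell."""
        return len(self.molecules)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.lattice)))

    def validate(self) -> None:
        if self.z < 1:
            raise InputError("crystal must contain at least one molecule (Z >= 1)")
        if self.volume <= 0:
            raise InputError("cell volume must be positive")
        for m, mol in enumerate(self.molecules):
            for (i, j), (_, r0) in zip(mol.bonds, mol.bond_params):
                r = float(np.linalg.norm(mol.coords[i] - mol.coords[j]))
                if not (0.5 * r0 <= r <= 1.5 * r0):
                    raise InputError(
                        f"molecule {m}: bond {i}-{j} length {r:.2f} Å deviates more "
                        f"than 50% from r0 = {r0:.2f} Å (molecule not whole?)"
                    )

    def all_coords(self) -> np.ndarray:
        """Concatenated (sum(N_i), 3) coordinates of every molecule."""
        return np.concatenate([m.coords for m in self.molecules], axis=0)

    def with_all_coords(self, coords: np.ndarray,
                        validate: bool = True) -> "CrystalStructure":
        """Copy with coordinates replaced from a concatenated array."""
        coords = np.asarray(coords, float).reshape(-1, 3)
        mols, start = [], 0
        for m in self.molecules:
            mols.append(m.with_coords(coords[start:start + m.n_atoms]))
            start += m.n_atoms
        if start != len(coords):
            raise InputError("coordinate count mismatch")
        return CrystalStructure(self.lattice.copy(), mols,
                                self.structure_id, self.compound_id,
                                validate_on_init=validate)


def make_supercell(xtal: CrystalStructure,
                   repeat: tuple[int, int, int]) -> CrystalStructure:
    """n×m×k replication of a crystal (per-molecule energy is invariant)."""
    na, nb, nc = repeat
    if min(na, nb, nc) < 1:
        raise InputError("replication factors must be >= 1")
    mols = []
    for ia in range(na):
        for ib in range(nb):
            for ic in range(nc):
                shift = (ia * xtal.lattice[0] + ib * xtal.lattice[1]
                         + ic * xtal.lattice[2])
                for m in xtal.molecules:
                    mols.append(m.with_coords(m.coords + shift))
    lat = np.diag([na, nb, nc]).astype(float) @ xtal.lattice
    return CrystalStructure(lat, mols, xtal.structure_id + f"-{na}x{nb}x{nc}",
                            xtal.compound_id)
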