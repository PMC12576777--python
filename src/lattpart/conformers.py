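"""Global-minimum gas-phase conformer search.

Systematic rotatable-torsion enumeration followed by local optimization:
torsion values are laid on a regular grid (optionally seeded with observed
crystal-conformation torsions), grid states are ranked by their
unoptimized energy, the lowest few are relaxed, and near-duplicates are
merged.  On the acyclic toy molecules this search is exhaustive and can
be cross-checked against a dense brute-force grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .forcefield import ForceFieldConfig, ToyForceField
from .model import Molecule, set_torsions

__all__ = ["ConformerSearchSettings", "Conformer", "ConformerSet",
           "generate_conformers", "global_min_energy"]


@dataclass(frozen=True)
class ConformerSearchSettings:
    """Knobs of the torsion-grid search.

    ``grid_step_deg`` is the torsion grid spacing; ``max_generated`` caps
    how many grid states are kept (lowest unoptimized energy first);
    ``top_k`` of those are locally optimized; duplicates are merged when
    both the energy gap and every circular torsion difference fall below
    the dedup thresholds.  Grids larger than ``max_grid`` require
    ``sample=True``, which draws ``max_generated`` random torsion vectors
    instead of enumerating.
    """

    grid_step_deg: float = 120.0
    max_generated: int = 200
    top_k: int = 5
    dedup_energy: float = 0.01        # kJ/mol
    dedup_torsion_deg: float = 15.0
    sample: bool = False
    max_grid: int = 10 ** 6
    seed: int = 0

    def __post_init__(self):
        if self.grid_step_deg <= 0 or self.grid_step_deg > 360:
            raise ConfigurationError("grid_step_deg must be in (0, 360]")
        if self.top_k < 1 or self.max_generated < 1:
            raise ConfigurationError("top_k and max_generated must be >= 1")


@dataclass
class Conformer:
    torsions_deg: np.ndarray
    coords: np.ndarray
    energy: float
    converged: bool = True


@dataclass
class ConformerSet:
    """Locally-optimized conformers, sorted by ascending energy."""

    conformers: list[Conformer]
    settings: ConformerSearchSettings = field(
        default_factory=ConformerSearchSettings)

    @property
    def global_min_index(self) -> int:
        return 0

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    def __len__(self) -> int:
        return len(self.conformers)


def _circular_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs((a - b + 180.0) % 360.0 - 180.0)


def generate_conformers(
    mol: Molecule,
    settings: ConformerSearchSettings | None = None,
    backend: ToyForceField | None = None,
    cfg: ForceFieldConfig | None = None,
    seed_torsions: list[np.ndarray] | None = None,
) -> ConformerSet:
    """Enumerate, rank, refine and deduplicate gas-phase conformers.

    ``seed_torsions`` adds observed torsion vectors (e.g. from crystal
    conformations) to the grid so the search always starts from them too.
    A molecule with no rotatable torsions yields exactly one conformer:
    its own local optimum.
    """
    settings = settings or ConformerSearchSettings()
    backend = backend or ToyForceField()
    cfg = cfg or ForceFieldConfig()
    nt = len(mol.rotatable)

    if nt == 0:
        res = backend.optimize_molecule(mol, cfg=cfg)
        conf = Conformer(np.empty(0), res.coords, res.energy, res.converged)
        return ConformerSet([conf], settings)

    grid_1d = np.arange(-180.0, 180.0, settings.grid_step_deg)
    n_grid = len(grid_1d) ** nt
    if n_grid > settings.max_grid and not settings.sample:
        raise ConfigurationError(
            f"torsion grid has {n_grid} points (> {settings.max_grid}); "
            "enable sampling to search this molecule"
        )
    if settings.sample and n_grid > settings.max_generated:
        rng = np.random.default_rng(settings.seed)
        candidates = [rng.choice(grid_1d, size=nt) for _ in
                      range(settings.max_generated)]
    else:
        candidates = [np.array(v) for v in itertools.product(grid_1d, repeat=nt)]
    for seed_vec in (seed_torsions or []):
        seed_vec = np.asarray(seed_vec, float)
        if seed_vec.shape != (nt,):
            raise InputError(f"seed torsion vector must have length {nt}")
        candidates.append(seed_vec)

    # rank grid states by unoptimized energy, keep at most max_generated
    scored = []
    for vec in candidates:
        coords = set_torsions(mol, vec)
        scored.append((backend.molecule_energy(mol, coords, cfg), tuple(vec), coords))
    scored.sort(key=lambda t: (t[0], t[1]))
    scored = scored[: settings.max_generated]

    refined: list[Conformer] = []
    for e_pre, vec, coords in scored[: settings.top_k]:
        res = backend.optimize_molecule(mol, coords, cfg)
        refined.append(Conformer(mol.torsion_values(res.coords), res.coords,
                                 res.energy, res.converged))

    # dedup: same basin if energies and all torsions agree within thresholds
    refined.sort(key=lambda c: (c.energy, tuple(np.round(c.torsions_deg, 6))))
    kept: list[Conformer] = []
    for c in refined:
        dup = any(
            abs(c.energy - k.energy) < settings.dedup_energy
            and np.all(_circular_diff_deg(c.torsions_deg, k.torsions_deg)
                       < settings.dedup_torsion_deg)
            for k in kept
        )
        if not dup:
            kept.append(c)
    return ConformerSet(kept, settings)


def global_min_energy(cs: ConformerSet) -> float:
    """Energy of the most stable conformer found (kJ·mol⁻¹)."""
    if len(cs) == 0:
        raise InputError("empty conformer set")
    return float(cs.energies.min())
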