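"""Built-in classical energy backend and local geometry optimizers.

The toy force field provides every reference-state energy the lattice
partition needs, at desk scale:

* intramolecular: harmonic bonds and angles, cosine-series torsions, and
  Lennard-Jones + Coulomb between non-bonded atom pairs (1-2 and 1-3
  excluded, 1-4 scaled by 0.5);
* intermolecular: pairwise Lennard-Jones + Coulomb summed over all
  periodic images within a cutoff, with the potential shifted to zero at
  the cutoff so energies are continuous in the coordinates.

Energies are kJ·mol⁻¹, lengths Å, charges e.  Gradients are analytic;
optimizers are L-BFGS-B with an explicit maximum-force convergence
criterion.  Any object implementing :class:`EnergyBackend` can replace
the toy field in the partition pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, InputError
from .model import CrystalStructure, Molecule

__all__ = [
    "COULOMB_KJ_MOL_ANG",
    "ForceFieldConfig",
    "BackendEnergies",
    "OptimizationResult",
    "EnergyBackend",
    "ToyForceField",
]

#: e²/(4πε₀) in kJ·mol⁻¹·Å·e⁻²
COULOMB_KJ_MOL_ANG = 1389.35457644382


@dataclass(frozen=True)
class ForceFieldConfig:
    """Evaluation and optimization settings for the toy field.

    ``cutoff`` (Å) bounds the intermolecular lattice sum; ``force_tol``
    (kJ·mol⁻¹·Å⁻¹) is the maximum-force convergence criterion of both
    optimizers; ``cell_mode`` selects fixed-cell or isotropic cell
    relaxation for crystals.
    """

    cutoff: float = 12.0
    coulomb_constant: float = COULOMB_KJ_MOL_ANG
    one_four_scale: float = 0.5
    force_tol: float = 1e-3
    max_iter: int = 5000
    cell_mode: str = "fixed"   # "fixed" | "isotropic"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")
        if self.cell_mode not in ("fixed", "isotropic"):
            raise ConfigurationError(f"unknown cell_mode {self.cell_mode!r}")


@dataclass(frozen=True)
class BackendEnergies:
    """The four reference-state energies of one crystal structure.

    ``crystal_per_molecule``: crystal electronic energy per molecule;
    ``gas_sp``: single point of the crystal conformation in isolation;
    ``gas_opt``: the nearest gas-phase local minimum of that conformation;
    ``gas_global_min``: the global-minimum gas-phase conformer.
    All kJ·mol⁻¹.
    """

    crystal_per_molecule: float
    gas_sp: float
    gas_opt: float
    gas_global_min: float
    backend: str = ""

    def validate(self, tol: float = 1e-6) -> None:
        if self.gas_opt > self.gas_sp + tol:
            raise InputError(
                f"gas_opt ({self.gas_opt:.6f}) exceeds gas_sp ({self.gas_sp:.6f})"
            )
        if self.gas_global_min > self.gas_opt + tol:
            raise InputError(
                f"gas_global_min ({self.gas_global_min:.6f}) exceeds "
                f"gas_opt ({self.gas_opt:.6f})"
            )


@dataclass
class OptimizationResult:
    """Outcome of a local geometry optimization."""

    coords: np.ndarray
    energy: float
    trace: list[float]
    converged: bool
    n_iter: int
    max_force: float
    scale: float = 1.0   # isotropic cell scale factor (crystals only)


@runtime_checkable
class EnergyBackend(Protocol):
    """Contract any energy backend must satisfy for the partition pipeline."""

    label: str

    def molecule_energy(self, mol: Molecule, coords: np.ndarray | None = None) -> float: ...

    def crystal_energy_per_molecule(
        self, xtal: CrystalStructure, cfg: ForceFieldConfig | None = None
    ) -> float: ...

    def optimize_molecule(
        self, mol: Molecule, coords: np.ndarray | None = None,
        cfg: ForceFieldConfig | None = None,
    ) -> OptimizationResult: ...

    def optimize_crystal(
        self, xtal: CrystalStructure, cfg: ForceFieldConfig | None = None
    ) -> tuple[CrystalStructure, OptimizationResult]: ...


def _lbfgs_until_force_tol(fun, x0, cfg: ForceFieldConfig, callback,
                           max_restarts: int = 8):
    """L-BFGS-B, restarted until the max-force criterion is met or stalls.

    L-BFGS-B terminates on its own relative-reduction test; a handful of
    warm restarts is a cheap, reliable way to push the gradient down to an
    absolute force tolerance.
    """
    x = np.asarray(x0, float)
    nit = 0
    for _ in range(max_restarts):
        res = minimize(fun, x, jac=True, method="L-BFGS-B", callback=callback,
                       options={"maxiter": cfg.max_iter, "ftol": 1e-16,
                                "gtol": 1e-12})
        nit += int(res.nit)
        moved = not np.array_equal(res.x, x)
        x = res.x
        if np.abs(fun(x)[1]).max() <= cfg.force_tol or not moved:
            break
        if nit >= cfg.max_iter:
            break
    return x, nit


class ToyForceField:
    """The built-in classical backend.

    ``torsion_scale`` and ``lj_scale`` uniformly rescale the torsion
    amplitudes and LJ well depths; distinctly-labelled rescaled instances
    act as alternative intra/inter models in mixed-model partitions.
    """

    def __init__(self, label: str = "toy-ff", *, torsion_scale: float = 1.0,
                 lj_scale: float = 1.0, use_coulomb: bool = True):
        self.label = label
        self.torsion_scale = float(torsion_scale)
        self.lj_scale = float(lj_scale)
        self.use_coulomb = bool(use_coulomb)

    # ------------------------------------------------------------------
    # intramolecular terms
    # ------------------------------------------------------------------

    def _bonded_energy_grad(self, mol: Molecule, coords: np.ndarray):
        e = 0.0
        g = np.zeros_like(coords)

        for (i, j), (k, r0) in zip(mol.bonds, mol.bond_params):
            d = coords[i] - coords[j]
            r = np.linalg.norm(d)
            e += k * (r - r0) ** 2
            f = 2.0 * k * (r - r0) * d / r
            g[i] += f
            g[j] -= f

        for (i, j, k), (ka, th0) in zip(mol.angles, mol.angle_params):
            u = coords[i] - coords[j]
            v = coords[k] - coords[j]
            lu, lv = np.linalg.norm(u), np.linalg.norm(v)
            uh, vh = u / lu, v / lv
            c = np.clip(np.dot(uh, vh), -1.0, 1.0)
            s = np.sqrt(max(1.0 - c * c, 1e-12))
            theta = np.arccos(c)
            dEdt = 2.0 * ka * (theta - th0)
            dti = (c * uh - vh) / (lu * s)
            dtk = (c * vh - uh) / (lv * s)
            g[i] += dEdt * dti
            g[k] += dEdt * dtk
            g[j] -= dEdt * (dti + dtk)
            e += ka * (theta - th0) ** 2

        for (i, j, k, l), series in zip(mol.torsions, mol.torsion_params):
            b1 = coords[j] - coords[i]
            b2 = coords[k] - coords[j]
            b3 = coords[l] - coords[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            lb2 = np.linalg.norm(b2)
            phi = np.arctan2(np.dot(np.cross(n1, b2 / lb2), n2), np.dot(n1, n2))
            dEdphi = 0.0
            for (V, n, gamma) in series:
                V = V * self.torsion_scale
                e += V * (1.0 + np.cos(n * phi - gamma))
                dEdphi += -V * n * np.sin(n * phi - gamma)
            dpi = (lb2 / np.dot(n1, n1)) * n1
            dpl = -(lb2 / np.dot(n2, n2)) * n2
            p = np.dot(b1, b2) / lb2 ** 2
            q = np.dot(b3, b2) / lb2 ** 2
            dpj = -(1.0 + p) * dpi + q * dpl
            dpk = p * dpi - (1.0 + q) * dpl
            g[i] += dEdphi * dpi
            g[j] += dEdphi * dpj
            g[k] += dEdphi * dpk
            g[l] += dEdphi * dpl

        return e, g

    def _intra_nonbonded_energy_grad(self, mol: Molecule, coords: np.ndarray,
                                     cfg: ForceFieldConfig):
        """LJ + Coulomb between non-excluded intramolecular pairs (no cutoff)."""
        e = 0.0
        g = np.zeros_like(coords)
        scale = mol.nonbonded_scale
        n = mol.n_atoms
        ke = cfg.coulomb_constant if self.use_coulomb else 0.0
        for i in range(n):
            for j in range(i + 1, n):
                s = scale[i, j]
                if s == 0.0:
                    continue
                if s == 0.5:
                    s = cfg.one_four_scale
                d = coords[i] - coords[j]
                r = np.linalg.norm(d)
                sig = 0.5 * (mol.sigma[i] + mol.sigma[j])
                eps = np.sqrt(mol.epsilon[i] * mol.epsilon[j]) * self.lj_scale
                x6 = (sig / r) ** 6
                qq = ke * mol.charges[i] * mol.charges[j]
                e += s * (4.0 * eps * (x6 * x6 - x6) + qq / r)
                dEdr = s * (4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) / r - qq / r ** 2)
                f = dEdr * d / r
                g[i] += f
                g[j] -= f
        return e, g

    def molecule_energy_grad(self, mol: Molecule, coords: np.ndarray | None = None,
                             cfg: ForceFieldConfig | None = None):
        """Gas-phase energy and analytic gradient of one conformation."""
        cfg = cfg or ForceFieldConfig()
        coords = mol.coords if coords is None else np.asarray(coords, float)
        if coords.shape != (mol.n_atoms, 3):
            raise InputError(f"coords shape {coords.shape} != ({mol.n_atoms}, 3)")
        if not np.all(np.isfinite(coords)):
            raise InputError("non-finite coordinates")
        e1, g1 = self._bonded_energy_grad(mol, coords)
        e2, g2 = self._intra_nonbonded_energy_grad(mol, coords, cfg)
        return e1 + e2, g1 + g2

    def molecule_energy(self, mol: Molecule, coords: np.ndarray | None = None,
                        cfg: ForceFieldConfig | None = None) -> float:
        return self.molecule_energy_grad(mol, coords, cfg)[0]

    # ------------------------------------------------------------------
    # periodic intermolecular term
    # ------------------------------------------------------------------

    @staticmethod
    def _image_vectors(lattice: np.ndarray, coords_all: np.ndarray,
                       cutoff: float) -> np.ndarray:
        """Integer image vectors guaranteed to cover all pairs within cutoff."""
        inv = np.linalg.inv(lattice)
        frac = coords_all @ inv
        span = frac.max(axis=0) - frac.min(axis=0)
        vol = abs(np.linalg.det(lattice))
        widths = np.array([
            vol / np.linalg.norm(np.cross(lattice[(i + 1) % 3], lattice[(i + 2) % 3]))
            for i in range(3)
        ])
        nmax = np.ceil(cutoff / widths + span).astype(int)
        grids = np.meshgrid(*[np.arange(-n, n + 1) for n in nmax], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def intermolecular_energy(self, xtal: CrystalStructure,
                              cfg: ForceFieldConfig | None = None) -> float:
        """Total intermolecular lattice energy of the cell, per molecule."""
        cfg = cfg or ForceFieldConfig()
        e, _ = self._inter_energy_grad(xtal, cfg, want_grad=False)
        return e / xtal.z

    def _inter_energy_grad(self, xtal: CrystalStructure, cfg: ForceFieldConfig,
                           want_grad: bool = True):
        """Shifted-potential LJ+Coulomb direct lattice sum over images in cutoff.

        Returns the *total* intermolecular energy of the simulation cell and
        the gradient w.r.t. every (central-cell) atom.  Each unordered
        molecule-pair interaction is visited twice and halved.
        """
        rc = cfg.cutoff
        ke = cfg.coulomb_constant if self.use_coulomb else 0.0
        shifts = (self._image_vectors(xtal.lattice, xtal.all_coords(), rc)
                  @ xtal.lattice)
        zero_shift = np.all(shifts == 0.0, axis=1)
        mols = xtal.molecules
        e_tot = 0.0
        grads = [np.zeros((m.n_atoms, 3)) for m in mols]
        for a, ma in enumerate(mols):
            ra = ma.coords
            for b, mb in enumerate(mols):
                rb = mb.coords
                sig = 0.5 * (ma.sigma[:, None] + mb.sigma[None, :])
                eps = np.sqrt(ma.epsilon[:, None] * mb.epsilon[None, :]) * self.lj_scale
                qq = ke * ma.charges[:, None] * mb.charges[None, :]
                # displacement r_ai - (r_bj + shift): (Na, Nb, M, 3)
                disp = (ra[:, None, None, :] - rb[None, :, None, :]
                        - shifts[None, None, :, :])
                r = np.sqrt(np.einsum("ijkl,ijkl->ijk", disp, disp))
                mask = r < rc
                if a == b:
                    mask &= ~zero_shift[None, None, :]
                if not mask.any():
                    continue
                rm = r[mask]
                i_idx, j_idx, _ = np.nonzero(mask)
                sig_m = sig[i_idx, j_idx]
                eps_m = eps[i_idx, j_idx]
                qq_m = qq[i_idx, j_idx]
                x6 = (sig_m / rm) ** 6
                x6c = (sig_m / rc) ** 6
                e_pair = (4.0 * eps_m * (x6 * x6 - x6)
                          - 4.0 * eps_m * (x6c * x6c - x6c)
                          + qq_m * (1.0 / rm - 1.0 / rc))
                e_tot += 0.5 * e_pair.sum()
                if want_grad:
                    dEdr = (4.0 * eps_m * (-12.0 * x6 * x6 + 6.0 * x6) / rm
                            - qq_m / rm ** 2)
                    f = (0.5 * dEdr / rm)[:, None] * disp[mask]
                    np.add.at(grads[a], i_idx, f)
                    np.add.at(grads[b], j_idx, -f)
        return e_tot, grads

    def crystal_energy_per_molecule(self, xtal: CrystalStructure,
                                    cfg: ForceFieldConfig | None = None) -> float:
        """(Σ intramolecular + total intermolecular) / Z."""
        cfg = cfg or ForceFieldConfig()
        e_intra = sum(self.molecule_energy(m, cfg=cfg) for m in xtal.molecules)
        e_inter, _ = self._inter_energy_grad(xtal, cfg, want_grad=False)
        return (e_intra + e_inter) / xtal.z

    def _crystal_energy_grad_flat(self, xtal: CrystalStructure,
                                  cfg: ForceFieldConfig):
        """Total cell energy and flat gradient over all molecules' atoms."""
        e_inter, g_inter = self._inter_energy_grad(xtal, cfg)
        e = e_inter
        gs = []
        for m, gi in zip(xtal.molecules, g_inter):
            em, gm = self.molecule_energy_grad(m, cfg=cfg)
            e += em
            gs.append(gm + gi)
        return e, np.concatenate(gs, axis=0)

    # ------------------------------------------------------------------
    # optimizers
    # ------------------------------------------------------------------

    def optimize_molecule(self, mol: Molecule, coords: np.ndarray | None = None,
                          cfg: ForceFieldConfig | None = None) -> OptimizationResult:
        """Relax a conformation to the nearest gas-phase local minimum."""
        cfg = cfg or ForceFieldConfig()
        x0 = (mol.coords if coords is None else np.asarray(coords, float)).ravel()
        if not np.all(np.isfinite(x0)):
            raise InputError("non-finite coordinates")
        trace: list[float] = []

        def fun(x):
            e, g = self.molecule_energy_grad(mol, x.reshape(-1, 3), cfg)
            return e, g.ravel()

        def cb(xk):
            trace.append(fun(xk)[0])

        x, nit = _lbfgs_until_force_tol(fun, x0, cfg, cb)
        coords_out = x.reshape(-1, 3)
        e, g = self.molecule_energy_grad(mol, coords_out, cfg)
        max_force = float(np.abs(g).max()) if g.size else 0.0
        return OptimizationResult(
            coords=coords_out, energy=float(e), trace=[fun(x0)[0]] + trace,
            converged=max_force <= cfg.force_tol,
            n_iter=nit, max_force=max_force,
        )

    def optimize_crystal(self, xtal: CrystalStructure,
                         cfg: ForceFieldConfig | None = None
                         ) -> tuple[CrystalStructure, OptimizationResult]:
        """Relax atomic positions (and optionally the cell, isotropically).

        In ``isotropic`` mode one extra degree of freedom scales the lattice
        vectors and the molecular centroids together while the internal
        geometry translates rigidly with its centroid.
        """
        cfg = cfg or ForceFieldConfig()
        x0 = xtal.all_coords().ravel()
        n_counts = [m.n_atoms for m in xtal.molecules]
        trace: list[float] = []

        if cfg.cell_mode == "fixed":
            def fun(x):
                xt = xtal.with_all_coords(x.reshape(-1, 3), validate=False)
                e, g = self._crystal_energy_grad_flat(xt, cfg)
                return e, g.ravel()
            x_init = x0
        else:
            def transform(x):
                s = np.exp(x[-1])
                coords = x[:-1].reshape(-1, 3)
                out, start = [], 0
                for na in n_counts:
                    block = coords[start:start + na]
                    c = block.mean(axis=0)
                    out.append(block - c + s * c)
                    start += na
                return np.concatenate(out), s

            def fun(x):
                coords_t, s = transform(x)
                xt = CrystalStructure(
                    s * xtal.lattice,
                    xtal.with_all_coords(coords_t, validate=False).molecules,
                    xtal.structure_id, xtal.compound_id,
                    validate_on_init=False)
                e, g = self._crystal_energy_grad_flat(xt, cfg)
                # chain rule back through the centroid transform
                gx = np.zeros(len(x))
                start = 0
                ds_terms = 0.0
                for na in n_counts:
                    gb = g[start:start + na]
                    block = x[:-1].reshape(-1, 3)[start:start + na]
                    c = block.mean(axis=0)
                    gx[3 * start:3 * (start + na)] = (
                        gb + (s - 1.0) / na * gb.sum(axis=0)[None, :]
                    ).ravel()
                    ds_terms += float(np.dot(gb.sum(axis=0), c))
                    start += na
                # dE/d(ln s): centroid motion term plus lattice scaling term
                eps_s = 1e-6
                xt2 = CrystalStructure((s * (1 + eps_s)) * xtal.lattice,
                                       xt.molecules, xtal.structure_id,
                                       xtal.compound_id,
                                       validate_on_init=False)
                e2, _ = self._inter_energy_grad(xt2, cfg, want_grad=False)
                e1, _ = self._inter_energy_grad(xt, cfg, want_grad=False)
                gx[-1] = s * ds_terms + (e2 - e1) / eps_s
                return e, gx
            x_init = np.concatenate([x0, [0.0]])

        def cb(xk):
            trace.append(fun(xk)[0])

        x, nit = _lbfgs_until_force_tol(fun, x_init, cfg, cb)
        if cfg.cell_mode == "fixed":
            coords_out, s = x.reshape(-1, 3), 1.0
            new = xtal.with_all_coords(coords_out)
        else:
            coords_t, s = transform(x)
            new = CrystalStructure(s * xtal.lattice,
                                   xtal.with_all_coords(
                                       coords_t, validate=False).molecules,
                                   xtal.structure_id, xtal.compound_id)
            new.validate()
        e, g = self._crystal_energy_grad_flat(new, cfg)
        max_force = float(np.abs(g).max())
        return new, OptimizationResult(
            coords=new.all_coords(), energy=float(e) / xtal.z,
            trace=[fun(x_init)[0]] + trace,
            converged=max_force <= cfg.force_tol,
            n_iter=nit, max_force=max_force, scale=s,
        )

    # ------------------------------------------------------------------

    def with_label(self, label: str, **changes) -> "ToyForceField":
        """Relabelled (optionally rescaled) copy of this backend."""
        return ToyForceField(label,
                             torsion_scale=changes.get("torsion_scale",
                                                       self.torsion_scale),
                             lj_scale=changes.get("lj_scale", self.lj_scale),
                             use_coulomb=changes.get("use_coulomb",
                                                     self.use_coulomb))
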