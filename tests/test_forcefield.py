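"""Toy force field: closed-form checks, oracles, optimizer contracts."""

import numpy as np
import pytest

from lattpart.errors import InputError
from lattpart.forcefield import ForceFieldConfig, ToyForceField
from lattpart.model import (CrystalStructure, Molecule, make_supercell,
                            set_torsions)
from lattpart.synthetic import make_chain_molecule


def diatomic(r: float, k: float = 1000.0, r0: float = 1.53) -> Molecule:
    return Molecule(elements=("C", "C"),
                    coords=np.array([[0.0, 0, 0], [r, 0, 0]]),
                    charges=np.zeros(2), bonds=((0, 1),),
                    bond_params=((k, r0),), epsilon=np.zeros(2))


class TestMoleculeEnergy:
    def test_diatomic_at_minimum_is_zero(self, ff):
        assert ff.molecule_energy(diatomic(1.53)) == pytest.approx(0.0)

    def test_diatomic_harmonic(self, ff):
        assert ff.molecule_energy(diatomic(1.63)) == pytest.approx(
            1000.0 * 0.1 ** 2)

    @pytest.mark.parametrize("phi,expected", [(0.0, 10.0), (180.0, 0.0),
                                              (60.0, 0.0), (120.0, 10.0)])
    def test_threefold_torsion_closed_form(self, ff, phi, expected):
        """V3(1 + cos 3φ) with V3 = 5: maxima 10 at 0/±120, minima 0."""
        mol = make_chain_molecule(4, torsion_terms=((5.0, 3, 0.0),),
                                  epsilon=0.0)
        coords = set_torsions(mol, [phi])
        assert ff.molecule_energy(mol, coords) == pytest.approx(expected,
                                                                abs=1e-9)

    def test_lj_pair_minimum_depth(self, ff):
        """Two nonbonded sites at 2^(1/6)σ sit at exactly −ε."""
        sigma, eps = 3.4, 0.7
        r = 2.0 ** (1.0 / 6.0) * sigma
        # 4-atom chain, zero force constants: only the 1-4 pair interacts
        mol = Molecule(
            elements=("C",) * 4,
            coords=np.array([[0, 0, 0], [r / 3, 0, 0], [2 * r / 3, 0, 0],
                             [r, 0, 0]]),
            charges=np.zeros(4), bonds=((0, 1), (1, 2), (2, 3)),
            bond_params=((0.0, r / 3),) * 3,
            sigma=np.full(4, sigma), epsilon=np.array([eps, 0, 0, eps]),
        )
        # 1-4 scale is 0.5
        assert ff.molecule_energy(mol) == pytest.approx(-0.5 * eps)

    def test_mismatched_coords_rejected(self, ff, butane):
        with pytest.raises(InputError):
            ff.molecule_energy(butane, np.zeros((3, 3)))
        with pytest.raises(InputError):
            ff.molecule_energy(butane, np.full((4, 3), np.nan))

    def test_analytic_gradient_matches_finite_difference(self, ff):
        mol = make_chain_molecule(6, charge=0.1)
        rng = np.random.default_rng(11)
        coords = mol.coords + rng.normal(0, 0.15, mol.coords.shape)
        e, g = ff.molecule_energy_grad(mol, coords)
        h = 1e-6
        for i in range(mol.n_atoms):
            for k in range(3):
                cp, cm = coords.copy(), coords.copy()
                cp[i, k] += h
                cm[i, k] -= h
                num = (ff.molecule_energy(mol, cp)
                       - ff.molecule_energy(mol, cm)) / (2 * h)
                assert g[i, k] == pytest.approx(num, abs=5e-5)


def brute_force_lattice_sum(xtal, cfg, ff):
    """Independent direct sum: explicit loops over all images in cutoff."""
    rc = cfg.cutoff
    lat = xtal.lattice
    nmax = [int(np.ceil(rc / np.linalg.norm(lat[i]))) + 2 for i in range(3)]
    e = 0.0
    mols = xtal.molecules
    for a, ma in enumerate(mols):
        for b, mb in enumerate(mols):
            for na in range(-nmax[0], nmax[0] + 1):
                for nb in range(-nmax[1], nmax[1] + 1):
                    for nc in range(-nmax[2], nmax[2] + 1):
                        if a == b and na == nb == nc == 0:
                            continue
                        shift = na * lat[0] + nb * lat[1] + nc * lat[2]
                        for i in range(ma.n_atoms):
                            for j in range(mb.n_atoms):
                                d = ma.coords[i] - mb.coords[j] - shift
                                r = np.linalg.norm(d)
                                if r >= rc:
                                    continue
                                sig = 0.5 * (ma.sigma[i] + mb.sigma[j])
                                eps = np.sqrt(ma.epsilon[i] * mb.epsilon[j])
                                qq = (cfg.coulomb_constant * ma.charges[i]
                                      * mb.charges[j])
                                for rr, sgn in ((r, 1.0), (rc, -1.0)):
                                    x6 = (sig / rr) ** 6
                                    e += sgn * 0.5 * (4 * eps * (x6 * x6 - x6)
                                                      + qq / rr)
    return e / xtal.z


class TestPeriodicEnergy:
    def test_isolated_molecule_equals_gas_energy(self, ff, butane):
        """One molecule in a huge cell: no image within cutoff."""
        x = CrystalStructure(np.eye(3) * 100.0, [butane], "iso", "c")
        cfg = ForceFieldConfig(cutoff=12.0)
        assert ff.crystal_energy_per_molecule(x, cfg) == pytest.approx(
            ff.molecule_energy(butane), abs=1e-12)

    def test_lj_simple_cubic_matches_direct_sum_oracle(self, ff, lj_sc):
        cfg = ForceFieldConfig(cutoff=12.0)
        mine = ff.crystal_energy_per_molecule(lj_sc, cfg)
        oracle = brute_force_lattice_sum(lj_sc, cfg, ff)
        assert mine == pytest.approx(oracle, abs=1e-10)
        assert mine < 0

    def test_molecular_crystal_matches_direct_sum_oracle(self, ff, cfg):
        mol = make_chain_molecule(4, charge=0.1)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        assert ff.crystal_energy_per_molecule(x, cfg) == pytest.approx(
            brute_force_lattice_sum(x, cfg, ff) + ff.molecule_energy(mol),
            abs=1e-10)

    @pytest.mark.parametrize("repeat", [(2, 1, 1), (2, 2, 2), (1, 3, 2)])
    def test_supercell_invariance(self, ff, cfg, repeat):
        mol = make_chain_molecule(4, charge=0.05)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        e1 = ff.crystal_energy_per_molecule(x, cfg)
        e2 = ff.crystal_energy_per_molecule(make_supercell(x, repeat), cfg)
        assert e2 == pytest.approx(e1, abs=1e-8)

    def test_lattice_translation_invariance(self, ff, cfg):
        mol = make_chain_molecule(4)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        e1 = ff.crystal_energy_per_molecule(x, cfg)
        for vec in (x.lattice[0], -x.lattice[2], x.lattice[1] + x.lattice[2]):
            shifted = CrystalStructure(
                x.lattice, [mol.with_coords(mol.coords + vec)], "x", "c")
            assert ff.crystal_energy_per_molecule(shifted, cfg) == \
                pytest.approx(e1, abs=1e-8)


class TestOptimizers:
    def test_molecule_opt_from_minimum_is_stationary(self, ff):
        mol = make_chain_molecule(4, epsilon=0.0)
        res0 = ff.optimize_molecule(mol)
        res = ff.optimize_molecule(mol, res0.coords)
        assert res.converged
        assert res.energy == pytest.approx(res0.energy, abs=1e-9)
        assert np.allclose(res.coords, res0.coords, atol=1e-4)

    def test_torsion_relaxes_to_anti_minimum(self, ff, butane):
        """Started at φ=150°, the chain must land in the anti basin, and
        the energy must match a dense 1-D torsion scan oracle."""
        start = set_torsions(butane, [150.0])
        res = ff.optimize_molecule(butane, start)
        assert res.converged
        phi = butane.torsion_values(res.coords)[0]
        assert abs(abs(phi) - 180.0) < 1.0
        # oracle: dense scan with local optimization at each grid point
        scan = []
        for phi0 in np.arange(100.0, 261.0, 5.0):
            r = ff.optimize_molecule(butane, set_torsions(butane, [phi0]))
            scan.append(r.energy)
        assert res.energy == pytest.approx(min(scan), abs=1e-6)

    def test_trace_monotone_and_force_tolerance(self, ff, hexane, cfg):
        start = set_torsions(hexane, [90.0, 140.0, -100.0])
        res = ff.optimize_molecule(hexane, start, cfg)
        assert res.converged
        assert res.max_force <= cfg.force_tol
        assert all(a >= b - 1e-8 for a, b in zip(res.trace, res.trace[1:]))

    def test_relaxed_crystal_is_unchanged(self, ff, cfg):
        mol = make_chain_molecule(4)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        x1, r1 = ff.optimize_crystal(x, cfg)
        x2, r2 = ff.optimize_crystal(x1, cfg)
        assert r2.energy == pytest.approx(r1.energy, abs=1e-8)
        assert np.allclose(x2.all_coords(), x1.all_coords(), atol=1e-3)

    def test_displaced_molecule_recovers_packing(self, ff, cfg):
        """Z = 2 crystal with one molecule nudged 0.3 Å off its site."""
        mol = make_chain_molecule(4)
        mol2 = mol.with_coords(mol.coords + np.array([0.0, 4.6, 0.0]))
        x = CrystalStructure(np.diag([8.0, 9.2, 5.2]), [mol, mol2], "x", "c")
        x_ref, r_ref = ff.optimize_crystal(x, cfg)
        displaced = x_ref.all_coords().copy()
        displaced[mol.n_atoms:] += np.array([0.3, 0.0, 0.0])
        x2, r2 = ff.optimize_crystal(x_ref.with_all_coords(displaced,
                                                           validate=False),
                                     cfg)
        assert r2.converged
        assert r2.energy == pytest.approx(r_ref.energy, abs=1e-6)

    def test_crystal_relaxation_never_raises_energy(self, ff, cfg):
        mol = make_chain_molecule(5, charge=0.05)
        x = CrystalStructure(np.diag([9.3, 4.8, 5.4]), [mol], "x", "c")
        _, res = ff.optimize_crystal(x, cfg)
        assert res.trace[-1] <= res.trace[0] + 1e-10
        assert all(a >= b - 1e-8 for a, b in zip(res.trace, res.trace[1:]))

    def test_isotropic_cell_relaxation_shrinks_loose_cell(self, ff):
        mol = make_chain_molecule(4)
        x = CrystalStructure(np.diag([9.0, 5.2, 5.6]), [mol], "x", "c")
        cfg = ForceFieldConfig(cutoff=9.0, cell_mode="isotropic")
        x2, res = ff.optimize_crystal(x, cfg)
        assert res.converged
        assert res.scale < 1.0
        fixed = ff.optimize_crystal(x, ForceFieldConfig(cutoff=9.0))[1]
        assert res.energy <= fixed.energy + 1e-9
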