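"""Lattice-energy partition: ledger arithmetic, components, pipeline."""

import numpy as np
import pytest

from lattpart.errors import InputError, PartitionError
from lattpart.forcefield import ForceFieldConfig, ToyForceField
from lattpart.model import CrystalStructure, set_torsions
from lattpart.partition import (EnergyPartition, assemble_partition,
                                compute_adjustment, compute_change_global,
                                compute_inter, extract_crystal_conformation,
                                run_partition_pipeline)
from lattpart.synthetic import gen_toy_polymorph_pair, make_chain_molecule


class TestAssemble:
    def test_worked_example_alpha_form(self):
        """E_inter −146.9 with a ~15 kJ/mol penalty gives E_latt ≈ −132."""
        p = assemble_partition("ACBNZA01", "o-acetamidobenzamide",
                               E_inter=-146.9, E_adjustment=15.0)
        assert p.E_latt_global == pytest.approx(-131.9)
        assert round(p.E_latt_global) == -132

    def test_worked_example_beta_form(self):
        """E_inter −205.3 with the 70.9 kJ/mol penalty: E_latt −134.4,
        2.5 kJ/mol below the alpha form."""
        p = assemble_partition("ACBNZA02", "o-acetamidobenzamide",
                               E_inter=-205.3, E_adjustment=70.9)
        assert p.E_latt_global == pytest.approx(-134.4)
        assert p.E_latt_global - (-131.9) == pytest.approx(-2.5)

    def test_all_zero_ledger(self):
        p = assemble_partition("z", "z", 0.0, 0.0, 0.0)
        assert p.E_intra_global == 0.0 and p.E_latt_global == 0.0

    def test_additivity_exact_by_construction(self):
        p = EnergyPartition("s", "c", -123.456, 7.89, 1.23)
        assert p.E_latt_global == p.E_inter + p.E_intra_global
        assert p.E_intra_global == p.E_adjustment + p.dE_change_global

    @pytest.mark.parametrize("adj,chg", [(-0.5, 0.0), (0.0, -0.5)])
    def test_negative_penalties_rejected(self, adj, chg):
        with pytest.raises(PartitionError):
            assemble_partition("s", "c", -100.0, adj, chg)

    def test_noise_floor_tolerated(self):
        p = assemble_partition("s", "c", -100.0, -1e-7, -1e-8)
        assert p.E_intra_global < 0  # tiny optimizer noise is allowed


class TestComponents:
    def test_inter_zero_beyond_cutoff(self, ff, butane):
        x = CrystalStructure(np.eye(3) * 200.0, [butane], "iso", "c")
        cfg = ForceFieldConfig(cutoff=12.0)
        assert compute_inter(x, ff, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_inter_matches_direct_intermolecular_sum(self, ff, cfg):
        mol = make_chain_molecule(4, charge=0.1)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        assert compute_inter(x, ff, cfg) == pytest.approx(
            ff.intermolecular_energy(x, cfg), abs=1e-10)
        assert compute_inter(x, ff, cfg) < 0

    def test_inter_invariant_to_lattice_translation(self, ff, cfg):
        mol = make_chain_molecule(4)
        x1 = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        x2 = CrystalStructure(x1.lattice,
                              [mol.with_coords(mol.coords + x1.lattice[1])],
                              "x", "c")
        assert compute_inter(x2, ff, cfg) == pytest.approx(
            compute_inter(x1, ff, cfg), abs=1e-9)

    def test_extracted_conformation_energy_matches_crystal_intra(self, ff, cfg):
        mol = make_chain_molecule(4)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "x", "c")
        x_opt, _ = ff.optimize_crystal(x, cfg)
        conf = extract_crystal_conformation(x_opt, 0)
        intra_in_crystal = (ff.crystal_energy_per_molecule(x_opt, cfg)
                            - ff.intermolecular_energy(x_opt, cfg))
        assert ff.molecule_energy(mol, conf) == pytest.approx(
            intra_in_crystal, abs=1e-9)

    def test_extraction_rewraps_split_molecule(self, ff):
        mol = make_chain_molecule(4)
        lattice = np.diag([8.0, 4.6, 5.2])
        wrapped = mol.coords.copy()
        wrapped[2:] += lattice[0]      # half the chain one image over
        x = CrystalStructure(lattice, [mol.with_coords(wrapped)], "x", "c",
                             validate_on_init=False)
        conf = extract_crystal_conformation(x, 0)
        for (i, j) in mol.bonds:
            assert np.linalg.norm(conf[i] - conf[j]) < 2.0

    def test_extraction_index_range(self, ff, butane):
        x = CrystalStructure(np.eye(3) * 20.0, [butane], "x", "c")
        with pytest.raises(InputError):
            extract_crystal_conformation(x, 1)

    def test_adjustment_zero_at_local_minimum(self, ff, cfg, butane):
        res = ff.optimize_molecule(butane)
        adj, _ = compute_adjustment(butane, res.coords, ff, cfg)
        assert adj == pytest.approx(0.0, abs=1e-6)

    def test_adjustment_matches_analytic_torsion_distortion(self, ff, cfg):
        """20° twist from the anti minimum of a pure-torsion chain: the
        penalty is the closed-form cosine-series difference."""
        mol = make_chain_molecule(4, epsilon=0.0)
        distorted = set_torsions(mol, [160.0])
        adj, opt = compute_adjustment(mol, distorted, ff, cfg)

        def series(phi_deg):
            phi = np.radians(phi_deg)
            return 4 * (1 + np.cos(phi)) + 6 * (1 + np.cos(3 * phi))

        assert adj == pytest.approx(series(160.0) - series(180.0), abs=1e-6)
        assert adj >= -1e-6

    def test_change_global_sign_contract(self):
        assert compute_change_global(5.0, 2.0) == pytest.approx(3.0)
        assert compute_change_global(2.0, 2.0) == 0.0
        with pytest.raises(PartitionError):
            compute_change_global(2.0, 2.1)


class TestPipeline:
    def test_rigid_crystal_has_pure_inter_partition(self, cfg):
        mol = make_chain_molecule(4, n_rotatable=0)
        x = CrystalStructure(np.diag([8.0, 4.6, 5.2]), [mol], "rigid", "c")
        run = run_partition_pipeline(x, cfg=cfg)
        p = run.partition
        assert p.E_adjustment == pytest.approx(0.0, abs=1e-3)
        assert p.dE_change_global == pytest.approx(0.0, abs=1e-3)
        assert p.E_latt_global == pytest.approx(p.E_inter, abs=2e-3)

    def test_toy_polymorph_pair_shows_conformational_tradeoff(self, cfg):
        """The strained-dense form must pay a larger intramolecular
        penalty AND gain more intermolecular stabilization."""
        a, b = gen_toy_polymorph_pair()
        pa = run_partition_pipeline(a, cfg=cfg).partition
        pb = run_partition_pipeline(b, cfg=cfg).partition
        assert pb.E_intra_global > pa.E_intra_global
        assert pb.E_inter < pa.E_inter

    def test_pipeline_is_deterministic(self, cfg):
        a, _ = gen_toy_polymorph_pair()
        p1 = run_partition_pipeline(a, cfg=cfg).partition
        p2 = run_partition_pipeline(a, cfg=cfg).partition
        assert p1 == p2   # bitwise-identical ledger

    def test_backend_swap_changes_intra_not_inter(self, cfg):
        """Mixed-model partitions: the intra backend must not touch
        E_inter (separability of the model grid)."""
        a, b = gen_toy_polymorph_pair()
        soft = ToyForceField("toy-soft", torsion_scale=0.5)
        rb = run_partition_pipeline(b, cfg=cfg).partition
        rb_soft = run_partition_pipeline(b, cfg=cfg,
                                         backend_intra=soft).partition
        assert rb_soft.E_inter == pytest.approx(rb.E_inter, abs=1e-9)
        assert rb_soft.dE_change_global != pytest.approx(
            rb.dE_change_global, abs=1e-3)
        assert rb_soft.intra_model == "toy-soft"
        assert rb_soft.inter_model == "toy-ff"

    def test_backend_energies_are_consistent(self, cfg):
        a, _ = gen_toy_polymorph_pair()
        run = run_partition_pipeline(a, cfg=cfg)
        be = run.backend_energies
        be.validate()
        assert be.gas_opt <= be.gas_sp + 1e-9
        assert be.gas_global_min <= be.gas_opt + 1e-9
        assert run.partition.E_inter == pytest.approx(
            be.crystal_per_molecule - be.gas_sp, abs=1e-9)

    def test_z2_crystal_averages_intra_terms(self, cfg, ff):
        mol = make_chain_molecule(4)
        mol2 = mol.with_coords(mol.coords + np.array([0.0, 4.6, 0.0]))
        x = CrystalStructure(np.diag([8.0, 9.2, 5.2]), [mol, mol2], "z2", "c")
        run = run_partition_pipeline(x, cfg=cfg)
        m0 = run.intermediates["molecule_0"]
        m1 = run.intermediates["molecule_1"]
        assert run.partition.E_adjustment == pytest.approx(
            0.5 * (m0["adjustment"] + m1["adjustment"]), abs=1e-12)
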