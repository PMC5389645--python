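"""Go-model construction: PDB parsing, contact maps, energies and forces."""

import numpy as np
import pytest

from smfskit.gomodel import (
    CGStructure,
    ContactMap,
    GoHamiltonian,
    build_contact_map,
    build_hamiltonian,
    energy_forces,
    parse_structure,
    write_contact_map,
)
from smfskit.synthetic import ToyStructureConfig, generate_toy_structure

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA AGLY A   2       4.600   0.000   0.000  0.40  0.00           C
ATOM      4  CA BGLY A   2       4.500   0.100   0.000  0.60  0.00           C
ATOM      5  CA  SER A   3       4.500   3.700   0.100  1.00  0.00           C
ATOM      6  CA  LEU B   1       0.000  50.000   0.000  1.00  0.00           C
ATOM      7  CA  LEU B   2       3.600  50.000   0.000  1.00  0.00           C
END
"""


class TestParseStructure:
    def test_minimal_fixture_with_altloc(self):
        st = parse_structure(THREE_RESIDUE_PDB, chain="A")
        assert st.n_residues == 3
        # highest-occupancy altloc (B, occ 0.60) wins for residue 2
        np.testing.assert_allclose(st.coords_A[1], [4.5, 0.1, 0.0])
        d12 = np.linalg.norm(st.coords_A[1] - st.coords_A[0])
        assert d12 == pytest.approx(np.sqrt(3.5**2 + 0.1**2), abs=1e-6)

    def test_chain_selection(self):
        st = parse_structure(THREE_RESIDUE_PDB, chain="B")
        assert st.n_residues == 2
        assert st.chain_id == "B"

    def test_missing_chain_rejected(self):
        with pytest.raises(ValueError):
            parse_structure(THREE_RESIDUE_PDB, chain="Z")

    def test_toy_structure_round_trip(self):
        structure, pdb_text = generate_toy_structure(ToyStructureConfig())
        back = parse_structure(pdb_text)
        np.testing.assert_allclose(back.coords_A, structure.coords_A, atol=1e-3)

    def test_broken_backbone_reports_gap(self):
        coords = np.array([[0, 0, 0], [3.6, 0, 0], [13.6, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="gap"):
            CGStructure(coords_A=coords)


class TestContactMap:
    def test_extended_chain_has_no_contacts(self):
        n = 20
        coords = np.column_stack([np.arange(n) * 3.6, np.zeros(n), np.zeros(n)])
        st = CGStructure(coords_A=coords)
        assert len(build_contact_map(st, method="calpha")) == 0

    def test_matches_brute_force_on_toy(self):
        structure, _ = generate_toy_structure(ToyStructureConfig())
        cmap = build_contact_map(structure, method="calpha", cutoff_A=8.0)
        x = structure.coords_A
        brute = {
            (i + 1, j + 1)
            for i in range(structure.n_residues)
            for j in range(i + 3, structure.n_residues)
            if np.linalg.norm(x[i] - x[j]) <= 8.0
        }
        assert {(i, j) for i, j, _ in cmap.pairs} == brute

    def test_heavy_atom_method_requires_heavy_atoms(self):
        structure, _ = generate_toy_structure(ToyStructureConfig())
        with pytest.raises(ValueError):
            build_contact_map(structure, method="heavy_atom")

    def test_pairs_validated(self):
        with pytest.raises(ValueError):
            ContactMap(pairs=[(3, 4, 5.0)], method="calpha", cutoff_A=8.0)
        with pytest.raises(ValueError):
            ContactMap(pairs=[(1, 5, 5.0), (1, 5, 5.0)], method="calpha", cutoff_A=8.0)

    def test_export(self, tmp_path):
        structure, _ = generate_toy_structure(ToyStructureConfig())
        cmap = build_contact_map(structure, method="calpha")
        path = tmp_path / "contacts.tsv"
        write_contact_map(cmap, path)
        rows = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == len(cmap)


class TestEnergyForces:
    def test_native_contacts_contribute_minus_epsilon(self, toy_domain, toy_hamiltonian):
        structure, _ = toy_domain
        ham = toy_hamiltonian
        e, _ = energy_forces(structure.coords_A, ham)
        n_contacts = len(ham.contact_r0)
        # bonded terms vanish at native; repulsion adds a small positive tail
        assert e == pytest.approx(-n_contacts, abs=0.05)

    def test_stretched_contact_energy(self):
        # an isolated native pair stretched to twice its rest distance
        r = 2.0
        e = (1 / r) ** 12 - 2 * (1 / r) ** 6
        assert e == pytest.approx(-0.03101, abs=1e-5)
        coords = np.array([[0, 0, 0], [10.0, 0, 0]], dtype=float)
        ham = GoHamiltonian(
            n_beads=2,
            bond_idx=np.empty((0, 2), dtype=np.int64), bond_b0=np.empty(0), k_bond=0.0,
            angle_idx=np.empty((0, 3), dtype=np.int64), angle_theta0=np.empty(0),
            k_angle=0.0,
            dihedral_idx=np.empty((0, 4), dtype=np.int64), dihedral_phi0=np.empty(0),
            k_dihedral_1=0.0, k_dihedral_3=0.0,
            contact_idx=np.array([[0, 1]], dtype=np.int64),
            contact_r0=np.array([5.0]), contact_eps=np.array([1.0]),
            repulsion_idx=np.empty((0, 2), dtype=np.int64), r_repulsive_A=4.0,
        )
        energy, _ = energy_forces(coords, ham)
        assert energy == pytest.approx(-0.03101, abs=1e-5)

    def test_forces_match_finite_differences(self, toy_domain, toy_hamiltonian):
        structure, _ = toy_domain
        rng = np.random.default_rng(0)
        x = structure.coords_A + rng.normal(0, 0.3, structure.coords_A.shape)
        _, forces = energy_forces(x, toy_hamiltonian)
        h = 1e-6
        for i in range(structure.n_residues):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                g = (
                    energy_forces(xp, toy_hamiltonian)[0]
                    - energy_forces(xm, toy_hamiltonian)[0]
                ) / (2 * h)
                assert abs(-g - forces[i, d]) < 1e-5

    def test_rigid_motion_invariance_and_zero_net_force(
        self, toy_domain, toy_hamiltonian
    ):
        from scipy.spatial.transform import Rotation

        structure, _ = toy_domain
        rng = np.random.default_rng(5)
        x = structure.coords_A + rng.normal(0, 0.2, structure.coords_A.shape)
        e0, f0 = energy_forces(x, toy_hamiltonian)
        for k in range(3):
            R = Rotation.random(random_state=k).as_matrix()
            shift = rng.normal(0, 10, 3)
            e1, _ = energy_forces(x @ R.T + shift, toy_hamiltonian)
            assert abs(e1 - e0) < 1e-9 * max(abs(e0), 1.0)
        assert np.abs(f0.sum(axis=0)).max() < 1e-9

    def test_native_state_is_local_minimum(self, toy_domain, toy_hamiltonian):
        from scipy import optimize

        structure, _ = toy_domain
        x0 = structure.coords_A

        def fun(flat):
            e, f = energy_forces(flat.reshape(-1, 3), toy_hamiltonian)
            return e, -f.ravel()

        res = optimize.minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                                options={"maxiter": 500})
        moved = res.x.reshape(-1, 3) - x0
        rmsd = float(np.sqrt((moved**2).sum(axis=1).mean()))
        assert rmsd < 0.3

    def test_overlapping_beads_rejected(self, toy_domain, toy_hamiltonian):
        structure, _ = toy_domain
        x = structure.coords_A.copy()
        x[10] = x[20] + 1e-3  # |i-j| >= 3, so the pair is repulsive
        with pytest.raises(ValueError):
            energy_forces(x, toy_hamiltonian)


def test_domain_scaled_contact_epsilon():
    cfg = ToyStructureConfig(n_domains=2, residues_per_domain=16, strand_length=5)
    structure, _ = generate_toy_structure(cfg)
    cmap = build_contact_map(structure, method="calpha")
    ham = build_hamiltonian(structure, cmap, contact_eps_scale={"SD1": 0.5})
    a, b = structure.domain_ranges["SD1"]
    for (i, j, _), eps in zip(cmap.pairs, ham.contact_eps):
        if a <= i <= b and a <= j <= b:
            assert eps == 0.5
        else:
            assert eps == 1.0
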