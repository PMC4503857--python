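"""Bond/hydrogen deduction, splitting, copying, SSSR, supercells."""

import itertools
import math

import numpy as np
import pytest

from molcanvas import fixtures as fx
from molcanvas.elements import lookup_element, valence_for
from molcanvas.errors import InvalidCellError
from molcanvas.informatics import (MIN_BOND_DISTANCE, UnitCell,
                                   build_supercell, copy_molecule,
                                   deduce_covalent_bonds,
                                   deduce_implicit_hydrogens,
                                   perceive_rings_sssr, split_disconnected)
from molcanvas.model import Atom, Molecule


def brute_force_bonds(mol, tol=1.1):
    """Independent pairwise-distance oracle for bond deduction."""
    pairs = set()
    for i, j in itertools.combinations(range(len(mol.atoms)), 2):
        a, b = mol.atoms[i], mol.atoms[j]
        d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
        rsum = (lookup_element(a.label).covalent_radius
                + lookup_element(b.label).covalent_radius)
        if MIN_BOND_DISTANCE <= d <= tol * rsum:
            pairs.add((i, j))
    return pairs


class TestBondDeduction:
    @pytest.mark.parametrize("factory,expected_bonds", [
        (fx.water_xyz, 2), (fx.methane_xyz, 4), (fx.ethane_xyz, 7)])
    def test_matches_pairwise_oracle(self, factory, expected_bonds):
        mol = factory()
        oracle = brute_force_bonds(mol)
        deduce_covalent_bonds(mol)
        assert {b.pair() for b in mol.bonds} == oracle
        assert len(mol.bonds) == expected_bonds

    def test_no_h_h_bond_in_methane(self):
        mol = deduce_covalent_bonds(fx.methane_xyz())
        for b in mol.bonds:
            assert "C" in (mol.atoms[b.begin].label, mol.atoms[b.end].label)

    def test_far_atoms_unbonded(self):
        mol = Molecule()
        mol.add_atom(label="C", x=0, y=0, z=0)
        mol.add_atom(label="C", x=5.0, y=0, z=0)
        assert len(deduce_covalent_bonds(mol).bonds) == 0

    def test_overlapping_atoms_guarded(self):
        mol = Molecule()
        mol.add_atom(label="C")
        mol.add_atom(label="C", x=0.1)
        assert len(deduce_covalent_bonds(mol).bonds) == 0

    def test_idempotent(self, water3d):
        deduce_covalent_bonds(water3d)
        once = {b.pair() for b in water3d.bonds}
        deduce_covalent_bonds(water3d)
        assert {b.pair() for b in water3d.bonds} == once

    def test_atom_order_invariant(self, rng):
        base = fx.ethane_xyz()
        perm = rng.permutation(len(base.atoms))
        shuffled = Molecule()
        for i in perm:
            shuffled.add_atom(Atom(**base.atoms[i].__dict__))
        deduce_covalent_bonds(base)
        deduce_covalent_bonds(shuffled)
        mapped = {tuple(sorted((int(perm[b.begin]), int(perm[b.end]))))
                  for b in shuffled.bonds}
        assert mapped == {b.pair() for b in base.bonds}

    def test_existing_bonds_preserved(self):
        mol = fx.water_xyz()
        mol.add_bond(0, 1, order=2.0)  # pre-existing, different order
        deduce_covalent_bonds(mol)
        assert mol.bonds[0].order == 2.0
        assert len(mol.bonds) == 2


class TestImplicitHydrogens:
    @pytest.mark.parametrize("label,charge,bonds,expected", [
        ("C", 0, [], 4), ("O", 0, [1.0, 1.0], 0), ("N", 1, [1.0], 3),
        ("N", 0, [1.0, 2.0], 0), ("O", -1, [1.0], 0), ("Fe", 0, [], 0),
        ("S", 0, [1.0], 1), ("C", 0, [3.0], 1)])
    def test_valence_formula(self, label, charge, bonds, expected):
        mol = Molecule()
        mol.add_atom(label=label, charge=charge)
        for k, order in enumerate(bonds):
            mol.add_atom(label="C", x=k + 1.0)
            mol.add_bond(0, k + 1, order)
        deduce_implicit_hydrogens(mol)
        assert mol.atoms[0].implicit_h == expected

    def test_pyridinium_nitrogen_gets_one_h(self):
        mol = deduce_implicit_hydrogens(fx.pyridinium())
        # N+ with one drawn double and one single bond
        assert mol.atoms[0].label == "N"
        assert mol.atoms[0].implicit_h == 1
        assert all(a.implicit_h == 1 for a in mol.atoms[1:])

    def test_special_bond_orders_in_bookkeeping(self):
        # zero-order contributes 0, half and resonance contribute 1
        mol = Molecule()
        mol.add_atom(label="C")
        mol.add_atom(label="C", x=1.0)
        mol.add_bond(0, 1, order=0.0)
        deduce_implicit_hydrogens(mol)
        assert mol.atoms[0].implicit_h == 4
        mol.bonds[0].order = 1.5
        deduce_implicit_hydrogens(mol)
        assert mol.atoms[0].implicit_h == 3

    def test_radicals_reduce_h(self):
        mol = Molecule()
        mol.add_atom(label="C", radicals=1)
        deduce_implicit_hydrogens(mol)
        assert mol.atoms[0].implicit_h == 3

    def test_matches_rdkit_on_random_neutral_organics(self, rng):
        """Independent oracle: rdkit's valence model agrees on molecules
        whose atoms stay within their first default valence."""
        Chem = pytest.importorskip("rdkit.Chem")
        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                     3.0: Chem.BondType.TRIPLE}
        checked = 0
        for _ in range(50):
            mol = fx.random_molecule(rng, int(rng.integers(3, 10)),
                                     charges=True, stereo=False)
            rd = Chem.RWMol()
            for a in mol.atoms:
                ra = Chem.Atom(a.label)
                ra.SetFormalCharge(a.charge)
                rd.AddAtom(ra)
            for b in mol.bonds:
                rd.AddBond(b.begin, b.end, order_map[b.order])
            try:
                Chem.SanitizeMol(rd)
            except Exception:
                continue  # rdkit rejects e.g. S/P expanded cases
            deduce_implicit_hydrogens(mol)
            for ours, theirs in zip(mol.atoms, rd.GetAtoms()):
                assert ours.implicit_h == theirs.GetTotalNumHs(), \
                    (ours.label, ours.charge)
            checked += 1
        assert checked >= 25


class TestSplitCopy:
    def test_benzene_plus_lone_sodium(self, benzene):
        benzene.add_atom(label="Na", x=10.0, y=0.0)
        parts = split_disconnected(benzene)
        assert [len(p.atoms) for p in parts] == [6, 1]
        assert parts[1].atoms[0].label == "Na"

    def test_connected_chain_single_component(self):
        assert len(split_disconnected(fx.hexane())) == 1

    def test_empty_molecule(self):
        assert split_disconnected(Molecule()) == []

    def test_zero_order_bond_connects(self):
        assert len(split_disconnected(fx.nacl_pair())) == 1

    def test_component_count_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(20):
            n = int(rng.integers(2, 15))
            mol = Molecule()
            for i in range(n):
                mol.add_atom(label="C", x=float(i))
            for _ in range(int(rng.integers(0, n))):
                a, b = int(rng.integers(n)), int(rng.integers(n))
                if a != b and mol.bond_between(a, b) is None:
                    mol.add_bond(min(a, b), max(a, b))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(b.pair() for b in mol.bonds)
            parts = split_disconnected(mol)
            assert len(parts) == nx.number_connected_components(g)
            assert sum(len(p.atoms) for p in parts) == n
            for p in parts:
                assert all(0 <= b.begin < len(p.atoms)
                           and 0 <= b.end < len(p.atoms) for b in p.bonds)

    def test_copy_is_independent(self, naphthalene):
        perceive_rings_sssr(naphthalene)
        dup = copy_molecule(naphthalene)
        assert dup is not naphthalene
        assert len(dup.rings) == len(naphthalene.rings)
        dup.remove_atom(0)
        assert len(naphthalene.atoms) == 10
        dup.atoms[0].label = "N"
        assert naphthalene.atoms[1].label == "C"


class TestRingPerception:
    def test_benzene_one_six_ring(self, benzene):
        perceive_rings_sssr(benzene)
        assert len(benzene.rings) == 1
        assert len(benzene.rings[0]) == 6

    def test_naphthalene_two_six_rings(self, naphthalene):
        perceive_rings_sssr(naphthalene)
        assert sorted(len(r) for r in naphthalene.rings) == [6, 6]

    def test_biphenyl_bridge_bond_in_no_ring(self):
        mol = fx.biphenyl()
        perceive_rings_sssr(mol)
        assert sorted(len(r) for r in mol.rings) == [6, 6]
        bridge = mol.bond_between(0, 9)
        assert all(bridge not in r.bond_indices for r in mol.rings)

    def test_hexane_acyclic(self):
        mol = perceive_rings_sssr(fx.hexane())
        assert mol.rings == []

    def test_ring_atoms_and_bonds_consistent(self, naphthalene):
        perceive_rings_sssr(naphthalene)
        for ring in naphthalene.rings:
            k = len(ring)
            for i in range(k):
                a = ring.atom_indices[i]
                b = ring.atom_indices[(i + 1) % k]
                bond = naphthalene.bonds[ring.bond_indices[i]]
                assert bond.pair() == (min(a, b), max(a, b))

    def test_count_equals_circuit_rank_on_random_graphs(self, rng):
        for _ in range(100):
            mol = fx.random_graph_molecule(rng, int(rng.integers(3, 13)))
            perceive_rings_sssr(mol)
            rank = len(mol.bonds) - len(mol.atoms) + len(
                split_disconnected(mol))
            assert len(mol.rings) == rank

    def test_ring_sizes_match_minimum_cycle_basis(self, rng):
        """networkx's minimum cycle basis is the independent oracle for
        the 'smallest' part of SSSR (total ring size is minimal)."""
        nx = pytest.importorskip("networkx")
        for _ in range(40):
            mol = fx.random_graph_molecule(rng, int(rng.integers(4, 12)))
            g = nx.Graph(b.pair() for b in mol.bonds)
            g.add_nodes_from(range(len(mol.atoms)))
            perceive_rings_sssr(mol)
            oracle = sorted(len(c) for c in nx.minimum_cycle_basis(g))
            assert sorted(len(r) for r in mol.rings) == oracle


class TestSupercell:
    def test_cubic_2x2x2_corners(self):
        mol = Molecule()
        mol.add_atom(label="Po", x=0.0, y=0.0, z=0.0)
        cell = UnitCell(4, 4, 4)
        sc = build_supercell(mol, cell, 2, 2, 2)
        assert len(sc.atoms) == 8
        corners = {(round(a.x, 9), round(a.y, 9), round(a.z, 9))
                   for a in sc.atoms}
        assert corners == {(float(i), float(j), float(k))
                           for i in (0.0, 4.0) for j in (0.0, 4.0)
                           for k in (0.0, 4.0)}

    def test_fractional_center_maps_to_cartesian_center(self):
        mol = Molecule()
        mol.add_atom(label="C", x=0.5, y=0.5, z=0.5)
        sc = build_supercell(mol, UnitCell(4, 4, 4), 1, 1, 1)
        a = sc.atoms[0]
        assert (a.x, a.y, a.z) == pytest.approx((2.0, 2.0, 2.0))

    def test_triclinic_matches_independent_matrix(self):
        """Oracle: the fractional->Cartesian matrix coded from scratch
        here, cross-checked against gemmi's orthogonalization."""
        cell = UnitCell(5, 6, 7, 80, 95, 100)
        al, be, ga = (math.radians(v) for v in (80, 95, 100))
        v = math.sqrt(1 - math.cos(al) ** 2 - math.cos(be) ** 2
                      - math.cos(ga) ** 2
                      + 2 * math.cos(al) * math.cos(be) * math.cos(ga))
        oracle = np.array([
            [5.0, 6 * math.cos(ga), 7 * math.cos(be)],
            [0.0, 6 * math.sin(ga),
             7 * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)],
            [0.0, 0.0, 7 * v / math.sin(ga)]])
        assert np.abs(cell.matrix() - oracle).max() < 1e-9
        gemmi = pytest.importorskip("gemmi")
        g = gemmi.UnitCell(5, 6, 7, 80, 95, 100)
        for frac in ((0.1, 0.7, 0.3), (0.9, 0.2, 0.5)):
            mine = cell.to_cartesian(np.array(frac))
            ref = g.orthogonalize(gemmi.Fractional(*frac))
            assert np.abs(mine - [ref.x, ref.y, ref.z]).max() < 1e-9

    def test_nacl_cif_2x2x2_has_16_atoms(self):
        from molcanvas.formats import read_cif
        mol, cell = read_cif(fx.nacl_cif_text())
        sc = build_supercell(mol, cell, 2, 2, 2)
        assert len(sc.atoms) == 16

    def test_volume_scales_with_multipliers(self):
        cell = UnitCell(3, 4, 5, 90, 90, 90)
        assert cell.volume() == pytest.approx(60.0)
        mol = Molecule()
        mol.add_atom(label="C", x=0.0, y=0.0, z=0.0)
        sc = build_supercell(mol, cell, 3, 2, 1)
        xs = [a.x for a in sc.atoms]
        ys = [a.y for a in sc.atoms]
        assert max(xs) - min(xs) == pytest.approx(2 * 3.0)
        assert max(ys) - min(ys) == pytest.approx(1 * 4.0)

    def test_bonds_replicated_within_images(self):
        mol = fx.nacl_pair()  # 2 atoms, 1 bond (fractional-ish coords)
        mol.atoms[1].x = 0.5
        sc = build_supercell(mol, UnitCell(5, 5, 5), 2, 1, 1)
        assert len(sc.atoms) == 4
        assert len(sc.bonds) == 2
        assert all(b.order == 0.0 for b in sc.bonds)

    @pytest.mark.parametrize("kwargs", [
        dict(a=0.0, b=1, c=1), dict(a=1, b=1, c=1, alpha=0.0),
        dict(a=1, b=1, c=1, alpha=179.9, beta=179.9, gamma=0.2)])
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(InvalidCellError):
            UnitCell(**kwargs)
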