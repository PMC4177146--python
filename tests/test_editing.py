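import numpy as np
import pytest

from molforge import fixtures
from molforge.editing import (
    EditHistory,
    Hybridization,
    add_bond,
    add_bonded_atom,
    add_hydrogen,
    change_element,
    delete_atom,
    delete_bond,
    hydrogens_needed,
    open_direction,
    redo,
    rotate_fragment,
    undo,
)
from molforge.elements import covalent_radius, default_table
from molforge.errors import (
    DuplicateBondError,
    EmptyHistoryError,
    RingBondError,
)
from molforge.geometry import dihedral, distance
from molforge.molecule import Molecule


class TestHydrogensNeeded:
    @pytest.mark.parametrize(
        "symbol,bonds,expected",
        [("C", 1, 3), ("N", 1, 2), ("O", 1, 1), ("F", 1, 0), ("Ne", 0, 0),
         ("C", 0, 3), ("C", 4, 0), ("B", 1, 3), ("Si", 1, 3), ("S", 2, 0)],
    )
    def test_octet_rule_counts(self, symbol, bonds, expected):
        assert hydrogens_needed(symbol, bonds) == expected

    def test_non_p_block_gets_none(self):
        for sym in ("Fe", "Na", "H", "Zn"):
            assert hydrogens_needed(sym, 0) == 0

    def test_never_exceeds_three_exhaustive(self):
        table = default_table()
        for sym in table.symbols():
            for bonds in range(7):
                assert 0 <= hydrogens_needed(sym, bonds) <= 3


class TestChangeElement:
    def test_multibonded_atom_changes_symbol_only(self, methane):
        out = change_element(methane, None, 0, "N")
        assert out.symbols[0] == "N"
        np.testing.assert_array_equal(out.coords, methane.coords)
        assert len(out) == 5  # no hydrogens added

    def test_singly_bonded_atom_repositioned_and_filled(self):
        hc = Molecule.from_arrays(["C", "H"], [[0, 0, 0], [1.07, 0, 0]], bonds=[(0, 1)])
        out = change_element(hc, None, 1, "O", Hybridization.SP3)
        assert out.symbols[1] == "O"
        assert distance(out, 0, 1) == pytest.approx(
            covalent_radius("C") + covalent_radius("O"), abs=1e-9
        )
        # O with one bond needs exactly one new hydrogen
        assert out.symbols.count("H") == 1
        h_idx = out.symbols.index("H")
        assert distance(out, 1, h_idx) == pytest.approx(
            covalent_radius("O") + covalent_radius("H"), abs=1e-9
        )

    def test_isolated_atom_changes_in_place(self):
        mol = Molecule.from_arrays(["C"], [[1, 2, 3]])
        out = change_element(mol, None, 0, "Si")
        assert out.symbols == ["Si"]
        np.testing.assert_array_equal(out.coords, [[1, 2, 3]])

    def test_snapshot_pushed_before_edit(self, methane):
        history = EditHistory()
        change_element(methane, history, 0, "N")
        assert history.can_undo
        assert history.undo_stack[-1].same_structure(methane)


class TestAddBondedAtom:
    def test_open_tetrahedral_direction(self, methane):
        stripped = delete_atom(methane, None, 4)  # 3-coordinate carbon
        ideal = methane.atoms[4].position / np.linalg.norm(methane.atoms[4].position)
        out = add_bonded_atom(stripped, None, 0, "C")
        new_c = out.symbols.index("C", 1)
        got = out.atoms[new_c].position - out.atoms[0].position
        got /= np.linalg.norm(got)
        assert np.degrees(np.arccos(np.clip(got @ ideal, -1, 1))) < 1.0

    def test_isolated_parent_uses_default_direction(self):
        mol = Molecule.from_arrays(["C"], [[0, 0, 0]])
        out = add_bonded_atom(mol, None, 0, "C")
        assert out.has_bond(0, 1)
        assert distance(out, 0, 1) == pytest.approx(2 * covalent_radius("C"), abs=1e-6)

    def test_bond_length_is_radii_sum(self, butanol):
        for parent, sym in [(0, "C"), (3, "N"), (5, "O")]:
            out = add_bonded_atom(butanol, None, parent, sym)
            new_idx = len(butanol)
            expected = covalent_radius(sym) + covalent_radius(butanol.symbols[parent])
            assert distance(out, parent, new_idx) == pytest.approx(expected, abs=1e-6)

    def test_new_carbon_receives_three_hydrogens(self, methane):
        stripped = delete_atom(methane, None, 4)
        out = add_bonded_atom(stripped, None, 0, "C")
        assert len(out) == len(stripped) + 4  # C + 3 H


class TestAddHydrogen:
    def test_lands_near_fourth_tetrahedral_direction(self, methane):
        stripped = delete_atom(methane, None, 4)
        ideal = methane.atoms[4].position / np.linalg.norm(methane.atoms[4].position)
        out = add_hydrogen(stripped, None, 0)
        got = out.atoms[-1].position - out.atoms[0].position
        got /= np.linalg.norm(got)
        assert np.degrees(np.arccos(np.clip(got @ ideal, -1, 1))) < 5.0

    def test_bare_atom_any_direction_correct_length(self):
        mol = Molecule.from_arrays(["O"], [[0, 0, 0]])
        out = add_hydrogen(mol, None, 0)
        assert distance(out, 0, 1) == pytest.approx(
            covalent_radius("O") + covalent_radius("H"), abs=1e-9
        )

    def test_existing_atoms_never_move(self, butanol):
        out = add_hydrogen(butanol, None, 0)
        np.testing.assert_array_equal(out.coords[: len(butanol)], butanol.coords)


class TestOpenDirection:
    def test_two_collinear_bonds_fall_back_to_grid(self):
        mol = Molecule.from_arrays(
            ["C", "O", "O"], [[0, 0, 0], [1.2, 0, 0], [-1.2, 0, 0]], bonds=[(0, 1), (0, 2)]
        )
        d = open_direction(mol, 0)
        # best direction is perpendicular to the O=C=O axis
        assert abs(d[0]) < 0.1
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-6)


class TestDeleteAtom:
    def test_deleting_methane_carbon_empties_molecule(self, methane):
        assert len(delete_atom(methane, None, 0)) == 0

    def test_deleting_one_hydrogen(self, methane):
        out = delete_atom(methane, None, 1)
        assert len(out) == 4
        assert len(out.bonds) == 3

    def test_hydroxyl_oxygen_takes_its_hydrogen(self, butanol):
        o_idx = butanol.symbols.index("O")
        oh_h = [n for n in butanol.neighbors(o_idx) if butanol.symbols[n] == "H"]
        assert len(oh_h) == 1
        out = delete_atom(butanol, None, o_idx)
        assert len(out) == len(butanol) - 2
        assert out.symbols.count("C") == 4  # carbon skeleton intact

    def test_indices_compacted_preserving_order(self, butanol):
        out = delete_atom(butanol, None, 2)  # methyl C + its 3 H
        expected = [s for i, s in enumerate(butanol.symbols)
                    if i != 2 and not (s == "H" and i in butanol.neighbors(2))]
        assert out.symbols == expected


class TestBondEdits:
    def test_add_then_delete_restores(self, methane):
        out = add_bond(methane, None, 1, 2)
        back = delete_bond(out, None, 1, 2)
        assert back.bonds == methane.bonds

    def test_self_bond_rejected(self, methane):
        with pytest.raises(DuplicateBondError):
            add_bond(methane, None, 1, 1)

    def test_cube_corner_cage(self):
        cube = fixtures.make("cube_corners")
        edges = [
            (0, 1), (0, 2), (0, 4), (1, 3), (1, 5), (2, 3),
            (2, 6), (3, 7), (4, 5), (4, 6), (5, 7), (6, 7),
        ]
        mol = cube
        for i, j in edges:
            mol = add_bond(mol, None, i, j)
        assert len(mol.bonds) == 12
        np.testing.assert_array_equal(mol.coords, cube.coords)


class TestRotateFragment:
    def test_sixty_degrees_changes_every_hcch_dihedral(self, ethane_staggered):
        es = ethane_staggered
        out = rotate_fragment(es, None, (0, 1), 60.0)
        for h1 in (2, 3, 4):
            for h2 in (5, 6, 7):
                delta = dihedral(out, h1, 0, 1, h2) - dihedral(es, h1, 0, 1, h2)
                delta = (delta + 180.0) % 360.0 - 180.0
                assert abs(delta) == pytest.approx(60.0, abs=1e-9)

    def test_full_turn_identity(self, butanol):
        out = rotate_fragment(butanol, None, (0, 3), 360.0)
        np.testing.assert_allclose(out.coords, butanol.coords, atol=1e-9)

    def test_ring_bond_rejected(self, perceived_benzene):
        with pytest.raises(RingBondError):
            rotate_fragment(perceived_benzene, None, (0, 1), 30.0)

    def test_smaller_fragment_moves(self, butanol):
        # bond C3-C4: methyl side (4 atoms) is smaller and moves
        out = rotate_fragment(butanol, None, (3, 5), 90.0)
        np.testing.assert_array_equal(out.coords[0], butanol.coords[0])
        assert not np.allclose(out.coords[len(butanol) - 1], butanol.coords[len(butanol) - 1])


class TestUndoRedo:
    def test_edit_then_undo_restores_exactly(self, methane):
        history = EditHistory()
        edited = change_element(methane, history, 0, "N")
        back = undo(history, edited)
        assert back.same_structure(methane)

    def test_undo_then_redo(self, methane):
        history = EditHistory()
        edited = change_element(methane, history, 0, "N")
        back = undo(history, edited)
        again = redo(history, back)
        assert again.same_structure(edited)

    def test_fifteen_edits_allow_exactly_ten_undos(self, methane):
        history = EditHistory()
        mol = methane
        for _ in range(15):
            mol = add_hydrogen(mol, history, 0)
        for _ in range(10):
            mol = undo(history, mol)
        with pytest.raises(EmptyHistoryError):
            undo(history, mol)

    def test_new_edit_clears_redo(self, methane):
        history = EditHistory()
        mol = change_element(methane, history, 0, "N")
        mol = undo(history, mol)
        assert history.can_redo
        change_element(mol, history, 0, "O")
        assert not history.can_redo

    def test_undo_folds_back_over_any_short_edit_sequence(self, butanol):
        rng = np.random.default_rng(42)
        for _ in range(5):
            history = EditHistory()
            mol = butanol
            n_edits = int(rng.integers(1, 11))
            for _ in range(n_edits):
                kind = rng.integers(0, 3)
                if kind == 0:
                    mol = add_hydrogen(mol, history, int(rng.integers(0, len(mol))))
                elif kind == 1:
                    mol = change_element(mol, history, int(rng.integers(0, len(mol))), "C")
                else:
                    non_ring = sorted(mol.bonds)[int(rng.integers(0, len(mol.bonds)))]
                    mol = rotate_fragment(mol, history, non_ring, float(rng.uniform(0, 180)))
            for _ in range(n_edits):
                mol = undo(history, mol)
            assert mol.same_structure(butanol)


class TestMoleculeInvariantsAfterEdits:
    @pytest.mark.parametrize("op_name", ["add_hydrogen", "delete_atom", "change_element"])
    def test_bonds_reference_valid_atoms(self, butanol, op_name):
        if op_name == "add_hydrogen":
            out = add_hydrogen(butanol, None, 3)
        elif op_name == "delete_atom":
            out = delete_atom(butanol, None, 3)
        else:
            out = change_element(butanol, None, 3, "N")
        for i, j in out.bonds:
            assert 0 <= i < j < len(out)
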