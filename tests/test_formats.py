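"""File format readers/writers and format sniffing."""

import numpy as np
import pytest

from conftest import assert_molecules_equal
from molcanvas import fixtures as fx
from molcanvas.errors import (CapacityError, ParseError,
                              UnknownFormatError, UnsupportedDialectError)
from molcanvas.formats import (detect_format, read_auto, read_cdjson,
                               read_cif, read_cml, read_jcamp, read_mol,
                               read_pdb, read_rxn, read_xyz, write_cdjson,
                               write_cml, write_mol, write_xyz)
from molcanvas.model import Atom, Molecule

METHANE_MOL = """methane
  test

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6294    0.6294    0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6294   -0.6294   -0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294    0.6294   -0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294   -0.6294    0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  1  0  0  0
  1  4  1  6  0  0  0
  1  5  1  0  0  0  0
M  END
"""

CHARGED_MOL = """ion
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 N   0  3  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 O   0  5  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
M  END
"""


class TestMol:
    def test_methane_counts_and_stereo(self):
        mol = read_mol(METHANE_MOL)
        assert len(mol.atoms) == 5
        assert len(mol.bonds) == 4
        assert mol.name == "methane"
        assert all(b.order == 1.0 for b in mol.bonds)
        assert mol.bonds[1].stereo == "protruding"   # flag 1
        assert mol.bonds[2].stereo == "recessed"     # flag 6
        assert mol.bonds[0].stereo == "none"

    def test_atom_block_charge_codes(self):
        mol = read_mol(CHARGED_MOL)
        assert mol.atoms[0].charge == 1    # code 3 -> +1
        assert mol.atoms[1].charge == -1   # code 5 -> -1

    def test_m_chg_supersedes_atom_block(self):
        text = CHARGED_MOL.replace("M  END",
                                   "M  CHG  1   2  -3\nM  END")
        mol = read_mol(text)
        assert mol.atoms[0].charge == 0    # block codes reset
        assert mol.atoms[1].charge == -3

    def test_v3000_rejected(self):
        bad = METHANE_MOL.replace("V2000", "V3000")
        with pytest.raises(UnsupportedDialectError):
            read_mol(bad)

    def test_malformed_counts_line_reports_line_number(self):
        bad = "name\n\n\n  x  y\nM  END\n"
        with pytest.raises(ParseError, match="line 4"):
            read_mol(bad)

    def test_empty_molecule_round_trip(self):
        text = write_mol(Molecule())
        mol = read_mol(text)
        assert len(mol.atoms) == 0 and len(mol.bonds) == 0

    def test_negative_charge_emits_m_chg(self):
        mol = Molecule()
        mol.add_atom(label="O", charge=-1)
        assert "M  CHG  1   1  -1" in write_mol(mol)

    def test_capacity_error_over_999(self):
        mol = Molecule()
        for i in range(1000):
            mol.add_atom(label="C", x=float(i))
        with pytest.raises(CapacityError):
            write_mol(mol)

    def test_crlf_tolerated(self):
        mol = read_mol(METHANE_MOL.replace("\n", "\r\n"))
        assert len(mol.atoms) == 5


class TestXyz:
    def test_water(self):
        text = "3\nwater\nO 0.0 0.0 0.0\nH 0.96 0.0 0.0\nH -0.24 0.93 0.0\n"
        mol = read_xyz(text)
        assert len(mol.atoms) == 3
        assert len(mol.bonds) == 0
        assert mol.atoms[1].x == pytest.approx(0.96)

    def test_trailing_blank_lines_tolerated(self):
        mol = read_xyz("1\nc\nC 0 0 0\n\n\n")
        assert len(mol.atoms) == 1

    def test_count_mismatch_raises(self):
        with pytest.raises(ParseError):
            read_xyz("3\nwater\nO 0 0 0\nH 1 0 0\n")

    def test_deduction_chain(self):
        mol = read_xyz(write_xyz(fx.water_xyz()))
        from molcanvas.informatics import deduce_covalent_bonds
        assert len(deduce_covalent_bonds(mol).bonds) == 2


class TestPdb:
    def test_water_with_conect(self):
        mol = read_pdb(fx.water_pdb_text())
        assert [a.label for a in mol.atoms] == ["O", "H", "H"]
        assert len(mol.bonds) == 2

    def test_element_inferred_from_atom_name(self):
        line = ("HETATM    1  CA  UNL A   1       0.000   0.000   0.000  "
                "1.00  0.00\n")
        mol = read_pdb(line)  # ' CA ' starts with a space -> carbon
        assert mol.atoms[0].label == "C"
        line2 = ("HETATM    1 FE   UNL A   1       0.000   0.000   0.000  "
                 "1.00  0.00\n")
        assert read_pdb(line2).atoms[0].label == "Fe"

    def test_first_model_only(self):
        text = ("MODEL     1\n"
                + fx.water_pdb_text().replace("END\n", "")
                + "ENDMDL\nMODEL     2\n"
                + fx.water_pdb_text().replace("END\n", "") + "ENDMDL\nEND\n")
        mol = read_pdb(text)
        assert len(mol.atoms) == 3

    def test_alt_loc_b_skipped(self):
        text = fx.water_pdb_text().replace(
            "HETATM    2  H1  HOH", "HETATM    2  H1 BHOH")
        assert len(read_pdb(text).atoms) == 2

    def test_duplicate_conect_collapsed(self):
        text = fx.water_pdb_text() + "CONECT    1    2\nCONECT    2    1\n"
        assert len(read_pdb(text).bonds) == 2


class TestCif:
    def test_nacl_cell_and_sites(self):
        mol, cell = read_cif(fx.nacl_cif_text())
        assert [a.label for a in mol.atoms] == ["Na", "Cl"]
        # '5.6400(2)' -> uncertainty parentheses stripped
        assert cell.a == pytest.approx(5.64)
        assert cell.alpha == 90.0
        assert mol.atoms[1].x == pytest.approx(0.5)

    def test_label_fallback_strips_digits(self):
        text = fx.nacl_cif_text().replace("_atom_site_type_symbol\n", "") \
            .replace("Na1 Na ", "Na1 ").replace("Cl1 Cl ", "Cl1 ")
        mol, _ = read_cif(text)
        assert [a.label for a in mol.atoms] == ["Na", "Cl"]

    def test_missing_cell_item_raises(self):
        bad = fx.nacl_cif_text().replace("_cell_length_b 5.64\n", "")
        with pytest.raises(ParseError, match="_cell_length_b"):
            read_cif(bad)


class TestCml:
    def test_round_trip(self, naphthalene):
        back = read_cml(write_cml(naphthalene))
        assert len(back) == 1
        assert_molecules_equal(back[0], naphthalene)

    def test_order_tokens(self):
        text = """<molecule id="m"><atomArray>
        <atom id="a0" elementType="C" x2="0" y2="0"/>
        <atom id="a1" elementType="O" x2="1" y2="0"/>
        </atomArray><bondArray>
        <bond atomRefs2="a0 a1" order="D"/>
        </bondArray></molecule>"""
        mol = read_cml(text)[0]
        assert mol.bonds[0].order == 2.0
        assert mol.atoms[0].z == 0.0  # x2-only file -> z defaults to 0

    def test_unknown_order_token_named(self):
        text = ('<molecule><atomArray><atom id="a0" x2="0" y2="0"/>'
                '<atom id="a1" x2="1" y2="0"/></atomArray><bondArray>'
                '<bond atomRefs2="a0 a1" order="Q"/></bondArray></molecule>')
        with pytest.raises(ParseError, match="'Q'"):
            read_cml(text)

    def test_malformed_xml_raises(self):
        with pytest.raises(ParseError):
            read_cml("<molecule><atomArray>")

    def test_multi_molecule_document(self, benzene):
        text = write_cml([benzene, fx.water_2d()])
        mols = read_cml(text)
        assert [len(m.atoms) for m in mols] == [6, 3]


class TestRxn:
    def _rxn(self, reactants, products):
        blocks = "".join("$MOL\n" + write_mol(m)
                         for m in reactants + products)
        return (f"$RXN\nfixture\n\n\n{len(reactants):3d}{len(products):3d}\n"
                + blocks)

    def test_one_plus_one(self, benzene):
        doc = read_rxn(self._rxn([benzene], [fx.water_2d()]))
        assert len(doc.molecules) == 2
        assert doc.reaction_roles == (1, 1)
        assert len(doc.reactants) == 1 and len(doc.products) == 1

    def test_two_plus_one(self, benzene):
        doc = read_rxn(self._rxn([benzene, fx.hexane()], [fx.water_2d()]))
        assert doc.reaction_roles == (2, 1)
        assert [len(m.atoms) for m in doc.molecules] == [6, 6, 3]

    def test_embedded_mol_fidelity(self, naphthalene):
        doc = read_rxn(self._rxn([naphthalene], [naphthalene]))
        standalone = read_mol(write_mol(naphthalene))
        assert_molecules_equal(doc.molecules[0], standalone)

    def test_count_block_mismatch_raises(self, benzene):
        text = self._rxn([benzene], [benzene]).replace("  1  1", "  2  1")
        with pytest.raises(ParseError):
            read_rxn(text)


class TestCdjson:
    def test_dialect_defaults(self):
        doc = read_cdjson('{"a":[{"x":0,"y":0}]}')
        atom = doc.molecules[0].atoms[0]
        assert atom.label == "C" and atom.charge == 0 and atom.z == 0.0

    def test_simple_bond(self):
        doc = read_cdjson(
            '{"a":[{"x":0,"y":0},{"x":1,"y":0,"l":"O"}],"b":[{"b":0,"e":1}]}')
        mol = doc.molecules[0]
        assert mol.atoms[1].label == "O"
        assert mol.bonds[0].order == 1.0

    def test_round_trip_byte_stable(self, rng):
        mol = fx.random_molecule(rng, 9)
        once = write_cdjson(mol)
        twice = write_cdjson(read_cdjson(once))
        assert once == twice

    def test_unknown_keys_preserved(self):
        text = '{"a":[{"x":0,"y":0,"custom":7}],"meta":{"k":1}}'
        out = write_cdjson(read_cdjson(text))
        assert '"custom":7' in out
        assert '"meta":{"k":1}' in out

    def test_missing_coordinates_raises(self):
        with pytest.raises(ParseError):
            read_cdjson('{"a":[{"x":0}]}')

    def test_bond_index_out_of_range_raises(self):
        with pytest.raises(ParseError):
            read_cdjson('{"a":[{"x":0,"y":0}],"b":[{"b":0,"e":3}]}')


class TestJcamp:
    def test_xypoints_affn(self):
        text = ("##TITLE=three\n##DATA TYPE=INFRARED SPECTRUM\n"
                "##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
                "##XYPOINTS=(XY..XY)\n400, 0.1; 500, 0.5; 600, 0.2\n##END=\n")
        s = read_jcamp(text)
        assert s.kind == "ir"
        assert list(s.x) == [400.0, 500.0, 600.0]
        assert list(s.y) == pytest.approx([0.1, 0.5, 0.2])

    def test_yfactor_scales_raw_integers(self):
        text = ("##TITLE=t\n##XUNITS=PPM\n##YUNITS=AU\n"
                "##XFACTOR=1.0\n##YFACTOR=0.01\n##FIRSTX=0\n##LASTX=2\n"
                "##NPOINTS=3\n##XYDATA=(X++(Y..Y))\n0 100 250 75\n##END=\n")
        s = read_jcamp(text)
        assert list(s.y) == pytest.approx([1.0, 2.5, 0.75])
        assert list(s.x) == pytest.approx([0.0, 1.0, 2.0])

    def test_dif_line_hand_decoded(self):
        """SQZ start, DIF deltas, DUP repeat — decoded by hand from the
        ASDF letter tables: A00=100, J5=+15, K0=+20, j3=-13,
        T=repeat the -13 difference, r5=-95."""
        text = ("##TITLE=t\n##FIRSTX=0\n##LASTX=5\n##NPOINTS=6\n"
                "##XYDATA=(X++(Y..Y))\n"
                "0 A00 J5 K0 j3 T r5\n##END=\n")
        s = read_jcamp(text)
        assert list(s.y) == pytest.approx([100, 115, 135, 122, 109, 14])

    def test_affn_and_dif_twins_decode_identically(self):
        spec = fx.gaussian_mixture_spectrum([(3.0, 1.0, 0.2)], n_points=500)
        a = read_jcamp(fx.jcamp_text("t", spec.x, spec.y, form="affn"))
        d = read_jcamp(fx.jcamp_text("t", spec.x, spec.y, form="dif"))
        assert np.allclose(a.y, d.y)
        assert np.allclose(a.x, d.x)

    def test_npoints_mismatch_reports_both_counts(self):
        text = ("##TITLE=t\n##FIRSTX=0\n##LASTX=2\n##NPOINTS=5\n"
                "##XYDATA=(X++(Y..Y))\n0 1 2 3\n##END=\n")
        with pytest.raises(ParseError, match="5.*3"):
            read_jcamp(text)

    def test_missing_title_raises(self):
        with pytest.raises(ParseError):
            read_jcamp("##XYPOINTS=(XY..XY)\n1, 2\n##END=\n")

    def test_metadata_retained(self):
        spec = fx.gaussian_mixture_spectrum([(3.0, 1.0, 0.2)], n_points=50)
        s = read_jcamp(fx.jcamp_text("probe", spec.x, spec.y))
        assert s.title == "probe"
        assert s.x_units == "PPM"
        assert s.metadata["DATATYPE"] == "NMR SPECTRUM"


class TestDetect:
    @pytest.mark.parametrize("text_fn,expected", [
        (lambda: write_mol(fx.benzene()), "mol"),
        (lambda: write_cml(fx.benzene()), "cml"),
        (lambda: write_cdjson(fx.benzene()), "cdjson"),
        (lambda: write_xyz(fx.water_xyz()), "xyz"),
        (fx.water_pdb_text, "pdb"),
        (fx.nacl_cif_text, "cif"),
    ])
    def test_each_fixture_detected(self, text_fn, expected):
        assert detect_format(text_fn()) == expected

    def test_rxn_and_jcamp_detected(self):
        assert detect_format("$RXN\n\n\n\n  1  1\n") == "rxn"
        spec = fx.gaussian_mixture_spectrum([(1, 1, 0.2)], n_points=10)
        assert detect_format(fx.jcamp_text("t", spec.x, spec.y)) == "jcamp"

    def test_content_wins_over_extension_hint(self):
        text = write_mol(fx.benzene())
        assert detect_format(text, filename_hint="thing.txt") == "mol"

    def test_empty_string_unknown(self):
        with pytest.raises(UnknownFormatError):
            detect_format("")

    def test_read_auto_dispatch(self):
        doc = read_auto(write_cdjson(fx.benzene()))
        assert doc.source_format == "cdjson"
        assert len(doc.molecules[0].atoms) == 6


class TestRoundTrips:
    @pytest.mark.parametrize("seed", range(8))
    def test_mol_cml_cdjson_chain_preserves_value(self, seed):
        rng = np.random.default_rng(1000 + seed)
        mol = fx.random_molecule(rng, int(rng.integers(2, 12)))
        chain = read_mol(write_mol(
            read_cdjson(write_cdjson(
                read_cml(write_cml(
                    read_mol(write_mol(mol))))[0])).molecules[0]))
        assert_molecules_equal(chain, mol)

    def test_cross_format_consistency(self, naphthalene):
        via_mol = read_mol(write_mol(naphthalene))
        via_json = read_cdjson(write_cdjson(naphthalene)).molecules[0]
        assert_molecules_equal(via_mol, via_json)
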