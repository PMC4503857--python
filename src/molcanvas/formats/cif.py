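"""CIF reader (P1 subset).

Parsing of the CIF syntax itself is delegated to gemmi; this module
maps the cell data items and the atom_site loop onto the molcanvas
types.  Atoms come back in *fractional* coordinates together with the
:class:`~molcanvas.informatics.UnitCell`, ready for
:func:`~molcanvas.informatics.build_supercell`.  Symmetry operations
are not expanded: the atom list is whatever the atom_site loop states.
"""

from __future__ import annotations

from gemmi import cif as gemmi_cif

from ..elements import ELEMENTS, normalize_symbol
from ..errors import ParseError
from ..informatics import UnitCell
from ..model import Atom, Molecule

__all__ = ["read_cif"]

_CELL_ITEMS = ("_cell_length_a", "_cell_length_b", "_cell_length_c",
               "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma")


def _strip_label(label: str) -> str:
    """'O1' -> 'O', 'Ca2a' -> 'Ca': leading letters only, then normalize."""
    letters = ""
    for ch in label:
        if ch.isalpha():
            letters += ch
        else:
            break
    for length in (2, 1):
        sym = normalize_symbol(letters[:length])
        if sym in ELEMENTS:
            return sym
    return letters


def read_cif(text: str) -> tuple[Molecule, UnitCell]:
    try:
        doc = gemmi_cif.read_string(text)
        block = doc.sole_block()
    except (ValueError, RuntimeError) as exc:
        raise ParseError(f"CIF syntax error: {exc}") from None

    values = []
    for item in _CELL_ITEMS:
        raw = block.find_value(item)
        if raw is None:
            raise ParseError(f"missing cell data item {item}")
        values.append(gemmi_cif.as_number(raw))  # strips '(su)' suffixes
    cell = UnitCell(*values)

    table = block.find("_atom_site_", ["fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise ParseError("no _atom_site_fract_* loop found")
    symbols = block.find_loop("_atom_site_type_symbol")
    labels = block.find_loop("_atom_site_label")
    mol = Molecule(name=block.name if block.name != "#" else "")
    for i, row in enumerate(table):
        if len(symbols) > i and symbols[i] not in ("?", "."):
            sym = normalize_symbol(gemmi_cif.as_string(symbols[i]))
            # type symbols may carry oxidation states, e.g. 'Na1+'
            sym = _strip_label(sym)
        elif len(labels) > i:
            sym = _strip_label(gemmi_cif.as_string(labels[i]))
        else:
            raise ParseError("atom_site loop has neither type_symbol nor label")
        fx, fy, fz = (gemmi_cif.as_number(row[k]) for k in range(3))
        mol.atoms.append(Atom(label=sym, x=fx, y=fy, z=fz))
    return mol, cell
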