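"""PDB reader (fixed-column ATOM/HETATM subset).

Coordinates and identity come from the fixed columns of ATOM/HETATM
records; CONECT records become order-1 bonds (duplicates collapsed).
Only the first MODEL of a multi-model file is read, and alternate
locations other than blank or 'A' are skipped.  Lines that fail to
parse are skipped with a logged warning rather than aborting the read.
"""

from __future__ import annotations

import logging

from ..elements import ELEMENTS, normalize_symbol
from ..model import Atom, Molecule

log = logging.getLogger(__name__)

__all__ = ["read_pdb"]


def _element_from_name(name: str) -> str:
    """Infer the element from the atom-name columns when the element
    column (77-78) is empty, e.g. ' CA ' -> C, 'FE  ' -> Fe."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = normalize_symbol(stripped[:2]) if len(stripped) >= 2 else ""
    # a name starting in column 13 (no leading space) may be a 2-letter
    # element; prefer the 2-letter match only if it is a real element
    # and the name is not a common organic atom like "CA" (C-alpha)
    if not name.startswith(" ") and two in ELEMENTS:
        return two
    one = stripped[0].upper()
    return one if one in ELEMENTS else two


def read_pdb(text: str) -> Molecule:
    mol = Molecule()
    serial_to_index: dict[int, int] = {}
    conect_pairs: set[tuple[int, int]] = set()
    for lineno, line in enumerate(text.replace("\r\n", "\n").split("\n"), 1):
        record = line[:6].strip()
        if record == "ENDMDL":
            break  # first model only
        if record in ("ATOM", "HETATM"):
            try:
                serial = int(line[6:11])
                name = line[12:16]
                alt_loc = line[16]
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                log.warning("skipping unparseable PDB line %d: %r",
                            lineno, line)
                continue
            if alt_loc not in (" ", "", "A"):
                continue
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _element_from_name(name)
            if normalize_symbol(element) not in ELEMENTS:
                log.warning("skipping PDB line %d: cannot resolve element "
                            "from %r", lineno, line)
                continue
            serial_to_index[serial] = len(mol.atoms)
            mol.atoms.append(Atom(label=normalize_symbol(element),
                                  x=x, y=y, z=z))
        elif record == "CONECT":
            fields = line[6:].split()
            try:
                serials = [int(f) for f in fields]
            except ValueError:
                log.warning("skipping unparseable CONECT line %d", lineno)
                continue
            if len(serials) >= 2:
                src = serials[0]
                for dst in serials[1:]:
                    conect_pairs.add((min(src, dst), max(src, dst)))
    for a, b in sorted(conect_pairs):
        if a in serial_to_index and b in serial_to_index:
            i, j = serial_to_index[a], serial_to_index[b]
            if i != j and mol.bond_between(i, j) is None:
                mol.add_bond(i, j, 1.0)
    return mol
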