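"""Chemical Markup Language (CML 2) reader and writer.

Reads molecule/atomArray/bondArray documents with per-atom child
elements (id, elementType, x2/y2 or x3/y3/z3, formalCharge) and bonds
referencing atoms by id (atomRefs2) with order tokens S/D/T or 1/2/3.
The writer emits one <cml> wrapper with 3D coordinates and numeric
orders; round trips preserve values exactly (coordinates at 6 decimals).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from ..errors import ParseError
from ..model import Atom, Bond, Molecule

__all__ = ["read_cml", "write_cml"]

_ORDER_TOKENS = {"S": 1.0, "D": 2.0, "T": 3.0, "1": 1.0, "2": 2.0, "3": 3.0}
_ORDER_OUT = {1.0: "1", 2.0: "2", 3.0: "3"}


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_all(root: ET.Element, name: str) -> list[ET.Element]:
    return [el for el in root.iter() if _localname(el.tag) == name]


def read_cml(text: str) -> list[Molecule]:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed XML: {exc}") from None
    mol_elements = _find_all(root, "molecule")
    if not mol_elements and _localname(root.tag) in ("atomArray", "bondArray"):
        mol_elements = [root]
    molecules = []
    for mel in mol_elements:
        mol = Molecule(name=mel.get("id", "") or mel.get("title", ""))
        id_to_index: dict[str, int] = {}
        for ael in _find_all(mel, "atom"):
            aid = ael.get("id")
            if aid is None:
                raise ParseError("atom element without id")
            if "x2" in ael.attrib:
                x, y, z = float(ael.get("x2")), float(ael.get("y2", "0")), 0.0
            elif "x3" in ael.attrib:
                x = float(ael.get("x3"))
                y = float(ael.get("y3", "0"))
                z = float(ael.get("z3", "0"))
            else:
                x = y = z = 0.0
            id_to_index[aid] = len(mol.atoms)
            mol.atoms.append(Atom(
                label=ael.get("elementType", "C"), x=x, y=y, z=z,
                charge=int(ael.get("formalCharge", "0"))))
        for bel in _find_all(mel, "bond"):
            refs = (bel.get("atomRefs2") or "").split()
            if len(refs) != 2:
                raise ParseError(f"bond needs atomRefs2 with two ids, got "
                                 f"{bel.get('atomRefs2')!r}")
            try:
                a, b = id_to_index[refs[0]], id_to_index[refs[1]]
            except KeyError as exc:
                raise ParseError(f"bond references unknown atom id "
                                 f"{exc.args[0]!r}") from None
            token = bel.get("order", "S")
            if token not in _ORDER_TOKENS:
                raise ParseError(f"unknown bond order token {token!r}")
            stereo = "none"
            for child in bel:
                if _localname(child.tag) == "bondStereo":
                    stereo = {"W": "protruding", "H": "recessed"}.get(
                        (child.text or "").strip(), "none")
            mol.bonds.append(Bond(a, b, _ORDER_TOKENS[token], stereo))
        molecules.append(mol)
    if not molecules:
        raise ParseError("no <molecule> element found")
    return molecules


def write_cml(mols: list[Molecule] | Molecule) -> str:
    if isinstance(mols, Molecule):
        mols = [mols]
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<cml>"]
    for m, mol in enumerate(mols):
        name = f' id="{mol.name}"' if mol.name else ""
        lines.append(f" <molecule{name}>")
        lines.append("  <atomArray>")
        for i, a in enumerate(mol.atoms):
            charge = f' formalCharge="{a.charge}"' if a.charge else ""
            lines.append(
                f'   <atom id="a{i}" elementType="{a.label}" '
                f'x3="{a.x:.6f}" y3="{a.y:.6f}" z3="{a.z:.6f}"{charge}/>')
        lines.append("  </atomArray>")
        lines.append("  <bondArray>")
        for b in mol.bonds:
            if b.order not in _ORDER_OUT:
                raise ValueError(f"bond order {b.order} is not representable "
                                 "in CML (only 1, 2, 3)")
            stereo = {"protruding": "W", "recessed": "H"}.get(b.stereo)
            if stereo:
                lines.append(f'   <bond atomRefs2="a{b.begin} a{b.end}" '
                             f'order="{_ORDER_OUT[b.order]}">'
                             f'<bondStereo>{stereo}</bondStereo></bond>')
            else:
                lines.append(f'   <bond atomRefs2="a{b.begin} a{b.end}" '
                             f'order="{_ORDER_OUT[b.order]}"/>')
        lines.append("  </bondArray>")
        lines.append(" </molecule>")
    lines.append("</cml>")
    return "\n".join(lines) + "\n"
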