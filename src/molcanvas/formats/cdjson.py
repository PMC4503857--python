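"""Native JSON interchange dialect.

The document is either ``{"m": [molecule, ...]}`` or a bare molecule
``{"a": [...], "b": [...]}``.  Atom records use short keys: ``x``/``y``
(required), ``z``, ``l`` (element label, default ``"C"``), ``c`` (formal
charge, default 0).  Bond records: ``b``/``e`` (atom indices), ``o``
(order, default 1), ``s`` (stereo, ``"protruding"``/``"recessed"``).

The writer omits keys holding their default value and emits a fixed key
order, so a read→write pass is byte-stable.  Unknown keys survive a
round trip: the reader stashes them and the writer re-emits them (sorted
by key, after the known keys).  The schema ships in ``docs/schema.json``.
"""

from __future__ import annotations

import json

from ..errors import ParseError
from ..model import Atom, Bond, Molecule, STEREO_NONE
from .document import InterchangeDocument

__all__ = ["read_cdjson", "write_cdjson"]

_ATOM_KEYS = ("x", "y", "z", "l", "c")
_BOND_KEYS = ("b", "e", "o", "s")


def _molecule_from_record(rec: dict) -> Molecule:
    mol = Molecule(name=rec.get("n", ""))
    extras = {k: v for k, v in rec.items() if k not in ("a", "b", "n")}
    if extras:
        mol._extras = extras  # noqa: SLF001 - forward-compat passthrough
    for i, arec in enumerate(rec.get("a", [])):
        if "x" not in arec or "y" not in arec:
            raise ParseError(f"atom record {i} missing x/y coordinates")
        atom = Atom(label=arec.get("l", "C"),
                    x=float(arec["x"]), y=float(arec["y"]),
                    z=float(arec.get("z", 0.0)),
                    charge=int(arec.get("c", 0)))
        unknown = {k: v for k, v in arec.items() if k not in _ATOM_KEYS}
        if unknown:
            atom._extras = unknown
        mol.atoms.append(atom)
    n = len(mol.atoms)
    for i, brec in enumerate(rec.get("b", [])):
        if "b" not in brec or "e" not in brec:
            raise ParseError(f"bond record {i} missing b/e atom indices")
        a, b = int(brec["b"]), int(brec["e"])
        if not (0 <= a < n and 0 <= b < n):
            raise ParseError(f"bond record {i} index out of range "
                             f"({a}, {b}) for {n} atoms")
        bond = Bond(a, b, float(brec.get("o", 1)),
                    brec.get("s", STEREO_NONE))
        unknown = {k: v for k, v in brec.items() if k not in _BOND_KEYS}
        if unknown:
            bond._extras = unknown
        mol.bonds.append(bond)
    return mol


def read_cdjson(text: str) -> InterchangeDocument:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise ParseError("top level must be a JSON object")
    if "m" in data:
        records = data["m"]
    elif "a" in data:
        records = [data]
    else:
        raise ParseError('expected top-level "m" list or bare "a"/"b" molecule')
    doc = InterchangeDocument(source_format="cdjson")
    for rec in records:
        doc.molecules.append(_molecule_from_record(rec))
    return doc


def _num(v: float) -> float | int:
    return int(v) if float(v).is_integer() else float(v)


def _atom_record(a: Atom) -> dict:
    rec: dict = {"x": _num(round(a.x, 6)), "y": _num(round(a.y, 6))}
    if a.z:
        rec["z"] = _num(round(a.z, 6))
    if a.label != "C":
        rec["l"] = a.label
    if a.charge:
        rec["c"] = a.charge
    for k in sorted(getattr(a, "_extras", {})):
        rec[k] = a._extras[k]
    return rec


def _bond_record(b: Bond) -> dict:
    rec: dict = {"b": b.begin, "e": b.end}
    if b.order != 1.0:
        rec["o"] = _num(b.order)
    if b.stereo != STEREO_NONE:
        rec["s"] = b.stereo
    for k in sorted(getattr(b, "_extras", {})):
        rec[k] = b._extras[k]
    return rec


def _molecule_record(mol: Molecule) -> dict:
    rec: dict = {}
    if mol.name:
        rec["n"] = mol.name
    rec["a"] = [_atom_record(a) for a in mol.atoms]
    if mol.bonds:
        rec["b"] = [_bond_record(b) for b in mol.bonds]
    for k in sorted(getattr(mol, "_extras", {})):
        rec[k] = mol._extras[k]
    return rec


def write_cdjson(doc: InterchangeDocument | Molecule) -> str:
    """Serialize to the JSON dialect (canonical key order, LF-free)."""
    if isinstance(doc, Molecule):
        mols = [doc]
    else:
        mols = doc.molecules
    if len(mols) == 1:
        payload: dict = _molecule_record(mols[0])
    else:
        payload = {"m": [_molecule_record(m) for m in mols]}
    return json.dumps(payload, separators=(",", ":"))
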