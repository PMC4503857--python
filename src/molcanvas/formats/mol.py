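"""MDL MOL (CTfile) V2000 reader and writer.

Fixed-column connection tables: the atom block carries coordinates,
symbol and a legacy charge code; ``M  CHG`` / ``M  RAD`` property lines
override the atom-block codes for the whole block, per the CTfile rules.
V3000 input is recognized and rejected explicitly.
"""

from __future__ import annotations

from ..errors import CapacityError, ParseError, UnsupportedDialectError
from ..model import (Atom, Bond, Molecule, STEREO_NONE, STEREO_PROTRUDING,
                     STEREO_RECESSED)

__all__ = ["read_mol", "write_mol"]

# atom-block charge codes (column 37-39): code -> formal charge
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
# code 4 is "doublet radical"
_STEREO_READ = {0: STEREO_NONE, 1: STEREO_PROTRUDING, 6: STEREO_RECESSED}
_STEREO_WRITE = {STEREO_NONE: 0, STEREO_PROTRUDING: 1, STEREO_RECESSED: 6}


def _int_field(line: str, start: int, end: int, lineno: int, what: str) -> int:
    raw = line[start:end].strip()
    if not raw:
        return 0
    try:
        return int(raw)
    except ValueError:
        raise ParseError(f"bad {what} field {raw!r}", lineno) from None


def read_mol(text: str) -> Molecule:
    """Parse a single MOL V2000 connection table."""
    lines = text.replace("\r\n", "\n").split("\n")
    if len(lines) < 4:
        raise ParseError("molfile shorter than header + counts line",
                         len(lines))
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedDialectError("V3000 connection tables are not "
                                      "supported (V2000 only)", 4)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed counts line: {counts!r}", 4) from None

    mol = Molecule(name=lines[0].strip())
    charge_codes: list[int] = []
    for i in range(n_atoms):
        lineno = 5 + i
        try:
            line = lines[4 + i]
        except IndexError:
            raise ParseError("atom block truncated", lineno) from None
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
        except ValueError:
            raise ParseError(f"bad atom coordinates: {line!r}", lineno) from None
        symbol = line[31:34].strip()
        if not symbol:
            raise ParseError("missing element symbol", lineno)
        code = _int_field(line, 36, 39, lineno, "charge")
        charge_codes.append(code)
        mol.atoms.append(Atom(label=symbol, x=x, y=y, z=z,
                              charge=_CHARGE_CODES.get(code, 0),
                              radicals=1 if code == 4 else 0))

    for i in range(n_bonds):
        lineno = 5 + n_atoms + i
        try:
            line = lines[4 + n_atoms + i]
        except IndexError:
            raise ParseError("bond block truncated", lineno) from None
        a = _int_field(line, 0, 3, lineno, "bond atom") - 1
        b = _int_field(line, 3, 6, lineno, "bond atom") - 1
        order = _int_field(line, 6, 9, lineno, "bond order")
        stereo = _int_field(line, 9, 12, lineno, "bond stereo")
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise ParseError(f"bond atom index out of range: {line!r}", lineno)
        if order not in (1, 2, 3):
            raise ParseError(f"unsupported V2000 bond order {order}", lineno)
        mol.bonds.append(Bond(a, b, float(order),
                              _STEREO_READ.get(stereo, STEREO_NONE)))

    # property block: M CHG / M RAD supersede atom-block codes entirely
    chg: dict[int, int] = {}
    rad: dict[int, int] = {}
    for off, line in enumerate(lines[4 + n_atoms + n_bonds:]):
        lineno = 5 + n_atoms + n_bonds + off
        if line.startswith("M  END"):
            break
        for prefix, store in (("M  CHG", chg), ("M  RAD", rad)):
            if line.startswith(prefix):
                fields = line[6:].split()
                try:
                    cnt = int(fields[0])
                    pairs = [(int(fields[1 + 2 * k]), int(fields[2 + 2 * k]))
                             for k in range(cnt)]
                except (ValueError, IndexError):
                    raise ParseError(f"malformed {prefix.strip()} line",
                                     lineno) from None
                for idx, val in pairs:
                    store[idx - 1] = val
    if chg or rad:
        for atom in mol.atoms:
            atom.charge = 0
            atom.radicals = 0
        for idx, val in chg.items():
            mol.atoms[idx].charge = val
        # RAD codes: 1 singlet, 2 doublet, 3 triplet
        for idx, val in rad.items():
            mol.atoms[idx].radicals = {1: 0, 2: 1, 3: 2}.get(val, 0)
    return mol


def write_mol(mol: Molecule) -> str:
    """Emit a MOL V2000 block (coordinates to 4 decimals, LF endings).

    Charges and radicals are written as ``M  CHG`` / ``M  RAD`` property
    lines; the legacy atom-block charge column is left 0.
    """
    if len(mol.atoms) > 999 or len(mol.bonds) > 999:
        raise CapacityError("V2000 connection tables hold at most 999 "
                            "atoms/bonds")
    out = [mol.name, "  molcanvas", "",
           f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for a in mol.atoms:
        out.append(f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.label:<3}"
                   f" 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in mol.bonds:
        if b.order not in (1.0, 2.0, 3.0):
            raise CapacityError(f"bond order {b.order} is not representable "
                                "in V2000 (only 1, 2, 3)")
        out.append(f"{b.begin + 1:3d}{b.end + 1:3d}{int(b.order):3d}"
                   f"{_STEREO_WRITE[b.stereo]:3d}  0  0  0")
    charged = [(i + 1, a.charge) for i, a in enumerate(mol.atoms) if a.charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k:k + 8]
        out.append("M  CHG" + f"{len(chunk):3d}"
                   + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    radical = [(i + 1, {1: 2, 2: 3}.get(a.radicals))
               for i, a in enumerate(mol.atoms) if a.radicals]
    radical = [(i, v) for i, v in radical if v]
    for k in range(0, len(radical), 8):
        chunk = radical[k:k + 8]
        out.append("M  RAD" + f"{len(chunk):3d}"
                   + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n"
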