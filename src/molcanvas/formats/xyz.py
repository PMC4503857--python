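"""XYZ coordinate files: count line, comment line, then `symbol x y z`."""

from __future__ import annotations

from ..errors import ParseError
from ..model import Atom, Molecule

__all__ = ["read_xyz", "write_xyz"]


def read_xyz(text: str) -> Molecule:
    """Parse an XYZ file into a bond-less molecule with 3D coordinates.

    Trailing blank lines are tolerated; a count that disagrees with the
    number of coordinate lines is a parse error.
    """
    lines = text.replace("\r\n", "\n").split("\n")
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ParseError("empty XYZ file", 1)
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"first line must be an atom count, got "
                         f"{lines[0]!r}", 1) from None
    coord_lines = lines[2:]
    if len(coord_lines) != n:
        raise ParseError(f"count line says {n} atoms but found "
                         f"{len(coord_lines)} coordinate lines", 1)
    mol = Molecule(name=lines[1].strip() if len(lines) > 1 else "")
    for i, line in enumerate(coord_lines):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"expected 'symbol x y z', got {line!r}", 3 + i)
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise ParseError(f"bad coordinates in {line!r}", 3 + i) from None
        mol.atoms.append(Atom(label=parts[0], x=x, y=y, z=z))
    return mol


def write_xyz(mol: Molecule) -> str:
    lines = [str(len(mol.atoms)), mol.name]
    for a in mol.atoms:
        lines.append(f"{a.label} {a.x:.6f} {a.y:.6f} {a.z:.6f}")
    return "\n".join(lines) + "\n"
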