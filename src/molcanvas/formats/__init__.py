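"""Chemical file I/O.

Readers: MOL (V2000), RXN, CML, XYZ, PDB (subset), CIF (P1 subset),
JCAMP-DX (subset), and the native JSON dialect.  Writers: MOL, CML,
JSON, XYZ.  :func:`detect_format` sniffs content (content beats any
filename hint); :func:`read_auto` combines the two.
"""

from __future__ import annotations

import json
import re

from ..errors import UnknownFormatError
from ..model import Molecule
from .cdjson import read_cdjson, write_cdjson
from .cif import read_cif
from .cml import read_cml, write_cml
from .document import InterchangeDocument
from .jcamp import read_jcamp
from .mol import read_mol, write_mol
from .pdb import read_pdb
from .rxn import read_rxn
from .xyz import read_xyz, write_xyz

__all__ = [
    "InterchangeDocument", "detect_format", "read_auto",
    "read_mol", "write_mol", "read_xyz", "write_xyz", "read_pdb",
    "read_cif", "read_cml", "write_cml", "read_rxn",
    "read_cdjson", "write_cdjson", "read_jcamp",
    "READABLE_FORMATS", "WRITABLE_FORMATS",
]

READABLE_FORMATS = ("mol", "rxn", "cml", "xyz", "pdb", "cif", "jcamp", "cdjson")
WRITABLE_FORMATS = ("mol", "cml", "cdjson", "xyz")

_EXT_HINTS = {
    "mol": "mol", "sdf": "mol", "rxn": "rxn", "cml": "cml", "xyz": "xyz",
    "pdb": "pdb", "ent": "pdb", "cif": "cif", "jdx": "jcamp", "dx": "jcamp",
    "jcamp": "jcamp", "json": "cdjson", "cdjson": "cdjson",
}

_PDB_RE = re.compile(r"^(ATOM  |HETATM)", re.M)
_XYZ_COORD_RE = re.compile(
    r"^\s*\S{1,3}(\s+[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?){3}\s*$")


def _looks_like_mol(text: str) -> bool:
    lines = text.replace("\r\n", "\n").split("\n")
    if len(lines) < 4:
        return False
    counts = lines[3]
    if "V2000" in counts or "V3000" in counts:
        return True
    # counts-line shape: two right-aligned 3-char integers
    if len(counts) >= 6:
        try:
            int(counts[0:3])
            int(counts[3:6])
            return "M  END" in text
        except ValueError:
            return False
    return False


def _looks_like_xyz(text: str) -> bool:
    lines = [ln for ln in text.replace("\r\n", "\n").split("\n")]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) < 3:
        return False
    try:
        n = int(lines[0].strip())
    except ValueError:
        return False
    coords = lines[2:]
    return len(coords) == n and all(_XYZ_COORD_RE.match(ln) for ln in coords)


def detect_format(text: str, filename_hint: str | None = None) -> str:
    """Sniff the chemical format of *text*.

    Content always wins; the filename extension only breaks ties where
    content alone is inconclusive.  Raises :class:`UnknownFormatError`
    when nothing matches.
    """
    stripped = text.lstrip()
    if stripped.startswith("{"):
        try:
            data = json.loads(text)
            if isinstance(data, dict) and ("a" in data or "m" in data):
                return "cdjson"
        except json.JSONDecodeError:
            pass
    if stripped.startswith("$RXN"):
        return "rxn"
    if "##TITLE" in text:
        return "jcamp"
    if stripped.startswith("<") and "<molecule" in text:
        return "cml"
    if "_cell_length_a" in text:
        return "cif"
    if _PDB_RE.search(text):
        return "pdb"
    if _looks_like_mol(text):
        return "mol"
    if _looks_like_xyz(text):
        return "xyz"
    if filename_hint:
        ext = filename_hint.rsplit(".", 1)[-1].lower()
        if ext in _EXT_HINTS:
            return _EXT_HINTS[ext]
    raise UnknownFormatError("could not determine chemical file format")


def read_auto(text: str,
              filename_hint: str | None = None) -> InterchangeDocument:
    """Detect the format and parse into an :class:`InterchangeDocument`."""
    fmt = detect_format(text, filename_hint)
    doc = InterchangeDocument(source_format=fmt)
    if fmt == "mol":
        doc.molecules = [read_mol(text)]
    elif fmt == "rxn":
        doc = read_rxn(text)
    elif fmt == "cml":
        doc.molecules = read_cml(text)
    elif fmt == "xyz":
        doc.molecules = [read_xyz(text)]
    elif fmt == "pdb":
        doc.molecules = [read_pdb(text)]
    elif fmt == "cif":
        mol, cell = read_cif(text)
        mol.unit_cell = cell  # attached for downstream supercell building
        doc.molecules = [mol]
    elif fmt == "jcamp":
        doc.spectra = [read_jcamp(text)]
    elif fmt == "cdjson":
        doc = read_cdjson(text)
    return doc


def write_format(mols: list[Molecule], fmt: str) -> str:
    """Serialize molecules to a writable format name."""
    if fmt == "mol":
        return write_mol(mols[0])
    if fmt == "cml":
        return write_cml(mols)
    if fmt == "cdjson":
        doc = InterchangeDocument(molecules=mols)
        return write_cdjson(doc)
    if fmt == "xyz":
        return write_xyz(mols[0])
    raise UnknownFormatError(
        f"cannot write format {fmt!r}; writable formats: "
        + ", ".join(WRITABLE_FORMATS))
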