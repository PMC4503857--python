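"""MDL RXN reader: $RXN header, counts line, embedded $MOL blocks."""

from __future__ import annotations

from ..errors import ParseError
from .document import InterchangeDocument
from .mol import read_mol

__all__ = ["read_rxn"]


def read_rxn(text: str) -> InterchangeDocument:
    lines = text.replace("\r\n", "\n").split("\n")
    if not lines or not lines[0].startswith("$RXN"):
        raise ParseError("missing $RXN header", 1)
    if len(lines) < 5:
        raise ParseError("RXN file truncated before counts line", len(lines))
    counts = lines[4]
    try:
        n_reactants = int(counts[0:3])
        n_products = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed RXN counts line: {counts!r}", 5) from None

    # split the remainder on $MOL markers; each chunk is one molfile
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in lines[5:]:
        if line.startswith("$MOL"):
            if current is not None:
                blocks.append(current)
            current = []
        elif current is not None:
            current.append(line)
    if current is not None:
        blocks.append(current)

    expected = n_reactants + n_products
    if len(blocks) != expected:
        raise ParseError(f"counts line promises {expected} molecules but "
                         f"found {len(blocks)} $MOL blocks", 5)
    doc = InterchangeDocument(source_format="rxn",
                              reaction_roles=(n_reactants, n_products))
    for block in blocks:
        doc.molecules.append(read_mol("\n".join(block)))
    return doc
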