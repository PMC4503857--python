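"""Packaged periodic-table data.

A single delimited table (``data/elements.tsv``) ships with the package
and is loaded once at import.  It covers elements 1-96 with:

* IUPAC standard atomic weights (amu),
* Cordero 2008 single-bond covalent radii (Å), used by distance-based
  bond deduction,
* default valence lists for main-group elements, used by the implicit
  hydrogen model (transition metals, lanthanides and actinides have an
  empty list and never receive implicit hydrogens),
* two RGB color tables: the classic CPK scheme and the Jmol scheme
  (the depiction default).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .errors import ElementNotFoundError

__all__ = ["ElementInfo", "lookup_element", "valence_for", "ELEMENTS"]


@dataclass(frozen=True)
class ElementInfo:
    symbol: str
    atomic_number: int
    atomic_mass: float          # unified amu (standard atomic weight)
    covalent_radius: float      # Å, Cordero 2008 single-bond
    default_valences: tuple[int, ...]
    cpk_color: tuple[int, int, int]
    jmol_color: tuple[int, int, int]


def _hex_rgb(s: str) -> tuple[int, int, int]:
    return int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16)


def _load_table() -> dict[str, ElementInfo]:
    text = (resources.files(__package__) / "data" / "elements.tsv").read_text()
    table: dict[str, ElementInfo] = {}
    for line in text.splitlines()[1:]:
        sym, z, mass, radius, valences, cpk, jmol = line.split("\t")
        table[sym] = ElementInfo(
            symbol=sym,
            atomic_number=int(z),
            atomic_mass=float(mass),
            covalent_radius=float(radius),
            default_valences=tuple(int(v) for v in valences.split(",")) if valences else (),
            cpk_color=_hex_rgb(cpk),
            jmol_color=_hex_rgb(jmol),
        )
    return table


ELEMENTS: dict[str, ElementInfo] = _load_table()

# Elements whose valence shifts with formal charge in the implicit-H
# model: pnictogens, chalcogens and halogens.  A cation gains bonding
# capacity (isoelectronic shift toward the next group), an anion loses
# it.  All other elements just lose |charge| capacity.
_CHARGE_SHIFT_FAMILY = frozenset(
    "N P As Sb Bi O S Se Te Po F Cl Br I At".split()
)


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an element symbol: first letter upper, rest lower."""
    s = symbol.strip()
    return s[:1].upper() + s[1:].lower()


def lookup_element(symbol: str) -> ElementInfo:
    """Return the :class:`ElementInfo` record for *symbol*.

    The lookup is case-insensitive (``"cl"`` resolves to Cl).  Raises
    :class:`ElementNotFoundError` for symbols outside elements 1-96.
    """
    if not symbol or not symbol.strip():
        raise ElementNotFoundError(symbol)
    key = normalize_symbol(symbol)
    try:
        return ELEMENTS[key]
    except KeyError:
        raise ElementNotFoundError(symbol) from None


def valence_for(symbol: str, charge: int = 0) -> int:
    """Target valence used by implicit-hydrogen deduction.

    For a neutral main-group atom this is the first entry of its default
    valence list.  Formal charge adjusts the target: for the N/O/S/P
    family (pnictogens, chalcogens, halogens) a positive charge adds to
    the valence and a negative charge subtracts, mirroring isoelectronic
    series (N+ behaves like C with valence 4, O- like F with valence 1);
    for every other element |charge| is subtracted.  The result is
    clamped at 0.  Elements with no tabulated valence (transition
    metals, f-block) return 0 and never receive implicit hydrogens.
    """
    info = lookup_element(symbol)
    if not info.default_valences:
        return 0
    base = info.default_valences[0]
    if info.symbol in _CHARGE_SHIFT_FAMILY:
        v = base + charge
    else:
        v = base - abs(charge)
    return max(0, v)
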