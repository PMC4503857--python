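"""Core molecule data structure.

A :class:`Molecule` stores atoms, bonds and rings in plain Python lists,
mirroring the array-backed container the 2D/3D drawing pipeline and the
cheminformatics algorithms all operate on.  The rings list is a cache
populated by ring perception; any structural mutation through the
provided mutators clears it.

2D drawing coordinates live in a y-down canvas space; the geometry
measurements (distance, angle, torsion) are pure Euclidean operations on
3D points and carry no axis convention of their own.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import elements
from .errors import DegenerateGeometryError, EmptyMoleculeError

__all__ = [
    "Atom", "Bond", "Ring", "Molecule",
    "BOND_ORDERS", "STEREO_NONE", "STEREO_PROTRUDING", "STEREO_RECESSED",
    "molecular_formula", "molecular_weight",
    "measure_distance", "measure_angle", "measure_torsion", "bounding_box",
]

#: Drawn bond orders: 0 = ionic/zero-order, 0.5 = half, 1.5 = resonance.
BOND_ORDERS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)

STEREO_NONE = "none"
STEREO_PROTRUDING = "protruding"   # wedge, toward the viewer
STEREO_RECESSED = "recessed"       # hash, away from the viewer


@dataclass
class Atom:
    label: str = "C"
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    charge: int = 0
    radicals: int = 0          # unpaired electron count
    lone_pairs: int = 0        # explicit lone-pair count
    implicit_h: int | None = None   # None = not yet deduced ("auto")
    is_query: bool = False

    def element(self) -> elements.ElementInfo:
        return elements.lookup_element(self.label)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Bond:
    begin: int
    end: int
    order: float = 1.0
    stereo: str = STEREO_NONE

    def __post_init__(self) -> None:
        if self.begin == self.end:
            raise ValueError("bond endpoints must differ")
        if float(self.order) not in BOND_ORDERS:
            raise ValueError(f"unsupported bond order {self.order!r}")
        if self.stereo not in (STEREO_NONE, STEREO_PROTRUDING, STEREO_RECESSED):
            raise ValueError(f"unsupported stereo {self.stereo!r}")
        self.order = float(self.order)

    def pair(self) -> tuple[int, int]:
        """Unordered endpoint pair."""
        return (self.begin, self.end) if self.begin < self.end else (self.end, self.begin)

    def valence_contribution(self) -> float:
        """Contribution of this bond to valence bookkeeping.

        Resonance (1.5) and half (0.5) bonds count as a full single bond;
        zero-order bonds count as nothing.  This keeps implicit-hydrogen
        counts integral and non-negative for any drawn structure.
        """
        if self.order == 0.0:
            return 0.0
        if self.order in (0.5, 1.5):
            return 1.0
        return self.order


@dataclass
class Ring:
    atom_indices: tuple[int, ...]
    bond_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    rings: list[Ring] = field(default_factory=list)
    name: str = ""

    # -- construction helpers ------------------------------------------
    def add_atom(self, atom: Atom | None = None, **kwargs) -> int:
        """Append an atom; returns its index.  Clears the ring cache."""
        self.atoms.append(atom if atom is not None else Atom(**kwargs))
        self.rings.clear()
        return len(self.atoms) - 1

    def add_bond(self, begin: int, end: int, order: float = 1.0,
                 stereo: str = STEREO_NONE) -> int:
        """Append a bond; returns its index.  Clears the ring cache.

        Rejects out-of-range indices and duplicate atom pairs.
        """
        n = len(self.atoms)
        if not (0 <= begin < n and 0 <= end < n):
            raise IndexError(f"bond ({begin}, {end}) out of range for {n} atoms")
        bond = Bond(begin, end, order, stereo)
        if bond.pair() in {b.pair() for b in self.bonds}:
            raise ValueError(f"duplicate bond between atoms {begin} and {end}")
        self.bonds.append(bond)
        self.rings.clear()
        return len(self.bonds) - 1

    def remove_atom(self, index: int) -> None:
        """Delete an atom, its incident bonds, and reindex.  Clears rings."""
        del self.atoms[index]
        kept = []
        for b in self.bonds:
            if index in (b.begin, b.end):
                continue
            kept.append(Bond(
                b.begin - (b.begin > index), b.end - (b.end > index),
                b.order, b.stereo))
        self.bonds = kept
        self.rings.clear()

    # -- graph views ----------------------------------------------------
    def neighbors(self, index: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.begin == index:
                out.append(b.end)
            elif b.end == index:
                out.append(b.begin)
        return out

    def incident_bonds(self, index: int) -> list[int]:
        return [i for i, b in enumerate(self.bonds) if index in (b.begin, b.end)]

    def degree(self, index: int) -> int:
        return len(self.incident_bonds(index))

    def bond_between(self, i: int, j: int) -> int | None:
        pair = (i, j) if i < j else (j, i)
        for k, b in enumerate(self.bonds):
            if b.pair() == pair:
                return k
        return None

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------
# Calculations
# ---------------------------------------------------------------------

def _implicit_h(atom: Atom, mol: Molecule, index: int) -> int:
    if atom.implicit_h is not None:
        return atom.implicit_h
    # deduce on the fly without mutating
    total = sum(mol.bonds[b].valence_contribution()
                for b in mol.incident_bonds(index))
    target = elements.valence_for(atom.label, atom.charge)
    return max(0, int(round(target - total)) - atom.radicals)


def _element_counts(mol: Molecule, count_implicit_h: bool) -> Counter:
    counts: Counter = Counter()
    for i, atom in enumerate(mol.atoms):
        info = atom.element()
        counts[info.symbol] += 1
        if count_implicit_h:
            counts["H"] += _implicit_h(atom, mol, i)
    if counts.get("H") == 0:
        del counts["H"]
    return counts


def molecular_formula(mol: Molecule, count_implicit_h: bool = True) -> str:
    """Hill-order molecular formula (C first, H second, rest alphabetical).

    With *count_implicit_h* the deduced implicit hydrogens of every atom
    are folded into the H count; otherwise only explicit atoms count.
    An empty molecule gives an empty string.
    """
    counts = _element_counts(mol, count_implicit_h)
    if not counts:
        return ""
    symbols = []
    if "C" in counts:
        symbols.append("C")
        if "H" in counts:
            symbols.append("H")
        symbols += sorted(s for s in counts if s not in ("C", "H"))
    else:
        symbols = sorted(counts)
    return "".join(
        s + (str(counts[s]) if counts[s] > 1 else "") for s in symbols)


def molecular_weight(mol: Molecule, count_implicit_h: bool = True) -> float:
    """Sum of standard atomic weights (amu) over atoms, optionally
    including deduced implicit hydrogens."""
    counts = _element_counts(mol, count_implicit_h)
    return float(sum(elements.lookup_element(s).atomic_mass * n
                     for s, n in counts.items()))


# ---------------------------------------------------------------------
# Geometry measurements
# ---------------------------------------------------------------------

Point = Sequence[float]


def _vec(p: Point) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape == (2,):
        v = np.append(v, 0.0)
    if not np.all(np.isfinite(v)):
        raise ValueError("point coordinates must be finite")
    return v


def measure_distance(p1: Point, p2: Point) -> float:
    """Euclidean distance between two points (2D points get z = 0)."""
    return float(np.linalg.norm(_vec(p2) - _vec(p1)))


def measure_angle(p1: Point, p2: Point, p3: Point) -> float:
    """Included angle at *p2*, in degrees within [0, 180]."""
    u = _vec(p1) - _vec(p2)
    v = _vec(p3) - _vec(p2)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle needs three distinct points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def measure_torsion(p1: Point, p2: Point, p3: Point, p4: Point) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking down the p2→p3 axis, a clockwise
    rotation carrying the p2-p1 projection onto the p3-p4 projection is
    positive.  The planar anti arrangement returns +180.
    """
    b1 = _vec(p2) - _vec(p1)
    b2 = _vec(p3) - _vec(p2)
    b3 = _vec(p4) - _vec(p3)
    if np.linalg.norm(b2) == 0.0:
        raise DegenerateGeometryError("torsion inner segment has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise DegenerateGeometryError("torsion needs non-collinear end segments")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def bounding_box(mol: Molecule) -> tuple[float, float, float, float]:
    """Tight axis-aligned 2D box over atom centers (labels excluded)."""
    if not mol.atoms:
        raise EmptyMoleculeError("bounding box of an empty molecule")
    xs = [a.x for a in mol.atoms]
    ys = [a.y for a in mol.atoms]
    return (min(xs), min(ys), max(xs), max(ys))
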