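"""Cheminformatics algorithms over the molecule graph.

* distance-based covalent bond deduction from 3D (or 2D) coordinates,
* implicit hydrogen deduction from the valence model,
* splitting into connected components and deep copying,
* SSSR ring perception (a minimum cycle basis),
* triclinic unit cells and supercell construction.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .errors import InvalidCellError
from .model import Atom, Bond, Molecule, Ring

__all__ = [
    "UnitCell", "deduce_covalent_bonds", "deduce_implicit_hydrogens",
    "split_disconnected", "copy_molecule", "perceive_rings_sssr",
    "build_supercell", "MIN_BOND_DISTANCE",
]

#: Pairs closer than this (Å) are treated as overlapping atoms, not bonds.
MIN_BOND_DISTANCE = 0.4


def deduce_covalent_bonds(mol: Molecule, tolerance_factor: float = 1.1) -> Molecule:
    """Create single bonds between atoms within covalent-radius reach.

    A bond of order 1 is added between every atom pair whose distance d
    satisfies ``MIN_BOND_DISTANCE <= d <= tolerance_factor * (r_A + r_B)``
    with Cordero covalent radii r.  Existing bonds are preserved and
    never duplicated, which makes the operation idempotent.  Modifies
    and returns *mol*.
    """
    radii = np.array([a.element().covalent_radius for a in mol.atoms])
    if len(mol.atoms) < 2:
        return mol
    pos = np.array([[a.x, a.y, a.z] for a in mol.atoms])
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cutoff = tolerance_factor * (radii[:, None] + radii[None, :])
    existing = {b.pair() for b in mol.bonds}
    n = len(mol.atoms)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in existing:
                continue
            if MIN_BOND_DISTANCE <= dist[i, j] <= cutoff[i, j]:
                mol.add_bond(i, j, 1.0)
    return mol


def deduce_implicit_hydrogens(mol: Molecule) -> Molecule:
    """Store the implicit hydrogen count on every atom.

    implicit_h = max(0, target_valence(label, charge)
                        - sum of incident drawn bond orders
                        - radical count)

    where resonance and half bonds count as one and zero-order bonds as
    zero (see :meth:`Bond.valence_contribution`).  Modifies and returns
    *mol*.
    """
    totals = [0.0] * len(mol.atoms)
    for b in mol.bonds:
        contrib = b.valence_contribution()
        totals[b.begin] += contrib
        totals[b.end] += contrib
    for i, atom in enumerate(mol.atoms):
        target = elements.valence_for(atom.label, atom.charge)
        atom.implicit_h = max(0, int(round(target - totals[i])) - atom.radicals)
    return mol


def copy_molecule(mol: Molecule) -> Molecule:
    """Deep, fully independent copy (atoms, bonds, ring cache, name)."""
    return _copy.deepcopy(mol)


def _components(mol: Molecule) -> list[list[int]]:
    """Connected components as sorted atom-index lists, ordered by first
    appearance.  Every drawn bond connects, including zero-order ones."""
    n = len(mol.atoms)
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in mol.bonds:
        adj[b.begin].append(b.end)
        adj[b.end].append(b.begin)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def split_disconnected(mol: Molecule) -> list[Molecule]:
    """Split into connected components of the atom-bond graph.

    Each component becomes a self-contained molecule with reindexed
    bonds; components appear in order of their lowest original atom
    index, and atom order inside a component follows the original.
    Zero-order (ionic) bonds count as connections, so a drawn ion pair
    stays in one component.
    """
    comps = _components(mol)
    out = []
    for comp in comps:
        remap = {old: new for new, old in enumerate(comp)}
        sub = Molecule(name=mol.name)
        sub.atoms = [_copy.deepcopy(mol.atoms[i]) for i in comp]
        sub.bonds = [Bond(remap[b.begin], remap[b.end], b.order, b.stereo)
                     for b in mol.bonds if b.begin in remap]
        out.append(sub)
    return out


# ---------------------------------------------------------------------
# SSSR ring perception
# ---------------------------------------------------------------------

def _adjacency(mol: Molecule) -> list[list[tuple[int, int]]]:
    adj: list[list[tuple[int, int]]] = [[] for _ in mol.atoms]
    for k, b in enumerate(mol.bonds):
        adj[b.begin].append((b.end, k))
        adj[b.end].append((b.begin, k))
    return adj


def _horton_candidates(mol: Molecule) -> list[tuple[int, ...]]:
    """Horton's candidate set: for every vertex v and bond (x, y), the
    cycle shortest-path(v, x) + (x, y) + shortest-path(y, v) whenever the
    two paths meet only at v.  The minimum cycle basis lives inside this
    family; candidates are returned sorted by (size, atom indices)."""
    n = len(mol.atoms)
    adj = _adjacency(mol)
    # BFS trees from every vertex (lowest-neighbor-first for determinism)
    parent = [[-1] * n for _ in range(n)]
    dist = [[-1] * n for _ in range(n)]
    for v in range(n):
        dist[v][v] = 0
        frontier = [v]
        while frontier:
            nxt = []
            for i in frontier:
                for j, _ in sorted(adj[i]):
                    if dist[v][j] == -1:
                        dist[v][j] = dist[v][i] + 1
                        parent[v][j] = i
                        nxt.append(j)
            frontier = nxt

    def path(v: int, x: int) -> list[int] | None:
        if dist[v][x] == -1:
            return None
        out = [x]
        while out[-1] != v:
            out.append(parent[v][out[-1]])
        return out[::-1]  # v ... x

    candidates: set[tuple[int, ...]] = set()
    for b in mol.bonds:
        x, y = b.begin, b.end
        for v in range(n):
            px, py = path(v, x), path(v, y)
            if px is None or py is None:
                continue
            if set(px) & set(py) != {v}:
                continue  # paths must meet only at v
            cycle = px + py[::-1][:-1]
            if len(cycle) >= 3:
                candidates.add(_canonical_cycle(cycle))
    return sorted(candidates, key=lambda c: (len(c), c))


def _fundamental_cycles(mol: Molecule) -> list[tuple[int, ...]]:
    """Cycle basis from a BFS spanning forest (completeness fallback)."""
    n = len(mol.atoms)
    adj = _adjacency(mol)
    parent = [-1] * n
    depth = [-1] * n
    tree_bonds: set[int] = set()
    for root in range(n):
        if depth[root] != -1:
            continue
        depth[root] = 0
        frontier = [root]
        while frontier:
            nxt = []
            for i in frontier:
                for j, k in sorted(adj[i]):
                    if depth[j] == -1:
                        depth[j] = depth[i] + 1
                        parent[j] = i
                        tree_bonds.add(k)
                        nxt.append(j)
            frontier = nxt
    cycles = []
    for k, b in enumerate(mol.bonds):
        if k in tree_bonds:
            continue
        x, y = b.begin, b.end
        px, py = [x], [y]
        while depth[px[-1]] > depth[py[-1]]:
            px.append(parent[px[-1]])
        while depth[py[-1]] > depth[px[-1]]:
            py.append(parent[py[-1]])
        while px[-1] != py[-1]:
            px.append(parent[px[-1]])
            py.append(parent[py[-1]])
        cycles.append(_canonical_cycle(px + py[:-1][::-1]))
    return cycles


def _canonical_cycle(atoms: list[int]) -> tuple[int, ...]:
    """Rotate/reflect a cycle so it starts at its lowest atom index and
    proceeds toward the lower of its two neighbors."""
    k = len(atoms)
    i0 = atoms.index(min(atoms))
    fwd = tuple(atoms[(i0 + i) % k] for i in range(k))
    rev = tuple(atoms[(i0 - i) % k] for i in range(k))
    return min(fwd, rev)


def _cycle_edge_vector(cycle: tuple[int, ...], edge_index: dict[tuple[int, int], int],
                       m: int) -> np.ndarray:
    vec = np.zeros(m, dtype=np.uint8)
    for i in range(len(cycle)):
        a, b = cycle[i], cycle[(i + 1) % len(cycle)]
        vec[edge_index[(a, b) if a < b else (b, a)]] = 1
    return vec


def perceive_rings_sssr(mol: Molecule) -> Molecule:
    """Populate ``mol.rings`` with a Smallest Set of Smallest Rings.

    The ring count always equals the circuit rank E - V + C.  Candidates
    come from Horton's family (shortest cycles through every vertex-bond
    pair, which contains a minimum cycle basis); rings are selected
    smallest-first, keeping only cycles linearly independent over GF(2),
    with ties broken by (size, lowest atom indices).  A spanning-forest
    fundamental basis tops up the rare residue of the rank left by
    shortest-path tie artifacts.  Modifies and returns *mol*; acyclic
    graphs get an empty ring list.
    """
    mol.rings = []
    m = len(mol.bonds)
    rank = m - len(mol.atoms) + len(_components(mol))
    if rank <= 0:
        return mol

    edge_index = {b.pair(): k for k, b in enumerate(mol.bonds)}
    basis: list[np.ndarray] = []       # rows in reduced row-echelon order
    pivots: list[int] = []
    chosen: list[tuple[int, ...]] = []

    def consider(cycle: tuple[int, ...]) -> None:
        vec = _cycle_edge_vector(cycle, edge_index, m)
        for row, piv in zip(basis, pivots):
            if vec[piv]:
                vec ^= row
        if not vec.any():
            return
        piv = int(np.argmax(vec))
        basis.append(vec)
        pivots.append(piv)
        chosen.append(cycle)

    for cycle in _horton_candidates(mol):
        consider(cycle)
        if len(chosen) == rank:
            break
    if len(chosen) < rank:
        for cycle in sorted(_fundamental_cycles(mol),
                            key=lambda c: (len(c), c)):
            consider(cycle)
            if len(chosen) == rank:
                break

    for cycle in chosen:
        bond_idx = tuple(
            edge_index[(cycle[i], cycle[(i + 1) % len(cycle)])
                       if cycle[i] < cycle[(i + 1) % len(cycle)]
                       else (cycle[(i + 1) % len(cycle)], cycle[i])]
            for i in range(len(cycle)))
        mol.rings.append(Ring(cycle, bond_idx))
    return mol


# ---------------------------------------------------------------------
# Unit cells and supercells
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180)")
        if self.volume() <= 0 or not math.isfinite(self.volume()):
            raise InvalidCellError("cell angles give non-positive volume")

    def matrix(self) -> np.ndarray:
        """Fractional→Cartesian transformation, columns = cell vectors.

        Standard crystallographic convention: **a** along x, **b** in
        the xy-plane.
        """
        al, be, ga = (math.radians(v) for v in (self.alpha, self.beta, self.gamma))
        cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
        sin_ga = math.sin(ga)
        cx = self.c * cos_be
        cy = self.c * (cos_al - cos_be * cos_ga) / sin_ga
        cz2 = self.c ** 2 - cx ** 2 - cy ** 2
        cz = math.sqrt(cz2) if cz2 > 0 else 0.0
        return np.array([
            [self.a, self.b * cos_ga, cx],
            [0.0,    self.b * sin_ga, cy],
            [0.0,    0.0,             cz],
        ])

    def volume(self) -> float:
        al, be, ga = (math.radians(v) for v in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        arg = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return (self.matrix() @ np.asarray(frac, dtype=float).T).T \
            + np.asarray(self.origin)


def build_supercell(mol: Molecule, cell: UnitCell,
                    na: int = 1, nb: int = 1, nc: int = 1) -> Molecule:
    """Replicate a fractional-coordinate molecule na×nb×nc and return a
    new Cartesian-coordinate molecule.

    Atom coordinates of *mol* are fractional in [0, 1); each of the
    na·nb·nc cell translations produces a full copy (atoms on cell
    boundaries are duplicated, not merged), so the result has
    ``len(mol) * na * nb * nc`` atoms.  Bonds are replicated within each
    image; no bonds are created across images.
    """
    if min(na, nb, nc) < 1:
        raise ValueError("supercell multipliers must be >= 1")
    out = Molecule(name=mol.name)
    frac = np.array([[a.x, a.y, a.z] for a in mol.atoms], dtype=float) \
        if mol.atoms else np.zeros((0, 3))
    for ia in range(na):
        for ib in range(nb):
            for ic in range(nc):
                offset = len(out.atoms)
                shift = np.array([ia, ib, ic], dtype=float)
                cart = cell.to_cartesian(frac + shift) if len(frac) else frac
                for atom, xyz in zip(mol.atoms, cart):
                    new = _copy.deepcopy(atom)
                    new.x, new.y, new.z = map(float, xyz)
                    out.atoms.append(new)
                for b in mol.bonds:
                    out.bonds.append(Bond(b.begin + offset, b.end + offset,
                                          b.order, b.stereo))
    return out
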