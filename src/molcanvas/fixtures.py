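"""Deterministic fixture generation.

Toy molecules with hand-set 2D/3D coordinates, random small molecules
that respect the valence caps of the implicit-hydrogen model, random
graphs for ring-perception stress tests, and synthetic spectra built
from Gaussian/Lorentzian lineshapes with generator-known areas — the
ground truth the integration tests measure against.  Everything is
reproducible from an integer seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np

from . import formats
from .elements import valence_for
from .model import Atom, Bond, Molecule
from .spectra import Spectrum

__all__ = [
    "water_2d", "water_xyz", "methane_xyz", "ethane_xyz", "benzene",
    "naphthalene", "biphenyl", "hexane", "nacl_pair", "pyridinium",
    "random_molecule", "random_graph_molecule",
    "gaussian_mixture_spectrum", "lorentzian", "gaussian",
    "jcamp_text", "water_pdb_text", "nacl_cif_text", "generate_fixtures",
]

_COS30 = math.cos(math.pi / 6)


# ---------------------------------------------------------------------
# Toy molecules
# ---------------------------------------------------------------------

def water_2d() -> Molecule:
    """Bent water in 2D drawing coordinates (y-down, O at the bottom)."""
    mol = Molecule(name="water")
    mol.add_atom(label="O", x=0.0, y=0.0)
    mol.add_atom(label="H", x=-_COS30, y=-0.5)
    mol.add_atom(label="H", x=_COS30, y=-0.5)
    mol.add_bond(0, 1)
    mol.add_bond(0, 2)
    return mol


def water_xyz() -> Molecule:
    """Water with 3D coordinates and no bonds (bond-deduction input)."""
    mol = Molecule(name="water")
    mol.add_atom(label="O", x=0.0, y=0.0, z=0.0)
    mol.add_atom(label="H", x=0.96, y=0.0, z=0.0)
    mol.add_atom(label="H", x=-0.24, y=0.93, z=0.0)
    return mol


def methane_xyz() -> Molecule:
    """Tetrahedral methane, C-H = 1.09 Å, no bonds."""
    mol = Molecule(name="methane")
    a = 1.09 / math.sqrt(3)
    mol.add_atom(label="C")
    for sx, sy, sz in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        mol.add_atom(label="H", x=sx * a, y=sy * a, z=sz * a)
    return mol


def ethane_xyz() -> Molecule:
    """Staggered ethane, C-C = 1.54 Å, C-H = 1.09 Å, no bonds."""
    mol = Molecule(name="ethane")
    mol.add_atom(label="C", x=0.0, y=0.0, z=0.0)
    mol.add_atom(label="C", x=1.54, y=0.0, z=0.0)
    ax = 1.09 * math.cos(math.radians(180 - 109.5))
    r = 1.09 * math.sin(math.radians(180 - 109.5))
    for k in range(3):
        ang = math.radians(120 * k)
        mol.add_atom(label="H", x=-ax, y=r * math.cos(ang),
                     z=r * math.sin(ang))
    for k in range(3):
        ang = math.radians(120 * k + 60)
        mol.add_atom(label="H", x=1.54 + ax, y=r * math.cos(ang),
                     z=r * math.sin(ang))
    return mol


def _hexagon(cx: float, cy: float, start_deg: float = 30.0,
             r: float = 1.4) -> list[tuple[float, float]]:
    return [(cx + r * math.cos(math.radians(start_deg + 60 * k)),
             cy + r * math.sin(math.radians(start_deg + 60 * k)))
            for k in range(6)]


def benzene() -> Molecule:
    """Benzene skeleton: 6 carbons, alternating drawn 2/1 bond orders."""
    mol = Molecule(name="benzene")
    for x, y in _hexagon(0.0, 0.0):
        mol.add_atom(label="C", x=x, y=y)
    for k in range(6):
        mol.add_bond(k, (k + 1) % 6, order=2.0 if k % 2 == 0 else 1.0)
    return mol


def naphthalene() -> Molecule:
    """Two fused six-membered rings sharing one bond (C10, Kekulé)."""
    h = 1.4 * _COS30
    coords = [(0.0, 0.7), (-h, 1.4), (-2 * h, 0.7), (-2 * h, -0.7),
              (-h, -1.4), (0.0, -0.7), (h, -1.4), (2 * h, -0.7),
              (2 * h, 0.7), (h, 1.4)]
    mol = Molecule(name="naphthalene")
    for x, y in coords:
        mol.add_atom(label="C", x=x, y=y)
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
             (5, 6), (6, 7), (7, 8), (8, 9), (9, 0)]
    doubles = {(1, 2), (3, 4), (5, 0), (6, 7), (8, 9)}
    for a, b in edges:
        mol.add_bond(a, b, order=2.0 if (a, b) in doubles else 1.0)
    return mol


def biphenyl() -> Molecule:
    """Two benzene rings joined by a single (non-ring) bridge bond."""
    mol = Molecule(name="biphenyl")
    for x, y in _hexagon(-2.1, 0.0, start_deg=0.0):
        mol.add_atom(label="C", x=x, y=y)
    for x, y in _hexagon(2.1, 0.0, start_deg=0.0):
        mol.add_atom(label="C", x=x, y=y)
    for base in (0, 6):
        for k in range(6):
            mol.add_bond(base + k, base + (k + 1) % 6,
                         order=2.0 if k % 2 else 1.0)
    # ring 1 vertex at (-0.7, 0) is index 0; ring 2 vertex at (0.7, 0)
    # is the one at angle 180 deg, index 6 + 3
    mol.add_bond(0, 9, order=1.0)
    return mol


def hexane() -> Molecule:
    """n-hexane zigzag (acyclic control for ring perception)."""
    mol = Molecule(name="hexane")
    for k in range(6):
        mol.add_atom(label="C", x=k * 1.4 * _COS30,
                     y=0.7 if k % 2 else 0.0)
        if k:
            mol.add_bond(k - 1, k)
    return mol


def nacl_pair() -> Molecule:
    """Na-Cl ion pair held together by a drawn zero-order bond."""
    mol = Molecule(name="sodium chloride")
    mol.add_atom(label="Na", x=0.0, y=0.0, charge=1)
    mol.add_atom(label="Cl", x=2.8, y=0.0, charge=-1)
    mol.add_bond(0, 1, order=0.0)
    return mol


def pyridinium() -> Molecule:
    """Pyridinium cation: N+ in a Kekulé six-ring (one implicit H on N)."""
    mol = Molecule(name="pyridinium")
    for k, (x, y) in enumerate(_hexagon(0.0, 0.0)):
        mol.add_atom(label="N" if k == 0 else "C", x=x, y=y,
                     charge=1 if k == 0 else 0)
    for k in range(6):
        mol.add_bond(k, (k + 1) % 6, order=2.0 if k % 2 == 0 else 1.0)
    return mol


def equilibrium_reaction_drawing(width: float = 460, height: float = 180):
    """Water self-ionization sketch: two structures, equilibrium arrow
    with text above — a composed-scene fixture for golden-file tests."""
    from .depict import build_drawing, render_arrow
    from .depict.specs import VisualSpecs
    specs = VisualSpecs()
    left = build_drawing(water_2d(), 160, height, specs)
    right = build_drawing(nacl_pair(), 160, height, specs)
    scene = left
    scene.width = width
    for p in right.primitives:
        for attr in ("x", "x1", "x2"):
            if hasattr(p, attr):
                setattr(p, attr, getattr(p, attr) + (width - 160))
        if hasattr(p, "points"):
            p.points = [(x + (width - 160), y) for x, y in p.points]
    scene.primitives.extend(right.primitives)
    scene.primitives.extend(render_arrow(
        "equilibrium", (180, height / 2), (width - 180, height / 2),
        specs, top_text="Δ"))
    return scene


def bracketed_ion_drawing(width: float = 220, height: float = 220):
    """Sulfate-like ion in brackets with a 2- annotation (golden fixture)."""
    from .depict import build_drawing, render_bracket
    from .depict.specs import VisualSpecs
    specs = VisualSpecs()
    mol = Molecule(name="sulfate")
    mol.add_atom(label="S", x=0.0, y=0.0)
    for k, (dx, dy) in enumerate(((1.4, 0), (-1.4, 0), (0, 1.4), (0, -1.4))):
        mol.add_atom(label="O", x=dx, y=dy, charge=-1 if k < 2 else 0)
        mol.add_bond(0, k + 1, order=1.0 if k < 2 else 2.0)
    drawing = build_drawing(mol, width, height, specs)
    box = drawing.extent()
    drawing.primitives.extend(render_bracket(box, specs, annotation="2−"))
    return drawing


# ---------------------------------------------------------------------
# Random generators
# ---------------------------------------------------------------------

_RANDOM_ELEMENTS = ("C", "C", "C", "C", "N", "O", "S", "P", "F", "Cl", "Br")


def random_molecule(rng: np.random.Generator, n_atoms: int = 8,
                    charges: bool = True, stereo: bool = True) -> Molecule:
    """A random connected molecule respecting valence caps.

    Atoms are drawn from common organic elements with random 2D
    coordinates; a spanning tree guarantees connectivity and extra
    edges/bond orders are accepted only while every endpoint stays
    within its target valence (so implicit-H deduction never clamps).
    Orders are limited to 1/2/3 so the result survives every writable
    format.
    """
    mol = Molecule(name="random")
    for i in range(n_atoms):
        label = _RANDOM_ELEMENTS[rng.integers(len(_RANDOM_ELEMENTS))]
        charge = 0
        if charges and rng.random() < 0.15:
            charge = int(rng.choice([-1, 1]))
            if valence_for(label, charge) == 0:
                charge = 0
        mol.add_atom(label=label, charge=charge,
                     x=float(rng.uniform(-5, 5)),
                     y=float(rng.uniform(-5, 5)))
    used = [0.0] * n_atoms
    cap = [float(valence_for(a.label, a.charge)) or 1.0 for a in mol.atoms]

    def try_bond(a: int, b: int, order: float) -> bool:
        if used[a] + order > cap[a] or used[b] + order > cap[b]:
            return False
        if mol.bond_between(a, b) is not None:
            return False
        st = "none"
        if stereo and order == 1.0 and rng.random() < 0.1:
            st = str(rng.choice(["protruding", "recessed"]))
        mol.add_bond(a, b, order, st)
        used[a] += order
        used[b] += order
        return True

    # spanning tree: attach each new atom to a random atom with spare
    # valence (one always exists; see relabel below)
    for i in range(1, n_atoms):
        open_atoms = [j for j in range(i) if used[j] < cap[j]]
        j = int(open_atoms[rng.integers(len(open_atoms))])
        try_bond(j, i, 1.0)
        # keep the invariant that some atom stays open for the next one
        if i < n_atoms - 1 and all(used[k] >= cap[k] for k in range(i + 1)):
            mol.atoms[i].label = "C"
            mol.atoms[i].charge = 0
            cap[i] = 4.0
    # ring closures / multiple bonds, still under the caps
    for _ in range(n_atoms):
        a, b = int(rng.integers(n_atoms)), int(rng.integers(n_atoms))
        if a != b:
            try_bond(min(a, b), max(a, b),
                     float(rng.choice([1.0, 1.0, 2.0, 3.0])))
    return mol


def random_graph_molecule(rng: np.random.Generator, n_atoms: int = 10,
                          extra_edges: int | None = None) -> Molecule:
    """A random connected graph (all C, order 1) for ring perception."""
    n = max(1, n_atoms)
    mol = Molecule(name="graph")
    for i in range(n):
        mol.add_atom(label="C", x=float(rng.uniform(-5, 5)),
                     y=float(rng.uniform(-5, 5)))
        if i:
            mol.add_bond(int(rng.integers(i)), i)
    if extra_edges is None:
        extra_edges = int(rng.integers(0, max(2, n // 2) + 1))
    tries = 0
    while extra_edges > 0 and tries < 50 * n:
        tries += 1
        a, b = int(rng.integers(n)), int(rng.integers(n))
        if a != b and mol.bond_between(a, b) is None:
            mol.add_bond(min(a, b), max(a, b))
            extra_edges -= 1
    return mol


# ---------------------------------------------------------------------
# Synthetic spectra
# ---------------------------------------------------------------------

def gaussian(x: np.ndarray, center: float, area: float,
             fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2)


def lorentzian(x: np.ndarray, center: float, area: float,
               fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return area / math.pi * hw / ((x - center) ** 2 + hw ** 2)


def gaussian_mixture_spectrum(
        peaks: list[tuple[float, float, float]],
        domain: tuple[float, float] = (0.0, 10.0),
        n_points: int = 2000, noise: float = 0.0,
        rng: np.random.Generator | None = None,
        kind: str = "nmr", shape: str = "gaussian") -> Spectrum:
    """Sum of lineshapes; *peaks* are (center, area, fwhm) triples.

    The requested areas are exact analytic areas of the lineshapes, so
    tests can compare measured integrals against generator truth.
    """
    x = np.linspace(domain[0], domain[1], n_points)
    y = np.zeros_like(x)
    fn = gaussian if shape == "gaussian" else lorentzian
    for center, area, fwhm in peaks:
        y += fn(x, center, area, fwhm)
    if noise > 0.0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0.0, noise, size=y.shape)
    return Spectrum(x=x, y=y, kind=kind, x_units="PPM",
                    y_units="ARBITRARY UNITS", title="synthetic")


# ---------------------------------------------------------------------
# JCAMP emission (fixtures only; the package reader is the consumer)
# ---------------------------------------------------------------------

_SQZ_POS = "@ABCDEFGHI"
_DIF_POS = "%JKLMNOPQR"
_DIF_NEG = "%jklmnopqr"
_DUP = " STUVWXYZs"


def _sqz(v: int) -> str:
    s = str(abs(v))
    head = _SQZ_POS[int(s[0])] if v >= 0 else "abcdefghi"[int(s[0]) - 1] \
        if s[0] != "0" else "@"
    return head + s[1:]


def _dif(d: int) -> str:
    s = str(abs(d))
    head = _DIF_POS[int(s[0])] if d >= 0 else _DIF_NEG[int(s[0])]
    return head + s[1:]


def jcamp_text(title: str, x: np.ndarray, y: np.ndarray, *,
               form: str = "affn", data_type: str = "NMR SPECTRUM",
               x_units: str = "PPM", y_units: str = "ARBITRARY UNITS",
               yfactor: float | None = None, per_line: int = 8) -> str:
    """Serialize an evenly spaced series as JCAMP-DX text.

    ``form="affn"`` writes plain numbers; ``form="dif"`` writes
    SQZ/DIF/DUP compressed lines.  Both encode the same integer raw
    ordinates (y / yfactor rounded), so the two decode identically.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if yfactor is None:
        peak = float(np.max(np.abs(y))) or 1.0
        yfactor = peak / 32000.0
    raw = np.rint(y / yfactor).astype(int)
    head = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        f"##DATA TYPE={data_type}",
        f"##XUNITS={x_units}",
        f"##YUNITS={y_units}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor:.10g}",
        f"##FIRSTX={x[0]:.10g}",
        f"##LASTX={x[-1]:.10g}",
        f"##NPOINTS={len(x)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    lines = []
    if form == "affn":
        for start in range(0, len(raw), per_line):
            chunk = raw[start:start + per_line]
            lines.append(" ".join([f"{x[start]:.6g}"]
                                  + [str(v) for v in chunk]))
    elif form == "dif":
        start = 0
        prev_last: int | None = None
        while start < len(raw):
            chunk = list(raw[start:start + per_line])
            parts = [f"{x[start]:.6g}"]
            if prev_last is None:
                parts.append(_sqz(chunk[0]))
                seq_prev = chunk[0]
                diffs = [chunk[k] - chunk[k - 1] for k in range(1, len(chunk))]
            else:
                parts.append(_sqz(prev_last))  # DIF checkpoint
                seq_prev = prev_last
                diffs = [chunk[0] - prev_last] + [
                    chunk[k] - chunk[k - 1] for k in range(1, len(chunk))]
            k = 0
            while k < len(diffs):
                run = 1
                while (k + run < len(diffs) and diffs[k + run] == diffs[k]
                       and run < 9):
                    run += 1
                parts.append(_dif(diffs[k]))
                if run > 1:
                    parts.append(_DUP[run])
                k += run
            lines.append(" ".join(parts))
            prev_last = int(chunk[-1])
            start += per_line
    else:
        raise ValueError(f"unknown JCAMP form {form!r}")
    return "\n".join(head + lines + ["##END="]) + "\n"


def water_pdb_text() -> str:
    """Hand-built 3-atom HETATM water with CONECT records."""
    return (
        "HEADER    FIXTURE\n"
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  "
        "1.00  0.00           O\n"
        "HETATM    2  H1  HOH A   1       0.960   0.000   0.000  "
        "1.00  0.00           H\n"
        "HETATM    3  H2  HOH A   1      -0.240   0.930   0.000  "
        "1.00  0.00           H\n"
        "CONECT    1    2    3\n"
        "CONECT    2    1\n"
        "CONECT    3    1\n"
        "END\n")


def nacl_cif_text() -> str:
    """Minimal P1 rock-salt CIF: cubic a=5.64 Å, 2 sites."""
    return (
        "data_nacl\n"
        "_cell_length_a 5.6400(2)\n"
        "_cell_length_b 5.64\n"
        "_cell_length_c 5.64\n"
        "_cell_angle_alpha 90\n"
        "_cell_angle_beta 90\n"
        "_cell_angle_gamma 90\n"
        "loop_\n"
        "_atom_site_label\n"
        "_atom_site_type_symbol\n"
        "_atom_site_fract_x\n"
        "_atom_site_fract_y\n"
        "_atom_site_fract_z\n"
        "Na1 Na 0.0000 0.0000 0.0000\n"
        "Cl1 Cl 0.5000 0.5000 0.5000\n")


# ---------------------------------------------------------------------
# File tree generation
# ---------------------------------------------------------------------

def generate_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the full fixture tree and return its manifest.

    Deterministic from *seed*: toy molecules in every writable format,
    hand-built PDB/CIF fixtures, random molecules for round-trip tests,
    and synthetic NMR spectra (AFFN + DIF twins) whose true peak areas
    are recorded in ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": {}, "true_areas": {}}

    def put(name: str, text: str) -> None:
        (out / name).write_text(text)
        digest = hashlib.sha256(text.encode()).hexdigest()[:16]
        manifest["files"][name] = digest

    toys = [water_2d(), methane_xyz(), benzene(), naphthalene(),
            biphenyl(), hexane(), nacl_pair()]
    for mol in toys:
        stem = mol.name.replace(" ", "_")
        writable = mol if all(b.order in (1.0, 2.0, 3.0) for b in mol.bonds) \
            else None
        if writable is not None:
            put(f"{stem}.mol", formats.write_mol(mol))
            put(f"{stem}.cml", formats.write_cml(mol))
        put(f"{stem}.cdjson", formats.write_cdjson(mol))
        put(f"{stem}.xyz", formats.write_xyz(mol))
    put("water.pdb", water_pdb_text())
    put("nacl.cif", nacl_cif_text())

    for k in range(8):
        mol = random_molecule(rng, n_atoms=int(rng.integers(3, 12)))
        put(f"random_{k}.cdjson", formats.write_cdjson(mol))

    peaks = [(3.0, 1.0, 0.15), (7.0, 2.0, 0.2)]
    spec = gaussian_mixture_spectrum(peaks, domain=(0.0, 10.0),
                                     n_points=2000)
    put("two_peak_nmr.jdx", jcamp_text("two-peak synthetic", spec.x, spec.y))
    put("two_peak_nmr_dif.jdx",
        jcamp_text("two-peak synthetic", spec.x, spec.y, form="dif"))
    manifest["true_areas"]["two_peak_nmr.jdx"] = [
        {"center": c, "area": a, "fwhm": w} for c, a, w in peaks]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
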