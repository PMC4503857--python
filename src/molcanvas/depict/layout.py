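"""Geometric layout: scale-to-fit, label/lone-pair placement, bond glyphs.

All screen coordinates are y-down.  Angles are measured in degrees with
atan2(dy, dx) on screen axes, so "above" an atom is 270° and "below" is
90°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ..errors import DegenerateGeometryError, EmptyMoleculeError
from ..model import Molecule, bounding_box
from .primitives import Line, Polygon
from .specs import VisualSpecs

__all__ = ["Transform", "scale_to_fit", "place_implicit_h_label",
           "place_lone_pairs", "layout_bond"]

#: Candidate label sides in tie-break priority order, with screen angles.
LABEL_SIDES = (("right", 0.0), ("left", 180.0),
               ("above", 270.0), ("below", 90.0))


@dataclass(frozen=True)
class Transform:
    """Similarity transform screen = scale * model + (tx, ty)."""

    scale: float
    tx: float
    ty: float

    def apply(self, x: float, y: float) -> tuple[float, float]:
        return self.scale * x + self.tx, self.scale * y + self.ty


def scale_to_fit(mol: Molecule, width: float, height: float,
                 specs: VisualSpecs) -> Transform:
    """Center a molecule on the canvas and scale it to fit.

    The scale is the smallest of: the horizontal fit, the vertical fit,
    and the bond-length normalization that maps the median drawn bond to
    ``specs.bond_length`` — so drawings are never blown up beyond the
    house bond length, and never overflow the margins.  A molecule with
    no spatial extent and no bonds (a single atom) is placed at the
    canvas center at unit scale.
    """
    if not mol.atoms:
        raise EmptyMoleculeError("cannot fit an empty molecule")
    if width <= 2 * specs.margin or height <= 2 * specs.margin:
        raise ValueError("canvas smaller than twice the margin")
    min_x, min_y, max_x, max_y = bounding_box(mol)
    box_w, box_h = max_x - min_x, max_y - min_y

    candidates = []
    if box_w > 0:
        candidates.append((width - 2 * specs.margin) / box_w)
    if box_h > 0:
        candidates.append((height - 2 * specs.margin) / box_h)
    lengths = sorted(
        math.hypot(mol.atoms[b.end].x - mol.atoms[b.begin].x,
                   mol.atoms[b.end].y - mol.atoms[b.begin].y)
        for b in mol.bonds)
    lengths = [l for l in lengths if l > 0]
    if lengths:
        median = lengths[len(lengths) // 2] if len(lengths) % 2 \
            else 0.5 * (lengths[len(lengths) // 2 - 1]
                        + lengths[len(lengths) // 2])
        candidates.append(specs.bond_length / median)
    s = min(candidates) if candidates else 1.0
    cx, cy = 0.5 * (min_x + max_x), 0.5 * (min_y + max_y)
    return Transform(s, width / 2 - s * cx, height / 2 - s * cy)


def _angular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def place_implicit_h_label(bond_angles: list[float]) -> str:
    """Pick the side (right/left/above/below) for the implicit-H suffix.

    The winning side has the greatest angular clearance from every
    incident bond direction; ties (including the no-bond case) resolve
    right > left > above > below.
    """
    best_side, best_clear = "right", -1.0
    for side, angle in LABEL_SIDES:
        clear = min((_angular_distance(angle, b) for b in bond_angles),
                    default=360.0)
        if clear > best_clear + 1e-9:
            best_side, best_clear = side, clear
    return best_side


def place_lone_pairs(bond_angles: list[float], count: int) -> list[float]:
    """Angular positions (degrees) for *count* lone pairs.

    Each pair goes at the bisector of the currently largest angular gap
    between occupied directions (bonds + already-placed pairs), largest
    gap first.  An isolated atom's first pair points right (0°), after
    which recursive gap splitting yields 180°, 90°, 270°, ...
    """
    occupied = sorted(a % 360.0 for a in bond_angles)
    placed: list[float] = []
    for _ in range(count):
        if not occupied:
            angle = 0.0
        else:
            gaps = []
            for i, a in enumerate(occupied):
                b = occupied[(i + 1) % len(occupied)]
                span = (b - a) % 360.0
                if span == 0.0 and len(occupied) > 1:
                    continue
                if len(occupied) == 1:
                    span = 360.0
                gaps.append((span, a))
            span, start = max(gaps, key=lambda g: (g[0], -g[1]))
            angle = (start + span / 2.0) % 360.0
        placed.append(angle)
        occupied = sorted(occupied + [angle])
    return placed


def _unit(dx: float, dy: float) -> tuple[float, float]:
    n = math.hypot(dx, dy)
    if n == 0.0:
        raise DegenerateGeometryError("coincident bond endpoints")
    return dx / n, dy / n


def layout_bond(order: float, stereo: str,
                p1: tuple[float, float], p2: tuple[float, float],
                specs: VisualSpecs, color: str = "#000000",
                inner_side: tuple[float, float] | None = None) -> list:
    """Primitives for one bond between trimmed endpoints *p1*, *p2*.

    ``inner_side`` is a point (usually a ring centroid) that the inner
    line of an in-ring double bond should face; without it the two lines
    of a double bond straddle the bond axis symmetrically.
    """
    (x1, y1), (x2, y2) = p1, p2
    ux, uy = _unit(x2 - x1, y2 - y1)
    px, py = -uy, ux  # perpendicular
    length = math.hypot(x2 - x1, y2 - y1)
    gap = specs.bond_double_gap * specs.bond_length
    w = specs.bond_width

    def line(off: float, shrink: float = 0.0,
             dash: tuple[float, float] | None = None) -> Line:
        sx = shrink * length
        return Line(x1 + off * px + sx * ux, y1 + off * py + sx * uy,
                    x2 + off * px - sx * ux, y2 + off * py - sx * uy,
                    width=w, color=color, dash=dash, cls="bond")

    if stereo == "protruding":
        # filled wedge, narrow at the begin atom
        half = max(gap, 2.0 * w)
        return [Polygon([(x1, y1),
                         (x2 + half * px, y2 + half * py),
                         (x2 - half * px, y2 - half * py)],
                        fill=color, cls="wedge")]
    if stereo == "recessed":
        # perpendicular strokes widening toward the end atom
        n = int(length // specs.dash_spacing) + 1
        half_max = max(gap, 2.0 * w)
        prims = []
        for i in range(n):
            t = (i * specs.dash_spacing) / length if length else 0.0
            half = half_max * max(t, 0.15)
            cx, cy = x1 + t * (x2 - x1), y1 + t * (y2 - y1)
            prims.append(Line(cx + half * px, cy + half * py,
                              cx - half * px, cy - half * py,
                              width=w, color=color, cls="hash"))
        return prims

    if order == 1.0:
        return [line(0.0)]
    if order == 2.0:
        if inner_side is not None:
            sx, sy = inner_side
            side = 1.0 if (sx - x1) * px + (sy - y1) * py > 0 else -1.0
            return [line(0.0), line(side * gap, shrink=0.15)]
        return [line(gap / 2), line(-gap / 2)]
    if order == 3.0:
        return [line(0.0), line(gap), line(-gap)]
    if order == 0.0:
        return [line(0.0, dash=(specs.dash_length, specs.dash_spacing))]
    if order == 0.5:
        return [line(0.0, dash=(specs.dash_length / 2, specs.dash_spacing))]
    if order == 1.5:
        return [line(gap / 2),
                line(-gap / 2, dash=(specs.dash_length, specs.dash_spacing))]
    raise ValueError(f"unsupported bond order {order}")
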