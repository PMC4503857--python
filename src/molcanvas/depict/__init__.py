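"""2D depiction pipeline.

``depict(mol, width, height)`` composes the full chain: implicit
hydrogen deduction → ring perception → scale-to-fit → per-atom and
per-bond layout → deterministic SVG.  ``build_drawing`` exposes the
intermediate :class:`Drawing` for callers that post-process primitives
(adding arrows, brackets, extra annotations) before serialization.
"""

from __future__ import annotations

import math

from ..informatics import (copy_molecule, deduce_implicit_hydrogens,
                           perceive_rings_sssr)
from ..model import Molecule
from .layout import (Transform, layout_bond, place_implicit_h_label,
                     place_lone_pairs, scale_to_fit, LABEL_SIDES)
from .primitives import Dot, Drawing, Text, render_svg
from .shapes import render_arrow, render_bracket
from .specs import (SpecScope, VisualSpecs, acs_preset, load_specs,
                    resolve_specs)

__all__ = [
    "depict", "build_drawing", "render_svg", "Drawing",
    "VisualSpecs", "SpecScope", "resolve_specs", "acs_preset", "load_specs",
    "scale_to_fit", "place_implicit_h_label", "place_lone_pairs",
    "layout_bond", "render_arrow", "render_bracket", "Transform",
]

_SIDE_ANGLE = dict(LABEL_SIDES)


def _atom_color(label: str, specs: VisualSpecs) -> str:
    if specs.element_color_scheme == "mono":
        return specs.atom_color
    from ..elements import lookup_element
    info = lookup_element(label)
    rgb = info.jmol_color if specs.element_color_scheme == "jmol" \
        else info.cpk_color
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _charge_text(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "−"
    mag = abs(charge)
    return sign if mag == 1 else f"{mag}{sign}"


def build_drawing(mol: Molecule, width: float, height: float,
                  scope: SpecScope | VisualSpecs | None = None) -> Drawing:
    """Lay out a molecule into a :class:`Drawing` (no serialization)."""
    if isinstance(scope, VisualSpecs):
        scope = SpecScope(global_specs=scope)
    scope = scope or SpecScope()
    canvas_specs = resolve_specs(scope, "canvas")

    work = copy_molecule(mol)
    deduce_implicit_hydrogens(work)
    perceive_rings_sssr(work)
    tf = scale_to_fit(work, width, height, canvas_specs)
    pos = [tf.apply(a.x, a.y) for a in work.atoms]

    drawing = Drawing(width, height, background=canvas_specs.background)

    # which atoms show a text label
    labeled = []
    for i, atom in enumerate(work.atoms):
        specs = resolve_specs(scope, ("atom", i))
        if atom.label != "C" or specs.show_carbon_labels \
                or atom.charge or atom.radicals or work.degree(i) == 0:
            labeled.append(True)
        else:
            labeled.append(False)

    # ring centroids for in-ring double bond orientation
    bond_ring_centroid: dict[int, tuple[float, float]] = {}
    for ring in work.rings:
        cx = sum(pos[i][0] for i in ring.atom_indices) / len(ring)
        cy = sum(pos[i][1] for i in ring.atom_indices) / len(ring)
        for bi in ring.bond_indices:
            bond_ring_centroid.setdefault(bi, (cx, cy))

    # bonds first (labels paint over them)
    for bi, bond in enumerate(work.bonds):
        specs = resolve_specs(scope, ("bond", bi))
        (x1, y1), (x2, y2) = pos[bond.begin], pos[bond.end]
        dx, dy = x2 - x1, y2 - y1
        length = math.hypot(dx, dy)
        if length == 0:
            continue
        trim = specs.label_buffer + specs.atom_font_size * 0.55
        t1 = trim / length if labeled[bond.begin] else 0.0
        t2 = trim / length if labeled[bond.end] else 0.0
        if t1 + t2 >= 1.0:  # bond fully swallowed by labels
            continue
        p1 = (x1 + t1 * dx, y1 + t1 * dy)
        p2 = (x2 - t2 * dx, y2 - t2 * dy)
        color = specs.atom_color if specs.element_color_scheme == "mono" \
            else "#000000"
        drawing.add(*layout_bond(bond.order, bond.stereo, p1, p2, specs,
                                 color=color,
                                 inner_side=bond_ring_centroid.get(bi)))

    # atom labels, implicit H, charges, lone pairs
    for i, atom in enumerate(work.atoms):
        specs = resolve_specs(scope, ("atom", i))
        x, y = pos[i]
        angles = [math.degrees(math.atan2(pos[j][1] - y, pos[j][0] - x))
                  for j in work.neighbors(i)]
        color = _atom_color(atom.label, specs)
        size = specs.atom_font_size
        if labeled[i]:
            drawing.add(Text(atom.label, x, y + size * 0.35, size,
                             specs.atom_font_family, color=color,
                             cls="label"))
            n_h = atom.implicit_h or 0
            if specs.show_implicit_h and n_h > 0:
                side = place_implicit_h_label(angles)
                w_label = size * 0.65 * len(atom.label)
                w_h = size * 0.65
                if side == "right":
                    hx, hy = x + w_label / 2 + w_h / 2 + 1, y + size * 0.35
                elif side == "left":
                    shift = w_h + (size * 0.45 if n_h > 1 else 0)
                    hx, hy = x - w_label / 2 - shift / 2 - 1, y + size * 0.35
                elif side == "above":
                    hx, hy = x, y - size * 0.75
                else:
                    hx, hy = x, y + size * 1.35
                drawing.add(Text("H", hx, hy, size,
                                 specs.atom_font_family, color=color,
                                 cls="implicit-h"))
                if n_h > 1:
                    drawing.add(Text(str(n_h), hx + w_h * 0.7,
                                     hy + size * 0.25, size * 0.7,
                                     specs.atom_font_family, color=color,
                                     baseline_shift="sub", cls="h-count"))
            if atom.charge:
                drawing.add(Text(_charge_text(atom.charge),
                                 x + size * 0.75, y - size * 0.35,
                                 size * 0.7, specs.atom_font_family,
                                 color=color, baseline_shift="super",
                                 cls="charge"))
        if atom.lone_pairs > 0:
            radius = specs.label_buffer + size / 2
            for angle in place_lone_pairs(angles, atom.lone_pairs):
                rad = math.radians(angle)
                cx = x + radius * math.cos(rad)
                cy = y + radius * math.sin(rad)
                # two dots perpendicular to the radial direction
                ppx, ppy = -math.sin(rad), math.cos(rad)
                half = specs.lone_pair_size / 2
                drawing.add(
                    Dot(cx + half * ppx, cy + half * ppy, 1.0, fill=color,
                        cls="lone-pair"),
                    Dot(cx - half * ppx, cy - half * ppy, 1.0, fill=color,
                        cls="lone-pair"))
    return drawing


def depict(mol: Molecule, width: float = 300, height: float = 300,
           scope: SpecScope | VisualSpecs | None = None) -> str:
    """Render a molecule to SVG text (the full pipeline)."""
    return render_svg(build_drawing(mol, width, height, scope))
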