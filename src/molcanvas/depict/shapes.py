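"""Reaction arrows and brackets."""

from __future__ import annotations

import math

from ..errors import DegenerateGeometryError
from .primitives import Line, Polygon, Polyline, Text
from .specs import VisualSpecs

__all__ = ["render_arrow", "render_bracket", "ARROW_KINDS"]

ARROW_KINDS = ("synthetic", "retrosynthetic", "resonance", "equilibrium")


def _unit(dx: float, dy: float) -> tuple[float, float]:
    n = math.hypot(dx, dy)
    if n == 0.0:
        raise DegenerateGeometryError("arrow endpoints coincide")
    return dx / n, dy / n


def _head(tip: tuple[float, float], ux: float, uy: float, size: float,
          color: str) -> Polygon:
    """Solid triangular head pointing along (ux, uy) with apex at *tip*."""
    px, py = -uy, ux
    bx, by = tip[0] - size * ux, tip[1] - size * uy
    return Polygon([tip, (bx + size * 0.4 * px, by + size * 0.4 * py),
                    (bx - size * 0.4 * px, by - size * 0.4 * py)],
                   fill=color, cls="arrowhead")


def _harpoon(x1: float, y1: float, x2: float, y2: float, side: float,
             size: float, width: float, color: str) -> list:
    """Half-headed arrow: shaft plus a single barb on *side*."""
    ux, uy = _unit(x2 - x1, y2 - y1)
    px, py = -uy, ux
    barb = Line(x2, y2,
                x2 - size * ux + side * size * 0.5 * px,
                y2 - size * uy + side * size * 0.5 * py,
                width=width, color=color, cls="harpoon")
    return [Line(x1, y1, x2, y2, width=width, color=color, cls="arrow"),
            barb]


def render_arrow(kind: str, start: tuple[float, float],
                 end: tuple[float, float], specs: VisualSpecs,
                 top_text: str = "", bottom_text: str = "",
                 color: str = "#000000") -> list:
    """Primitives for a reaction arrow from *start* to *end*.

    synthetic: single shaft + solid head; retrosynthetic: two parallel
    shafts + open (stroked) head; resonance: double-headed;
    equilibrium: two opposed harpoons with opposite barbs.  Optional
    text is centered above/below the midpoint at label-buffer offset.
    """
    if kind not in ARROW_KINDS:
        raise ValueError(f"unknown arrow kind {kind!r}")
    (x1, y1), (x2, y2) = start, end
    ux, uy = _unit(x2 - x1, y2 - y1)
    px, py = -uy, ux
    size = specs.atom_font_size * 0.7
    w = specs.bond_width
    prims: list = []
    if kind == "synthetic":
        prims.append(Line(x1, y1, x2 - size * 0.6 * ux, y2 - size * 0.6 * uy,
                          width=w, color=color, cls="arrow"))
        prims.append(_head((x2, y2), ux, uy, size, color))
    elif kind == "retrosynthetic":
        off = size * 0.35
        for side in (1.0, -1.0):
            prims.append(Line(x1 + side * off * px, y1 + side * off * py,
                              x2 - size * 0.8 * ux + side * off * px,
                              y2 - size * 0.8 * uy + side * off * py,
                              width=w, color=color, cls="arrow"))
        # open head: two strokes meeting at the tip
        for side in (1.0, -1.0):
            prims.append(Line(x2, y2,
                              x2 - size * ux + side * size * 0.7 * px,
                              y2 - size * uy + side * size * 0.7 * py,
                              width=w, color=color, cls="arrowhead"))
    elif kind == "resonance":
        prims.append(Line(x1 + size * 0.6 * ux, y1 + size * 0.6 * uy,
                          x2 - size * 0.6 * ux, y2 - size * 0.6 * uy,
                          width=w, color=color, cls="arrow"))
        prims.append(_head((x2, y2), ux, uy, size, color))
        prims.append(_head((x1, y1), -ux, -uy, size, color))
    else:  # equilibrium
        off = size * 0.35
        prims += _harpoon(x1 + off * px, y1 + off * py,
                          x2 + off * px, y2 + off * py, 1.0, size, w, color)
        prims += _harpoon(x2 - off * px, y2 - off * py,
                          x1 - off * px, y1 - off * py, 1.0, size, w, color)
    mx, my = 0.5 * (x1 + x2), 0.5 * (y1 + y2)
    dy = specs.label_buffer + specs.atom_font_size * 0.6
    if top_text:
        prims.append(Text(top_text, mx, my - dy, specs.atom_font_size,
                          specs.atom_font_family, color=color,
                          cls="arrowtext"))
    if bottom_text:
        prims.append(Text(bottom_text, mx, my + dy + specs.atom_font_size * 0.6,
                          specs.atom_font_size, specs.atom_font_family,
                          color=color, cls="arrowtext"))
    return prims


def render_bracket(box: tuple[float, float, float, float],
                   specs: VisualSpecs, annotation: str = "",
                   subscript: str = "",
                   color: str = "#000000") -> list:
    """Mirrored square brackets around *box* (min_x, min_y, max_x, max_y).

    ``annotation`` (e.g. a global charge "2-") goes superscript at the
    upper right; ``subscript`` (e.g. a polymer repeat "n") at the lower
    right.
    """
    min_x, min_y, max_x, max_y = box
    pad = specs.label_buffer * 2
    serif = max(4.0, specs.atom_font_size * 0.4)
    lx, rx = min_x - pad, max_x + pad
    ty, by = min_y - pad, max_y + pad
    w = specs.bond_width
    prims = [
        Polyline([(lx + serif, ty), (lx, ty), (lx, by), (lx + serif, by)],
                 width=w, color=color, cls="bracket"),
        Polyline([(rx - serif, ty), (rx, ty), (rx, by), (rx - serif, by)],
                 width=w, color=color, cls="bracket"),
    ]
    if annotation:
        prims.append(Text(annotation, rx + specs.label_buffer,
                          ty + specs.atom_font_size * 0.3,
                          specs.atom_font_size * 0.8,
                          specs.atom_font_family, color=color,
                          anchor="start", cls="bracket-annotation"))
    if subscript:
        prims.append(Text(subscript, rx + specs.label_buffer,
                          by + specs.atom_font_size * 0.5,
                          specs.atom_font_size * 0.8,
                          specs.atom_font_family, color=color,
                          anchor="start", cls="bracket-subscript"))
    return prims
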