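"""Device-independent render primitives and the Drawing container."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..svgcanvas import SvgCanvas

__all__ = ["Line", "Polyline", "Polygon", "Dot", "Text", "Drawing",
           "render_svg"]


@dataclass
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    width: float = 1.0
    color: str = "#000000"
    dash: tuple[float, float] | None = None
    cls: str | None = None


@dataclass
class Polyline:
    points: list[tuple[float, float]]
    width: float = 1.0
    color: str = "#000000"
    cls: str | None = None


@dataclass
class Polygon:
    points: list[tuple[float, float]]
    fill: str = "#000000"
    cls: str | None = None


@dataclass
class Dot:
    x: float
    y: float
    r: float
    fill: str = "#000000"
    cls: str | None = None


@dataclass
class Text:
    content: str
    x: float
    y: float
    size: float
    family: str = "Helvetica"
    color: str = "#000000"
    anchor: str = "middle"
    baseline_shift: str | None = None   # "sub" / "super"
    cls: str | None = None


Primitive = Line | Polyline | Polygon | Dot | Text


@dataclass
class Drawing:
    """Ordered primitive list plus canvas size; painter's-algorithm order."""

    width: float
    height: float
    background: str = "#ffffff"
    primitives: list[Primitive] = field(default_factory=list)

    def add(self, *prims: Primitive) -> None:
        self.primitives.extend(prims)

    def extent(self) -> tuple[float, float, float, float]:
        """Bounding box over primitive anchor coordinates."""
        xs, ys = [], []
        for p in self.primitives:
            if isinstance(p, Line):
                xs += [p.x1, p.x2]
                ys += [p.y1, p.y2]
            elif isinstance(p, (Polyline, Polygon)):
                xs += [pt[0] for pt in p.points]
                ys += [pt[1] for pt in p.points]
            elif isinstance(p, (Dot, Text)):
                xs.append(p.x)
                ys.append(p.y)
        if not xs:
            return (0.0, 0.0, 0.0, 0.0)
        return (min(xs), min(ys), max(xs), max(ys))


def render_svg(drawing: Drawing) -> str:
    """Serialize a Drawing to deterministic SVG 1.1 text."""
    c = SvgCanvas(drawing.width, drawing.height,
                  background=drawing.background)
    for p in drawing.primitives:
        if isinstance(p, Line):
            c.line(p.x1, p.y1, p.x2, p.y2, stroke=p.color,
                   stroke_width=p.width, dash=p.dash, cls=p.cls)
        elif isinstance(p, Polyline):
            c.polyline(p.points, stroke=p.color, stroke_width=p.width,
                       cls=p.cls)
        elif isinstance(p, Polygon):
            c.polygon(p.points, fill=p.fill, cls=p.cls)
        elif isinstance(p, Dot):
            c.circle(p.x, p.y, p.r, fill=p.fill, cls=p.cls)
        elif isinstance(p, Text):
            c.text(p.content, p.x, p.y, p.size, p.family, fill=p.color,
                   anchor=p.anchor, baseline_shift=p.baseline_shift,
                   cls=p.cls)
    return c.to_svg()
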