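"""Deterministic SVG 1.1 serialization.

A tiny device-independent canvas: primitives are appended in draw order
(painter's algorithm) and serialized with a fixed attribute order and
fixed number formatting, so identical input always yields byte-identical
SVG — the property golden-file tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

__all__ = ["SvgCanvas", "fmt"]


def fmt(v: float) -> str:
    """Format a coordinate: 2 decimals, no trailing zeros, no '-0'."""
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return "0" if s == "-0" else s


@dataclass
class SvgCanvas:
    width: float
    height: float
    background: str | None = "#ffffff"
    _parts: list[str] = field(default_factory=list)

    def _emit(self, tag: str, attrs: list[tuple[str, str]],
              text: str | None = None) -> None:
        pieces = [f"<{tag}"]
        for k, v in attrs:
            pieces.append(f" {k}={quoteattr(v)}")
        if text is None:
            pieces.append("/>")
        else:
            pieces.append(f">{escape(text)}</{tag}>")
        self._parts.append("".join(pieces))

    # -- primitives ----------------------------------------------------
    def line(self, x1: float, y1: float, x2: float, y2: float, *,
             stroke: str = "#000000", stroke_width: float = 1.0,
             dash: tuple[float, float] | None = None,
             cap: str = "round", cls: str | None = None) -> None:
        attrs = [("x1", fmt(x1)), ("y1", fmt(y1)),
                 ("x2", fmt(x2)), ("y2", fmt(y2)),
                 ("stroke", stroke), ("stroke-width", fmt(stroke_width)),
                 ("stroke-linecap", cap)]
        if dash:
            attrs.append(("stroke-dasharray", f"{fmt(dash[0])} {fmt(dash[1])}"))
        if cls:
            attrs.append(("class", cls))
        self._emit("line", attrs)

    def polyline(self, points: list[tuple[float, float]], *,
                 stroke: str = "#000000", stroke_width: float = 1.0,
                 fill: str = "none", cls: str | None = None) -> None:
        pts = " ".join(f"{fmt(x)},{fmt(y)}" for x, y in points)
        attrs = [("points", pts), ("fill", fill), ("stroke", stroke),
                 ("stroke-width", fmt(stroke_width)),
                 ("stroke-linejoin", "round")]
        if cls:
            attrs.append(("class", cls))
        self._emit("polyline", attrs)

    def polygon(self, points: list[tuple[float, float]], *,
                fill: str = "#000000", stroke: str = "none",
                cls: str | None = None) -> None:
        pts = " ".join(f"{fmt(x)},{fmt(y)}" for x, y in points)
        attrs = [("points", pts), ("fill", fill), ("stroke", stroke)]
        if cls:
            attrs.append(("class", cls))
        self._emit("polygon", attrs)

    def circle(self, cx: float, cy: float, r: float, *,
               fill: str = "#000000", stroke: str = "none",
               cls: str | None = None) -> None:
        attrs = [("cx", fmt(cx)), ("cy", fmt(cy)), ("r", fmt(r)),
                 ("fill", fill), ("stroke", stroke)]
        if cls:
            attrs.append(("class", cls))
        self._emit("circle", attrs)

    def text(self, content: str, x: float, y: float,
             size: float, family: str, *, fill: str = "#000000",
             anchor: str = "middle", baseline_shift: str | None = None,
             cls: str | None = None) -> None:
        attrs = [("x", fmt(x)), ("y", fmt(y)),
                 ("font-family", family), ("font-size", fmt(size)),
                 ("fill", fill), ("text-anchor", anchor)]
        if baseline_shift:
            attrs.append(("baseline-shift", baseline_shift))
        if cls:
            attrs.append(("class", cls))
        self._emit("text", attrs, text=content)

    # -- serialization -------------------------------------------------
    def to_svg(self) -> str:
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width={quoteattr(fmt(self.width))} '
            f'height={quoteattr(fmt(self.height))} '
            f'viewBox={quoteattr(f"0 0 {fmt(self.width)} {fmt(self.height)}")}>'
        )
        body = list(self._parts)
        if self.background:
            body.insert(0, f'<rect x="0" y="0" width={quoteattr(fmt(self.width))} '
                           f'height={quoteattr(fmt(self.height))} '
                           f'fill={quoteattr(self.background)}/>')
        return "\n".join([head, *body, "</svg>"]) + "\n"
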