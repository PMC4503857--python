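"""Spectrum model, NMR integration, and spectrum plotting to SVG.

A :class:`Spectrum` is an ordered (x, y) point series with metadata —
sufficient for NMR, IR, UV/Vis and mass spectra.  Integration uses the
trapezoid rule with linear interpolation at region cut points, matching
the piecewise-linear way the trace is displayed.  Region ratios are
normalized so the smallest region area is 1.00, the convention used to
read off relative proton counts from an NMR integration trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidRegionsError, NoSignalError
from .svgcanvas import SvgCanvas

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum", "PlotSpecs", "normalize_spectrum", "integrate_region",
    "integration_curve", "IntegrationResult", "render_spectrum_svg",
]

KINDS = ("nmr", "ir", "uvvis", "ms")


@dataclass
class Spectrum:
    x: np.ndarray
    y: np.ndarray
    kind: str = "nmr"
    x_units: str = ""
    y_units: str = ""
    title: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) > 1:
            d = np.diff(self.x)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("x must be strictly monotonic")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")
        if self.kind not in KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def ascending(self) -> "Spectrum":
        """A view-copy with x sorted ascending."""
        if len(self.x) > 1 and self.x[0] > self.x[-1]:
            return replace(self, x=self.x[::-1].copy(), y=self.y[::-1].copy())
        return self

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Rescale y so max |y| = 1 (signs preserved, x untouched)."""
    peak = float(np.max(np.abs(s.y))) if len(s.y) else 0.0
    if peak == 0.0:
        raise NoSignalError("spectrum has no nonzero intensity")
    return replace(s, y=s.y / peak)


def integrate_region(s: Spectrum, x1: float, x2: float) -> float:
    """Trapezoidal integral of y over [x1, x2].

    The region bounds may be given in either order; values at the cut
    points are linearly interpolated.  A region that does not overlap
    the spectrum domain integrates to 0 (with a logged warning).
    """
    lo, hi = sorted((float(x1), float(x2)))
    asc = s.ascending()
    x, y = asc.x, asc.y
    lo_c, hi_c = max(lo, x[0]), min(hi, x[-1])
    if hi_c <= lo_c:
        log.warning("integration region [%g, %g] outside spectrum domain "
                    "[%g, %g]; area = 0", lo, hi, x[0], x[-1])
        return 0.0
    inside = (x > lo_c) & (x < hi_c)
    xs = np.concatenate(([lo_c], x[inside], [hi_c]))
    ys = np.concatenate(([np.interp(lo_c, x, y)], y[inside],
                         [np.interp(hi_c, x, y)]))
    return float(np.trapezoid(ys, xs))


@dataclass
class IntegrationResult:
    regions: list[tuple[float, float]]
    areas: list[float]
    ratios: list[float]                      # smallest area = 1.00
    curves: list[tuple[np.ndarray, np.ndarray]]  # cumulative per region


def integration_curve(s: Spectrum,
                      regions: list[tuple[float, float]]) -> IntegrationResult:
    """Per-region cumulative integration curves and relative area ratios.

    Regions must be pairwise disjoint (bounds in either order are
    normalized first).  Ratios are areas divided by the smallest
    nonzero |area|, reported so the smallest region reads 1.00.
    """
    norm = [tuple(sorted((float(a), float(b)))) for a, b in regions]
    for i in range(len(norm)):
        for j in range(i + 1, len(norm)):
            a, b = norm[i], norm[j]
            if a[0] < b[1] and b[0] < a[1]:
                raise InvalidRegionsError(
                    f"integration regions {regions[i]} and {regions[j]} overlap")
    asc = s.ascending()
    x, y = asc.x, asc.y
    areas, curves = [], []
    for lo, hi in norm:
        lo_c, hi_c = max(lo, x[0]), min(hi, x[-1])
        if hi_c <= lo_c:
            areas.append(0.0)
            curves.append((np.array([lo, hi]), np.zeros(2)))
            continue
        inside = (x > lo_c) & (x < hi_c)
        xs = np.concatenate(([lo_c], x[inside], [hi_c]))
        ys = np.concatenate(([np.interp(lo_c, x, y)], y[inside],
                             [np.interp(hi_c, x, y)]))
        cum = np.concatenate(([0.0], np.cumsum(
            0.5 * (ys[1:] + ys[:-1]) * np.diff(xs))))
        areas.append(float(cum[-1]))
        curves.append((xs, cum))
    nonzero = [abs(a) for a in areas if a != 0.0]
    base = min(nonzero) if nonzero else 1.0
    ratios = [a / base for a in areas]
    return IntegrationResult(list(norm), areas, ratios, curves)


# ---------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------

@dataclass
class PlotSpecs:
    """Spectrum plot styling: domain/range, gridlines, ticks, labels."""

    domain: tuple[float, float] | None = None    # None = data extent
    range: tuple[float, float] | None = None     # None = auto
    gridlines: bool = False
    tick_interval: float | None = None           # None = auto (~8 ticks)
    title: str | None = None                     # None = spectrum title
    x_label: str | None = None
    y_label: str | None = None
    font_family: str = "Helvetica"
    font_size: float = 10.0
    line_color: str = "#000000"
    grid_color: str = "#cccccc"
    background: str = "#ffffff"
    invert_x: bool | None = None                 # None = NMR convention
    margin: float = 44.0

    def __post_init__(self) -> None:
        if self.domain is not None and self.domain[0] == self.domain[1]:
            raise ValueError("plot domain must be non-degenerate")


def _nice_tick(span: float, target: int = 8) -> float:
    raw = span / target
    mag = 10.0 ** np.floor(np.log10(raw))
    for mult in (1.0, 2.0, 5.0, 10.0):
        if raw <= mult * mag:
            return float(mult * mag)
    return float(10.0 * mag)


def render_spectrum_svg(s: Spectrum, plot: PlotSpecs | None = None,
                        width: float = 500, height: float = 300,
                        integration: IntegrationResult | None = None) -> str:
    """Render a spectrum as deterministic SVG.

    Continuous kinds draw a polyline; mass spectra draw one vertical
    stick per point.  NMR spectra invert the x axis by default (higher
    chemical shift on the left).  Integration curves, when given, are
    overlaid scaled to the top third of the plot area.
    """
    plot = plot or PlotSpecs()
    invert = plot.invert_x if plot.invert_x is not None else (s.kind == "nmr")
    x0, x1 = plot.domain if plot.domain else (min(s.domain), max(s.domain))
    if x0 > x1:
        x0, x1 = x1, x0
    asc = s.ascending()
    if plot.range:
        y0, y1 = plot.range
    else:
        y0 = min(0.0, float(asc.y.min()))
        y1 = float(asc.y.max())
        if y1 == y0:
            y1 = y0 + 1.0
    m = plot.margin
    pw, ph = width - 2 * m, height - 2 * m

    def px(x: float) -> float:
        t = (x - x0) / (x1 - x0)
        if invert:
            t = 1.0 - t
        return m + t * pw

    def py(y: float) -> float:
        return m + ph - (y - y0) / (y1 - y0) * ph

    c = SvgCanvas(width, height, background=plot.background)
    tick = plot.tick_interval or _nice_tick(x1 - x0)
    first = np.ceil(x0 / tick) * tick
    ticks = np.arange(first, x1 + tick * 1e-9, tick)
    if plot.gridlines:
        for tx in ticks:
            c.line(px(tx), m, px(tx), m + ph, stroke=plot.grid_color,
                   stroke_width=0.5, cls="grid")
    # axes
    c.line(m, m + ph, m + pw, m + ph, stroke="#000000", stroke_width=1.0)
    c.line(m, m, m, m + ph, stroke="#000000", stroke_width=1.0)
    for tx in ticks:
        c.line(px(tx), m + ph, px(tx), m + ph + 4, stroke="#000000",
               stroke_width=1.0)
        c.text(f"{tx:g}", px(tx), m + ph + 6 + plot.font_size,
               plot.font_size, plot.font_family, anchor="middle")
    # trace
    if s.kind == "ms":
        base = py(max(0.0, y0))
        for xx, yy in zip(asc.x, asc.y):
            if x0 <= xx <= x1:
                c.line(px(xx), base, px(xx), py(yy),
                       stroke=plot.line_color, stroke_width=1.0, cls="stick")
    else:
        pts = [(px(xx), py(yy)) for xx, yy in zip(asc.x, asc.y)
               if x0 <= xx <= x1]
        if len(pts) >= 2:
            c.polyline(pts, stroke=plot.line_color, stroke_width=1.0,
                       cls="trace")
    if integration is not None:
        peak = max((abs(cum[-1]) for _, cum in integration.curves
                    if len(cum)), default=0.0)
        if peak > 0:
            for xs, cum in integration.curves:
                pts = [(px(xx), m + ph * 0.33 - cc / peak * ph * 0.30)
                       for xx, cc in zip(xs, cum)]
                if invert:
                    pts = pts[::-1]
                c.polyline(pts, stroke="#cc0000", stroke_width=1.0,
                           cls="integral")
    title = plot.title if plot.title is not None else s.title
    if title:
        c.text(title, width / 2, m - 8, plot.font_size * 1.2,
               plot.font_family, anchor="middle")
    x_label = plot.x_label if plot.x_label is not None else s.x_units
    if x_label:
        c.text(x_label, width / 2, height - 6, plot.font_size,
               plot.font_family, anchor="middle")
    y_label = plot.y_label if plot.y_label is not None else s.y_units
    if y_label:
        c.text(y_label, 12, m - 8, plot.font_size, plot.font_family,
               anchor="start")
    return c.to_svg()
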