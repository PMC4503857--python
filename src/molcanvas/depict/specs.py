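"""Hierarchical visual specifications.

A :class:`VisualSpecs` bundle holds every styling knob the 2D engine
reads.  Specs cascade through a :class:`SpecScope`: global defaults,
then per-canvas overrides, then per-atom / per-bond overrides — the most
local setting wins, field by field.  The ACS-style preset (black
monochrome, 14.4 px bonds, Helvetica 10) ships as packaged data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources

__all__ = ["VisualSpecs", "SpecScope", "resolve_specs", "acs_preset",
           "load_specs"]

COLOR_SCHEMES = ("mono", "jmol", "cpk")


@dataclass(frozen=True)
class VisualSpecs:
    bond_length: float = 20.0          # px target for the median bond
    bond_width: float = 1.0            # px stroke width
    bond_double_gap: float = 0.2       # gap between lines, ratio of bond length
    atom_font_family: str = "Helvetica"
    atom_font_size: float = 12.0       # px
    atom_color: str = "#000000"        # used by the mono scheme
    element_color_scheme: str = "jmol"
    show_carbon_labels: bool = False
    show_implicit_h: bool = True
    lone_pair_size: float = 4.0        # px between the two dots of a pair
    label_buffer: float = 3.0          # px padding around drawn labels
    dash_length: float = 4.0           # px, dashed (zero-order/half) bonds
    dash_spacing: float = 4.0          # px
    background: str = "#ffffff"
    margin: float = 12.0               # px canvas margin for scale-to-fit

    def __post_init__(self) -> None:
        for name in ("bond_length", "bond_width", "atom_font_size",
                     "lone_pair_size", "dash_length", "dash_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.bond_double_gap < 0.5:
            raise ValueError("bond_double_gap must lie in (0, 0.5)")
        if self.element_color_scheme not in COLOR_SCHEMES:
            raise ValueError(
                f"unknown color scheme {self.element_color_scheme!r}")

    def override(self, **kwargs) -> "VisualSpecs":
        return replace(self, **kwargs)


_FIELD_NAMES = frozenset(f.name for f in fields(VisualSpecs))
_FIELD_TYPES = {f.name: f.type for f in fields(VisualSpecs)}


def _check_keys(overrides: dict) -> dict:
    for key in overrides:
        if key not in _FIELD_NAMES:
            raise KeyError(f"unknown visual spec field: {key!r}")
    return dict(overrides)


@dataclass
class SpecScope:
    """Cascading override layers; resolution order local > canvas > global."""

    global_specs: VisualSpecs = field(default_factory=VisualSpecs)
    canvas: dict = field(default_factory=dict)
    atoms: dict[int, dict] = field(default_factory=dict)
    bonds: dict[int, dict] = field(default_factory=dict)

    def set_canvas(self, **overrides) -> None:
        self.canvas.update(_check_keys(overrides))

    def set_atom(self, index: int, **overrides) -> None:
        self.atoms.setdefault(index, {}).update(_check_keys(overrides))

    def set_bond(self, index: int, **overrides) -> None:
        self.bonds.setdefault(index, {}).update(_check_keys(overrides))


def resolve_specs(scope: SpecScope,
                  target: str | tuple[str, int] = "canvas") -> VisualSpecs:
    """Resolve the effective specs for ``"canvas"``, ``("atom", i)`` or
    ``("bond", i)`` by applying the override cascade field-wise."""
    merged = dict(scope.canvas)
    if target != "canvas":
        kind, index = target
        layer = {"atom": scope.atoms, "bond": scope.bonds}[kind]
        merged.update(layer.get(index, {}))
    return scope.global_specs.override(**_check_keys(merged)) \
        if merged else scope.global_specs


def _coerce(key: str, value):
    current = getattr(VisualSpecs(), key)
    if isinstance(current, bool):
        if isinstance(value, str):
            return value.lower() in ("1", "true", "yes", "on")
        return bool(value)
    if isinstance(current, float):
        return float(value)
    return str(value)


def load_specs(data: dict | str) -> VisualSpecs:
    """Build specs from a JSON object/text keyed by field names.

    Unknown keys are rejected, naming the offending key.
    """
    if isinstance(data, str):
        data = json.loads(data)
    overrides = {k: _coerce(k, v) for k, v in _check_keys(data).items()}
    return VisualSpecs().override(**overrides)


def acs_preset() -> VisualSpecs:
    """The packaged ACS-document style preset."""
    text = (resources.files("molcanvas") / "data" / "acs1996.json").read_text()
    return load_specs(text)
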