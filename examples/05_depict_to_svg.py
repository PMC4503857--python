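"""Render structures to SVG with cascading visual specifications.

The pipeline deduces implicit hydrogens, perceives rings (so the inner
line of an in-ring double bond faces the centroid), scales to fit, and
serializes deterministically — the same input always gives the same
bytes.
"""

from pathlib import Path

from molcanvas import SpecScope, acs_preset, depict, fixtures

svg = depict(fixtures.benzene(), 300, 300)
Path("benzene.svg").write_text(svg)
print("benzene.svg :", svg.count("<line"), "lines",
      "(6 ring bonds + 3 inner double-bond lines)")

scope = SpecScope(global_specs=acs_preset())
scope.set_canvas(bond_width=1.2)
styled = depict(fixtures.pyridinium(), 300, 300, scope)
Path("pyridinium_acs.svg").write_text(styled)
print("pyridinium_acs.svg : ACS-style monochrome;",
      "N+ carries its implicit H and charge label")
print("deterministic :", svg == depict(fixtures.benzene(), 300, 300))
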