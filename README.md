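# molcanvas

2D chemical structure depiction, cheminformatics algorithms, and
multi-format chemical file I/O for Python — the computational core of a
chemical drawing toolkit, as an importable library with a thin CLI.

Who it is for: tool builders and computational chemists who need to
parse structure/spectrum files, run the standard structure algorithms
(bond and hydrogen deduction, fragment splitting, ring perception,
supercells, measurements), and emit deterministic publication-style SVG
without a browser or a GUI.

## What's inside

* **Model** — molecules as atom/bond/ring arrays; drawn bond orders
  {0, ½, 1, 1½, 2, 3} with wedge/hash stereo; Hill-order formula
  (C, H, then alphabetical) and molecular weight; distance, angle and
  IUPAC signed torsion measurements.
* **Algorithms** — covalent bond deduction
  (0.4 Å ≤ d ≤ 1.1·(r_A + r_B), Cordero radii); implicit hydrogens from
  `max(0, V(element, charge) − Σ bond orders − radicals)`;
  connected-component splitting; deep copies; SSSR ring perception
  (a minimum cycle basis — ring count is always E − V + C);
  triclinic fractional→Cartesian supercell construction.
* **I/O** — read MOL V2000, RXN, CML, XYZ, PDB, CIF (P1), JCAMP-DX
  (AFFN + SQZ/DIF/DUP) and a compact JSON dialect
  (`docs/schema.json`); write MOL, CML, JSON, XYZ; content-based format
  sniffing.
* **Depiction** — cascading visual specs (global → canvas → per-atom /
  per-bond), scale-to-fit, automatic implicit-H / lone-pair / charge
  placement, ring-aware double bonds, reaction arrows and brackets, an
  ACS-style preset, byte-deterministic SVG.
* **Spectra** — NMR/IR/UV-Vis/MS container, trapezoidal integration
  with region ratios (smallest = 1.00), integration-curve overlays,
  SVG plots with inverted x for NMR.

## A worked example

```python
from molcanvas import (fixtures, molecular_formula, molecular_weight,
                       perceive_rings_sssr, depict)

benzene = fixtures.benzene()          # 6 C, alternating drawn 1/2 bonds
print(molecular_formula(benzene))     # C6H6
print(round(molecular_weight(benzene), 2))   # 78.11
print([len(r) for r in perceive_rings_sssr(benzene).rings])  # [6]
svg = depict(benzene, 300, 300)
print(svg.count("<line"))             # 9  (6 ring bonds + 3 inner lines)
```

The formula and weight include the six implicit hydrogens the valence
model adds to the bare drawn skeleton; ring perception finds the single
six-membered ring; the depiction draws each double bond as an outer
line plus a shortened inner line on the ring side.

Spectra, end to end:

```python
from molcanvas import integration_curve
from molcanvas.fixtures import gaussian_mixture_spectrum

s = gaussian_mixture_spectrum([(3.0, 1.0, 0.15), (7.0, 2.0, 0.2)],
                              n_points=2000)
r = integration_curve(s, [(2.5, 3.5), (6.5, 7.5)])
print([f"{x:.2f}" for x in r.ratios])   # ['1.00', '2.00']
```

More narrative scripts live in `examples/` — one per capability
(calculations, conversion, deduction, rings/fragments, depiction,
supercells, NMR integration).

## Command line

```bash
molcanvas convert  water.xyz water.mol --deduce-bonds
molcanvas info     benzene.mol                 # formula, weight, rings...
molcanvas depict   benzene.mol out.svg --style acs --spec bond_width=1.2
molcanvas spectrum spec.jdx out.svg --integrate 2.5:3.5 --integrate 6.5:7.5
molcanvas fixtures out_dir --seed 7            # deterministic fixture tree
```

Exit codes: 0 ok, 1 data/parse error, 2 usage error.

## Design notes

Models, assumptions, numerical choices and known limitations are
documented in `docs/methods.md`.
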