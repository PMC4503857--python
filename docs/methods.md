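# Methods

This note documents the models and numerical choices behind molcanvas:
what each algorithm assumes, which knobs matter, and what the synthetic
fixtures do and do not exercise.

## Molecule model

A molecule is three parallel arrays — atoms, bonds, rings — plus a name.
Atoms carry an element label, 2D/3D coordinates, formal charge, radical
and lone-pair counts, and a deduced implicit-hydrogen count.  Bonds use
drawn orders {0, 0.5, 1, 1.5, 2, 3}: 0 is an ionic/zero-order bond, 0.5
a half bond, 1.5 a resonance bond; stereo is `protruding` (wedge) or
`recessed` (hash).  The ring array is a cache: any structural mutation
through the mutating methods clears it, so a populated ring list is
always consistent with the current bonds.

2D drawing coordinates are y-down (screen convention); the geometry
measurements (distance, angle, torsion) are pure Euclidean operations on
3D points with no axis convention.  The torsion follows the IUPAC sign
convention — positive when, sighting down the inner bond, the far bond
is rotated clockwise from the near one.  Note a property of this
convention that is easy to get backwards: the value is *unchanged* when
the four points are traversed in reverse order; it is *negated* by
reflection.  Our implementation agrees with rdkit's
`GetDihedralDeg` to machine precision on random point sets (pinned by a
test).

## Element data and the valence model

`data/elements.tsv` ships elements 1–96 with IUPAC standard atomic
weights, Cordero 2008 single-bond covalent radii (low-spin values where
the published table distinguishes spin states), main-group default
valence lists, and two RGB tables (classic CPK and Jmol; Jmol is the
depiction default).

The implicit-hydrogen target valence of an atom is the first entry of
its element's valence list, adjusted by formal charge:

* pnictogens, chalcogens and halogens: `valence + charge` (a cation
  gains a bonding slot, isoelectronically — N⁺ behaves like carbon;
  an anion loses one — O⁻ behaves like fluorine);
* all other elements (including carbon and boron): `valence − |charge|`;
* clamped at 0; transition metals and the f-block have no tabulated
  valence and never receive implicit hydrogens.

The deduced count is `max(0, target − Σ drawn bond orders − radicals)`,
where resonance (1.5) and half (0.5) bonds contribute 1 and zero-order
bonds contribute 0 — this keeps counts integral and non-negative for
any drawable structure.  On neutral/±1 organic molecules within their
first default valence this model coincides with rdkit's (cross-checked
in tests).

## Bond deduction

Distance-based: a single bond joins every atom pair with
`0.4 Å ≤ d ≤ t·(r_A + r_B)`, tolerance factor `t = 1.1` by default.
The 0.4 Å floor guards against duplicated/overlapping atoms.  Existing
bonds are never duplicated, so the operation is idempotent, and the
bond set depends only on geometry, not atom order.  All deduced bonds
are single; bond-order perception is out of scope.

## Ring perception (SSSR)

The ring set is a minimum cycle basis, so its size always equals the
circuit rank `E − V + C`.  Candidates are Horton's family: for every
vertex v and bond (x, y), the cycle `SP(v,x) + (x,y) + SP(y,v)`
whenever the two BFS shortest paths meet only at v — a family proven to
contain a minimum cycle basis.  Candidates are ranked by (size, atom
indices) and selected greedily under GF(2) linear independence until the
rank is reached; BFS neighbor order is lowest-index-first, making the
output deterministic.  A spanning-forest fundamental basis serves as a
completeness fallback.  Agreement with networkx's `minimum_cycle_basis`
(ring-size multiset) is pinned on hundreds of random graphs.

## Splitting and copying

Connected components are computed over all drawn bonds — including
zero-order ones, so a drawn ion pair stays together.  Components keep
original atom order and are reindexed; copies are deep and fully
independent (rings cache included).

## Unit cells and supercells

A cell is (a, b, c, α, β, γ) with the standard crystallographic
fractional→Cartesian matrix (**a** along x, **b** in the xy-plane).
Supercell construction translates the fractional content by every
integer offset in the na×nb×nc block and converts to Cartesian; atoms
on cell boundaries are intentionally duplicated (no merging), so the
atom count is exactly `N·na·nb·nc`.  The matrix agrees with gemmi's
orthogonalization to < 1e-9 Å.  CIF reading (via gemmi's CIF parser)
takes the atom_site loop literally: no symmetry-operation expansion,
P1 content only.

## File formats

* **MOL V2000** — fixed-column read/write; `M  CHG`/`M  RAD` supersede
  the legacy atom-block codes on read (per the CTfile rules) and are
  the only charge channel on write.  V3000 is rejected explicitly.
  Orders 0/0.5/1.5 are not representable and raise on write.
* **CML 2** — atom/bond arrays, S/D/T or numeric orders, wedge/hash via
  `bondStereo` W/H.  Coordinates are written at 6 decimals.
* **JSON dialect** — short-key records (schema in `docs/schema.json`);
  writers omit default values and use a canonical key order, so a
  read→write pass is byte-stable; unknown keys ride through round trips.
* **XYZ / PDB / CIF / RXN / JCAMP-DX** — read-only.  PDB uses the fixed
  columns, first MODEL only, altLoc blank/'A' only, element inferred
  from the atom name when column 77–78 is blank; unparseable lines are
  skipped with a warning rather than failing the file.  JCAMP supports
  `(X++(Y..Y))` AFFN plus the ASDF SQZ/DIF/DUP digit forms with
  XFACTOR/YFACTOR scaling, the DIF line-checkpoint rule, and an NPOINTS
  consistency check; `##XYPOINTS`/`##PEAK TABLE` pair lists are also
  accepted.
* File coordinates are taken as-is (no y-axis flip on I/O); the y-down
  interpretation applies only at depiction time.
* All parsers accept LF and CRLF; writers emit LF.

`detect_format` sniffs content in a fixed precedence (JSON → RXN →
JCAMP → CML → CIF → PDB → MOL → XYZ); a filename extension only breaks
ties when content is inconclusive.

## Depiction

Visual specifications cascade global → canvas → per-atom/per-bond, most
local wins, field by field; unknown keys are rejected by name.  Defaults:
20 px bond length, 12 px labels, Jmol colors, carbon labels hidden.  The
ACS-style preset (14.4 px bonds, 0.6 px lines, Helvetica 10, monochrome,
2.5 px hash/dash) ships as `data/acs1996.json`.

Scale-to-fit uses `s = min(fit_w, fit_h, bond_length / median bond)`,
dropping inactive terms (no bonds → no bond term; a degenerate box
dimension → no fit term for it; nothing active → s = 1), then centers
the coordinate bounding box on the canvas.  Consequences: drawings are
never blown up beyond the house bond length, a lone atom lands at the
canvas center, and translation of the input changes nothing (byte-
identical SVG).  Rotation preserves the drawn rigid geometry but the
recentering is bounding-box based, so byte equality is not promised
under rotation.

Label placement scans the four candidate sides (right, left, above,
below — that order breaks ties) and picks the one with the greatest
angular clearance from the incident bonds.  Lone pairs split the
largest angular gap recursively, largest first; an isolated atom's four
pairs land at the four cardinal directions.  Carbon atoms are labeled
only when isolated, charged, or radical-bearing (or when
`show_carbon_labels` is on); bond lines are trimmed by
`label_buffer + 0.55·font_size` around drawn labels.

Bond glyphs: double bonds inside a ring put the shortened inner line on
the ring-centroid side; zero-order and half bonds are dashed (half with
half-length dashes); resonance is solid + dashed; wedges are filled
triangles narrow at the begin atom; hash bonds are perpendicular
strokes widening toward the end atom, one per `dash_spacing`.

SVG output is serialized with fixed attribute order and fixed number
formatting (2 decimals, no trailing zeros), so identical input yields
byte-identical files — the golden tests rely on this, and PNG export is
deliberately left to external rasterizers.

## Spectra

A spectrum is a strictly monotonic x series with finite y.  Integration
is trapezoidal with linear interpolation at region cut points — exactly
the area under the piecewise-linear displayed trace — making it additive
over adjacent regions to rounding error and linear in y.  Region ratios
are normalized so the smallest nonzero area reads 1.00 (two-decimal
convention).  Plotting draws a polyline (or per-point sticks for mass
spectra), optional gridlines at the tick interval, and inverts the x
axis for NMR by default.

## Synthetic data

The fixture generator is deterministic from an integer seed.

* Toy molecules (water, methane, ethane, benzene, naphthalene,
  biphenyl, hexane, an NaCl pair, pyridinium) have hand-set coordinates
  at standard geometries.
* Random molecules draw common organic elements, build a spanning tree,
  then add ring closures and multiple bonds only while every atom stays
  within its target valence — so implicit-H deduction never clamps and
  every structure survives every writable format (orders limited to
  1/2/3).
* Random graphs (for ring perception) are spanning trees plus random
  extra edges, with no chemical constraints.
* Synthetic spectra are sums of Gaussian or Lorentzian lineshapes with
  analytically known areas, optionally with Gaussian noise; the JCAMP
  emitter writes AFFN and SQZ/DIF/DUP twins of the same integer raw
  ordinates.

What this does not emulate: real instrument baselines, phase errors or
peak overlap in spectra; crowded 2D layouts needing coordinate
generation (input coordinates are required); macromolecular PDB content.
Tests passing on these fixtures demonstrate the algorithms' contracts,
not robustness to dirty real-world files.

## Problem sizes

The test suite and the acceptance script run at desk scale: 200–300
random graphs of ≤ 12 atoms for ring perception, 500 random molecules
for round trips, 2000-point spectra, 20–50 random cases for geometry
and depiction properties.  These sizes give exact combinatorial checks
(counts, byte equality) and sub-1% statistical ones (integration) in a
few seconds.

## Known limitations

* No aromaticity model: rings are graph cycles; orders are as drawn.
* No SMILES/InChI, no V3000, no mmCIF, no CIF symmetry expansion.
* No 2D coordinate generation from connectivity.
* The charge-adjusted valence rule is a drawing-tool convention, not a
  quantum-chemical statement; exotic oxidation states will read 0
  implicit hydrogens.
* Text metrics are approximated (0.65 em per character) rather than
  measured from font files; extreme font substitutions could overlap
  labels slightly.
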