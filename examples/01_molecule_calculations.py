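"""Build a molecule in memory and compute formula, weight and geometry.

The benzene skeleton is drawn with alternating single/double bonds and
no explicit hydrogens; the valence model fills in the implicit ones.
"""

from molcanvas import (fixtures, measure_angle, measure_distance,
                       measure_torsion, molecular_formula, molecular_weight)

benzene = fixtures.benzene()
print("formula :", molecular_formula(benzene))
print("weight  :", round(molecular_weight(benzene), 2), "amu")
# C6H6 at 78.11 amu: six CH units deduced from the drawn skeleton.

ethane = fixtures.ethane_xyz()
a = [(at.x, at.y, at.z) for at in ethane.atoms]
print("C-C distance :", round(measure_distance(a[0], a[1]), 3), "Å")
print("H-C-C angle  :", round(measure_angle(a[2], a[0], a[1]), 1), "deg")
print("H-C-C-H torsion :", round(measure_torsion(a[2], a[0], a[1], a[5]), 1),
      "deg (staggered conformer, IUPAC sign convention)")
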