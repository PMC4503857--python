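"""Deduce connectivity from raw coordinates, then implicit hydrogens.

An XYZ file carries only element symbols and positions.  Bonds are
created wherever two atoms sit within 1.1x the sum of their covalent
radii; the valence model then assigns implicit hydrogen counts.
"""

from molcanvas import deduce_covalent_bonds, deduce_implicit_hydrogens
from molcanvas.formats import read_xyz

XYZ = """3
water
O  0.00  0.00  0.00
H  0.96  0.00  0.00
H -0.24  0.93  0.00
"""

mol = read_xyz(XYZ)
print("bonds after parse    :", len(mol.bonds))
deduce_covalent_bonds(mol)
print("bonds after deduction:", len(mol.bonds), "(two O-H, no H-H)")
deduce_implicit_hydrogens(mol)
print("implicit H on O      :", mol.atoms[0].implicit_h,
      "(both hydrogens are explicit, so none are added)")
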