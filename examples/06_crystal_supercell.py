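"""Read a CIF, build a supercell, convert fractional to Cartesian.

The unit cell's triclinic transformation matrix places each of the
na*nb*nc translated images; a 2x2x2 expansion of the 2-site rock-salt
cell yields 16 atoms.
"""

from molcanvas import build_supercell
from molcanvas.fixtures import nacl_cif_text
from molcanvas.formats import read_cif

mol, cell = read_cif(nacl_cif_text())
print("cell      :", cell.a, "Å cubic,", len(mol.atoms), "sites")
print("volume    :", round(cell.volume(), 2), "Å^3")

supercell = build_supercell(mol, cell, 2, 2, 2)
print("supercell :", len(supercell.atoms), "atoms")
cl = supercell.atoms[1]
print("first Cl  : (%.2f, %.2f, %.2f) Å  (fractional 0.5,0.5,0.5 -> a/2)"
      % (cl.x, cl.y, cl.z))
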