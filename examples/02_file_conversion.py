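"""Round-trip a structure through MOL V2000, CML and the JSON dialect.

The same molecule survives every chain of writers and readers with
coordinates, charges and stereo intact; detect_format sniffs content.
"""

from molcanvas import fixtures
from molcanvas.formats import (detect_format, read_cdjson, read_cml,
                               read_mol, write_cdjson, write_cml, write_mol)

mol = fixtures.naphthalene()
as_mol = write_mol(mol)
as_cml = write_cml(read_mol(as_mol))
as_json = write_cdjson(read_cml(as_cml)[0])
back = read_cdjson(as_json).molecules[0]

print("atoms preserved :", len(back.atoms) == len(mol.atoms))
print("bonds preserved :", {b.pair() for b in back.bonds}
      == {b.pair() for b in mol.bonds})
print("sniffed formats :", detect_format(as_mol), detect_format(as_cml),
      detect_format(as_json))
print("JSON size       :", len(as_json), "bytes (the lightest format)")
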