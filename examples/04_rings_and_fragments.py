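"""Perceive smallest rings and split disconnected structures.

SSSR returns exactly E - V + C rings, each a smallest cycle: fused
naphthalene gives two 6-rings, never the 10-membered envelope.  A drawn
zero-order bond keeps an ion pair in one fragment.
"""

from molcanvas import fixtures, perceive_rings_sssr, split_disconnected

naph = perceive_rings_sssr(fixtures.naphthalene())
print("naphthalene rings :", [len(r) for r in naph.rings])

biphenyl = perceive_rings_sssr(fixtures.biphenyl())
print("biphenyl rings    :", [len(r) for r in biphenyl.rings],
      "(the bridge bond belongs to no ring)")

salt = fixtures.nacl_pair()
print("NaCl fragments    :", len(split_disconnected(salt)),
      "(zero-order bond counts as a connection)")

benzene = fixtures.benzene()
benzene.add_atom(label="Na", x=10.0, y=0.0)
print("benzene + Na atom :", [len(m.atoms)
                              for m in split_disconnected(benzene)])
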