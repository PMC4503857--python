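"""The container returned by multi-payload readers."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..model import Molecule
from ..spectra import Spectrum

__all__ = ["InterchangeDocument"]


@dataclass
class InterchangeDocument:
    """What a chemical file parsed into.

    ``reaction_roles`` is the (n_reactants, n_products) partition of the
    molecule list for reaction files, None otherwise.
    """

    molecules: list[Molecule] = field(default_factory=list)
    spectra: list[Spectrum] = field(default_factory=list)
    reaction_roles: tuple[int, int] | None = None
    source_format: str = ""

    @property
    def reactants(self) -> list[Molecule]:
        if self.reaction_roles is None:
            return []
        return self.molecules[:self.reaction_roles[0]]

    @property
    def products(self) -> list[Molecule]:
        if self.reaction_roles is None:
            return []
        n = self.reaction_roles[0]
        return self.molecules[n:n + self.reaction_roles[1]]
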