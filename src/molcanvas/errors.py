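"""Exception hierarchy.

Everything raised on purpose by molcanvas derives from
:class:`MolcanvasError`, so callers (including the CLI) can catch one
type and report cleanly.
"""


class MolcanvasError(Exception):
    """Base class for all molcanvas errors."""


class ElementNotFoundError(MolcanvasError, KeyError):
    """An element symbol is not in the packaged periodic table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


class EmptyMoleculeError(MolcanvasError, ValueError):
    """An operation that needs at least one atom got none."""


class DegenerateGeometryError(MolcanvasError, ValueError):
    """Coincident points where a direction or plane is required."""


class InvalidCellError(MolcanvasError, ValueError):
    """Unit-cell lengths/angles do not describe a positive-volume cell."""


class ParseError(MolcanvasError, ValueError):
    """A chemical file could not be parsed.

    ``line`` is the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedDialectError(ParseError):
    """A recognized format in a dialect outside scope (e.g. MOL V3000)."""


class UnknownFormatError(MolcanvasError, ValueError):
    """Content could not be matched to any supported format."""


class CapacityError(MolcanvasError, ValueError):
    """Input exceeds a hard limit of the output format (e.g. V2000 999 atoms)."""


class NoSignalError(MolcanvasError, ValueError):
    """A spectrum operation that needs nonzero intensity got an all-zero y."""


class InvalidRegionsError(MolcanvasError, ValueError):
    """Integration regions overlap or are otherwise inconsistent."""
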