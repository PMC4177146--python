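"""Exception hierarchy for molforge.

All domain failures derive from :class:`MolforgeError` so the CLI can map
them onto exit codes uniformly.
"""


class MolforgeError(Exception):
    """Base class for all molforge errors."""


class UnknownElementError(MolforgeError):
    """An element symbol is not present in the element table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")


class ParseError(MolforgeError):
    """A structure file could not be parsed."""


class MalformedCountError(ParseError):
    """Declared atom count disagrees with the number of atom lines."""


class BadIndexError(MolforgeError, IndexError):
    """An atom index is out of range."""


class NoSuchBondError(MolforgeError):
    """The requested bond does not exist."""


class DuplicateBondError(MolforgeError):
    """The bond to be added already exists (or joins an atom to itself)."""


class RingBondError(MolforgeError):
    """Operation requires a non-ring bond but the bond lies on a cycle."""


class DegenerateGeometryError(MolforgeError):
    """Zero-length arm or collinear atoms where an angle is undefined."""


class EmptyHistoryError(MolforgeError):
    """Undo/redo requested with an empty stack."""


class EmptyMoleculeError(MolforgeError):
    """Operation requires at least one atom."""
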