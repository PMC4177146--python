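"""Element property table.

Every other module resolves element symbols through this one.  The table is
shipped as a plain CSV (``data/elements.csv``) so it is inspectable and can
be overridden: one row per element with the covalent radius (Å, Cordero 2008
compilation), display color (Jmol scheme), main-group valence-electron
count, atomic mass (u) and a p-block flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import UnknownElementError

__all__ = ["ElementRecord", "ElementTable", "lookup", "is_p_block", "covalent_radius"]


@dataclass(frozen=True)
class ElementRecord:
    """Per-element constants used across the package."""

    symbol: str
    covalent_radius: float  # Å, > 0
    color: tuple[int, int, int]  # 0-255 RGB, Jmol scheme
    valence_electrons: int  # s+p electron count for main-group; 0 for d/f-block
    mass: float  # u, > 0
    p_block: bool

    def __post_init__(self):
        if self.covalent_radius <= 0:
            raise ValueError(f"covalent radius must be positive: {self.symbol}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive: {self.symbol}")
        if not 0 <= self.valence_electrons <= 8:
            raise ValueError(f"valence electrons out of [0, 8]: {self.symbol}")


def _normalize(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        return s
    return s[0].upper() + s[1:].lower()


class ElementTable:
    """Symbol -> :class:`ElementRecord` mapping with case-normalizing lookup."""

    def __init__(self, records: dict[str, ElementRecord]):
        self._records = records

    @classmethod
    def from_csv(cls, path: str | Path | None = None) -> "ElementTable":
        """Load a table; defaults to the CSV shipped inside the package."""
        if path is None:
            text = (resources.files("molforge") / "data" / "elements.csv").read_text()
        else:
            text = Path(path).read_text()
        records: dict[str, ElementRecord] = {}
        for row in csv.DictReader(text.splitlines()):
            sym = _normalize(row["symbol"])
            records[sym] = ElementRecord(
                symbol=sym,
                covalent_radius=float(row["covalent_radius"]),
                color=(int(row["r"]), int(row["g"]), int(row["b"])),
                valence_electrons=int(row["valence_electrons"]),
                mass=float(row["mass"]),
                p_block=row["p_block"] == "1",
            )
        return cls(records)

    def lookup(self, symbol: str) -> ElementRecord:
        rec = self._records.get(_normalize(symbol))
        if rec is None:
            raise UnknownElementError(symbol)
        return rec

    def __contains__(self, symbol: str) -> bool:
        return _normalize(symbol) in self._records

    def __len__(self) -> int:
        return len(self._records)

    def symbols(self) -> list[str]:
        return list(self._records)


_DEFAULT: ElementTable | None = None


def default_table() -> ElementTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ElementTable.from_csv()
    return _DEFAULT


def lookup(symbol: str) -> ElementRecord:
    """Look up an element by symbol (case-insensitive: "CL", "cl" -> Cl)."""
    return default_table().lookup(symbol)


def is_p_block(symbol: str) -> bool:
    """True iff the element's differentiating electron is in a p subshell.

    Hydrogen and helium are s-block; hydrogen autocompletion treats H via
    its own rule and never through this predicate.
    """
    return lookup(symbol).p_block


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å from the shipped table."""
    return lookup(symbol).covalent_radius
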