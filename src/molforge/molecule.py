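"""The Molecule container: ordered atoms plus an unordered bond set.

Bonds are plain connectivity — index pairs with no order attribute.  Atom
indices are 0-based internally; file formats and the CLI surface use
1-based numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BadIndexError, DuplicateBondError, NoSuchBondError

__all__ = ["Atom", "Molecule"]


@dataclass
class Atom:
    symbol: str
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.symbol, self.position.copy())


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class Molecule:
    """Atoms (symbol + Cartesian Å coordinates) and bonds (index pairs)."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: set[tuple[int, int]] = field(default_factory=set)
    title: str = ""

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_arrays(cls, symbols, coords, bonds=(), title="") -> "Molecule":
        coords = np.asarray(coords, dtype=float).reshape(len(symbols), 3)
        atoms = [Atom(s, c) for s, c in zip(symbols, coords)]
        mol = cls(atoms=atoms, title=title)
        for i, j in bonds:
            mol.add_bond(i, j)
        return mol

    # -- basics --------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array; a copy, safe to mutate."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, coords):
            atom.position = row.copy()

    def check_index(self, i: int) -> None:
        if not (isinstance(i, (int, np.integer)) and 0 <= i < len(self.atoms)):
            raise BadIndexError(f"atom index out of range: {i}")

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[a.copy() for a in self.atoms],
            bonds=set(self.bonds),
            title=self.title,
        )

    # -- bond bookkeeping ----------------------------------------------------
    def has_bond(self, i: int, j: int) -> bool:
        return _canon(i, j) in self.bonds

    def add_bond(self, i: int, j: int) -> None:
        self.check_index(i)
        self.check_index(j)
        if i == j:
            raise DuplicateBondError(f"cannot bond atom {i} to itself")
        b = _canon(i, j)
        if b in self.bonds:
            raise DuplicateBondError(f"bond {b} already present")
        self.bonds.add(b)

    def remove_bond(self, i: int, j: int) -> None:
        b = _canon(i, j)
        if b not in self.bonds:
            raise NoSuchBondError(f"no bond {b}")
        self.bonds.remove(b)

    def neighbors(self, i: int) -> list[int]:
        """Bonded partners of atom i, ascending."""
        self.check_index(i)
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    # -- equality used by undo tests ----------------------------------------
    def same_structure(self, other: "Molecule", tol: float = 0.0) -> bool:
        """Field-for-field equality (coordinates within tol)."""
        if self.symbols != other.symbols or self.bonds != other.bonds:
            return False
        if self.title != other.title:
            return False
        if len(self) == 0:
            return True
        return bool(np.allclose(self.coords, other.coords, rtol=0.0, atol=tol))

    def formula(self) -> str:
        """Hill-order molecular formula (C, H, then alphabetical)."""
        from collections import Counter

        counts = Counter(self.symbols)
        parts = []
        for sym in ["C", "H"]:
            if sym in counts:
                n = counts.pop(sym)
                parts.append(sym + (str(n) if n > 1 else ""))
        for sym in sorted(counts):
            n = counts[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)
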