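"""Structure editing: add/change/delete atoms and bonds, hydrogen
autocompletion, fragment rotation about non-ring bonds, bounded undo/redo.

Editing operations are functional: each takes a molecule (and optionally an
:class:`EditHistory`), pushes a snapshot of the input onto the history, and
returns a new molecule.  Existing atoms are never moved by atom-addition
operations.

Hydrogen autocompletion follows the octet rule for p-block elements:
``needed = clamp(8 − valence_electrons − existing_bonds, 0, 3)``.  Added
hydrogens sit at the covalent-radii-sum distance, at the ideal angle of the
chosen hybridization (sp3 109.471°, sp2 120°, sp 180°).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .elements import default_table, is_p_block
from .errors import EmptyHistoryError
from .geometry import RotationSpec, rotate
from .molecule import Atom, Molecule
from .perception import split_by_bond

__all__ = [
    "Hybridization",
    "EditHistory",
    "hydrogens_needed",
    "open_direction",
    "ideal_fill_directions",
    "change_element",
    "add_bonded_atom",
    "add_hydrogen",
    "delete_atom",
    "add_bond",
    "delete_bond",
    "rotate_fragment",
    "undo",
    "redo",
]

_TETRAHEDRAL = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.4712...


class Hybridization(Enum):
    """sp3 / sp2 / sp with the corresponding VSEPR ideal angle."""

    SP3 = "sp3"
    SP2 = "sp2"
    SP = "sp"

    @property
    def ideal_angle(self) -> float:
        return {"sp3": _TETRAHEDRAL, "sp2": 120.0, "sp": 180.0}[self.value]

    @property
    def max_neighbors(self) -> int:
        return {"sp3": 4, "sp2": 3, "sp": 2}[self.value]

    @classmethod
    def parse(cls, name: str) -> "Hybridization":
        return cls(name.strip().lower())


@dataclass
class EditHistory:
    """Bounded snapshot stacks for undo and redo (capacity 10 each).

    The oldest snapshot is evicted on overflow; any new edit clears the
    redo stack.
    """

    capacity: int = 10
    undo_stack: list[Molecule] = field(default_factory=list)
    redo_stack: list[Molecule] = field(default_factory=list)

    def record(self, molecule: Molecule) -> None:
        """Push a pre-edit snapshot; called by every editing operation."""
        self.undo_stack.append(molecule.copy())
        if len(self.undo_stack) > self.capacity:
            self.undo_stack.pop(0)
        self.redo_stack.clear()

    @property
    def can_undo(self) -> bool:
        return bool(self.undo_stack)

    @property
    def can_redo(self) -> bool:
        return bool(self.redo_stack)


def undo(history: EditHistory, molecule: Molecule) -> Molecule:
    """Restore the previous snapshot, pushing the current state for redo."""
    if not history.undo_stack:
        raise EmptyHistoryError("nothing to undo")
    history.redo_stack.append(molecule.copy())
    if len(history.redo_stack) > history.capacity:
        history.redo_stack.pop(0)
    return history.undo_stack.pop()


def redo(history: EditHistory, molecule: Molecule) -> Molecule:
    """Re-apply an undone edit."""
    if not history.redo_stack:
        raise EmptyHistoryError("nothing to redo")
    history.undo_stack.append(molecule.copy())
    if len(history.undo_stack) > history.capacity:
        history.undo_stack.pop(0)
    return history.redo_stack.pop()


def hydrogens_needed(symbol: str, existing_bonds: int) -> int:
    """Octet-rule hydrogen count for a p-block atom with the given bonds.

    clamp(8 − V − B, 0, 3); 0 for any non-p-block element (the original
    builder adds hydrogens for p-block elements only).
    """
    rec = default_table().lookup(symbol)
    if not rec.p_block:
        return 0
    return int(np.clip(8 - rec.valence_electrons - existing_bonds, 0, 3))


# ---------------------------------------------------------------------------
# direction selection

_DEFAULT_DIRECTION = np.array([0.0, 0.0, 1.0])


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def open_direction(molecule: Molecule, target: int) -> np.ndarray:
    """Unit vector from `target` maximizing the minimum angle to its bonds.

    Analytic for 1–3 existing bonds (negative normalized sum of unit bond
    vectors); deterministic spherical grid search otherwise or when the
    analytic vector degenerates (e.g. trans-collinear bonds).
    """
    nbrs = molecule.neighbors(target)
    if not nbrs:
        return _DEFAULT_DIRECTION.copy()
    p = molecule.atoms[target].position
    units = []
    for n in nbrs:
        v = molecule.atoms[n].position - p
        norm = np.linalg.norm(v)
        if norm > 0:
            units.append(v / norm)
    if not units:
        return _DEFAULT_DIRECTION.copy()
    units = np.array(units)
    if len(units) <= 3:
        s = -units.sum(axis=0)
        norm = np.linalg.norm(s)
        if norm > 1e-6:
            return s / norm
    # grid search: maximize the minimum angular separation
    grid = _fibonacci_sphere(2000)
    cosines = grid @ units.T  # (2000, k)
    worst = cosines.max(axis=1)  # smallest angle per candidate
    return grid[int(np.argmin(worst))].copy()


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing `d` to a right-handed frame.

    The first lies in the plane of `d` and a fixed reference (global z,
    falling back to x when parallel) so placement is deterministic.
    """
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, d)) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
    u = ref - np.dot(ref, d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def ideal_fill_directions(existing: np.ndarray, count: int, hyb: Hybridization) -> list[np.ndarray]:
    """Unit directions completing a center's coordination at ideal angles.

    `existing` holds the unit vectors of the center's current bonds.  With
    one existing bond the new directions sit at the hybridization's ideal
    angle from it, azimuthally spaced, the first in the plane of the bond
    and a fixed reference vector.  With two existing bonds a pair of new
    directions straddles the existing-bond plane symmetrically; a single
    one takes the in-plane open direction.  With three (or a bare atom)
    the negative-sum / default direction is used.
    """
    theta = np.radians(hyb.ideal_angle)
    if len(existing) == 0:
        d = -_DEFAULT_DIRECTION
        existing = d.reshape(1, 3)  # pretend a bond points down: H's fan upward
        n_real = 0
    else:
        n_real = len(existing)

    if n_real <= 1:
        d = existing[0]
        u, v = _orthonormal_frame(d)
        spacing = 2.0 * np.pi / max(hyb.max_neighbors - 1, 1)
        out = []
        for m in range(count):
            az = m * spacing
            out.append(np.cos(theta) * d + np.sin(theta) * (np.cos(az) * u + np.sin(az) * v))
        return out

    s = -existing.sum(axis=0)
    norm = np.linalg.norm(s)
    bisector = s / norm if norm > 1e-9 else _DEFAULT_DIRECTION.copy()
    if n_real == 2 and count == 2:
        w = np.cross(existing[0], existing[1])
        wn = np.linalg.norm(w)
        if wn < 1e-9:  # collinear existing bonds: fall back to frame method
            u, v = _orthonormal_frame(existing[0])
            w = v
        else:
            w = w / wn
        half = theta / 2.0
        return [
            np.cos(half) * bisector + np.sin(half) * w,
            np.cos(half) * bisector - np.sin(half) * w,
        ]
    # one slot left (or over-coordinated): open direction, repeated if needed
    return [bisector.copy() for _ in range(count)]


def _hydrogen_fill(molecule: Molecule, target: int, hyb: Hybridization) -> None:
    """Append octet-rule hydrogens around `target` in place (p-block only)."""
    sym = molecule.atoms[target].symbol
    nbrs = molecule.neighbors(target)
    count = hydrogens_needed(sym, len(nbrs))
    if count == 0:
        return
    table = default_table()
    length = table.lookup(sym).covalent_radius + table.lookup("H").covalent_radius
    p = molecule.atoms[target].position
    units = []
    for n in nbrs:
        v = molecule.atoms[n].position - p
        nv = np.linalg.norm(v)
        if nv > 0:
            units.append(v / nv)
    for direction in ideal_fill_directions(np.array(units).reshape(-1, 3), count, hyb):
        molecule.atoms.append(Atom("H", p + length * direction))
        molecule.bonds.add((target, len(molecule) - 1))


# ---------------------------------------------------------------------------
# editing operations


def _begin(molecule: Molecule, history: EditHistory | None) -> Molecule:
    if history is not None:
        history.record(molecule)
    return molecule.copy()


def change_element(
    molecule: Molecule,
    history: EditHistory | None,
    target: int,
    new_symbol: str,
    hyb: Hybridization = Hybridization.SP3,
) -> Molecule:
    """Change the element of an atom.

    With two or more bonds only the symbol changes.  With exactly one bond
    the atom is repositioned along its bond at the new covalent-radii-sum
    distance from the neighbor, then hydrogens are autocompleted (p-block
    elements only).  An isolated atom changes symbol in place.
    """
    molecule.check_index(target)
    rec = default_table().lookup(new_symbol)
    out = _begin(molecule, history)
    atom = out.atoms[target]
    nbrs = out.neighbors(target)
    atom.symbol = rec.symbol
    if len(nbrs) == 1:
        table = default_table()
        nb = out.atoms[nbrs[0]]
        d = atom.position - nb.position
        norm = np.linalg.norm(d)
        d = d / norm if norm > 0 else _DEFAULT_DIRECTION
        ideal = rec.covalent_radius + table.lookup(nb.symbol).covalent_radius
        atom.position = nb.position + ideal * d
        if is_p_block(rec.symbol):
            _hydrogen_fill(out, target, hyb)
    return out


def add_bonded_atom(
    molecule: Molecule,
    history: EditHistory | None,
    parent: int,
    symbol: str,
    hyb: Hybridization = Hybridization.SP3,
) -> Molecule:
    """Attach a new atom to `parent` along its most open direction.

    The new bond length is the sum of covalent radii; the new atom then
    receives octet-rule hydrogens (computed with its one bond to parent).
    """
    molecule.check_index(parent)
    table = default_table()
    rec = table.lookup(symbol)
    out = _begin(molecule, history)
    direction = open_direction(out, parent)
    length = rec.covalent_radius + table.lookup(out.atoms[parent].symbol).covalent_radius
    pos = out.atoms[parent].position + length * direction
    out.atoms.append(Atom(rec.symbol, pos))
    new_idx = len(out) - 1
    out.bonds.add((parent, new_idx) if parent < new_idx else (new_idx, parent))
    if is_p_block(rec.symbol):
        _hydrogen_fill(out, new_idx, hyb)
    return out


def add_hydrogen(molecule: Molecule, history: EditHistory | None, target: int) -> Molecule:
    """Add a single H to `target`, placed to minimize crowding.

    The direction maximizes the minimum angle to the target's existing
    bonds; no other atom moves, so the result on a strained center is not
    necessarily ideal.
    """
    molecule.check_index(target)
    table = default_table()
    out = _begin(molecule, history)
    direction = open_direction(out, target)
    length = table.lookup(out.atoms[target].symbol).covalent_radius + table.lookup("H").covalent_radius
    out.atoms.append(Atom("H", out.atoms[target].position + length * direction))
    new_idx = len(out) - 1
    out.bonds.add((target, new_idx) if target < new_idx else (new_idx, target))
    return out


def delete_atom(molecule: Molecule, history: EditHistory | None, target: int) -> Molecule:
    """Delete an atom together with its directly attached hydrogens."""
    molecule.check_index(target)
    out = _begin(molecule, history)
    doomed = {target}
    doomed.update(n for n in out.neighbors(target) if out.atoms[n].symbol == "H")
    keep = [i for i in range(len(out)) if i not in doomed]
    remap = {old: new for new, old in enumerate(keep)}
    out.atoms = [out.atoms[i] for i in keep]
    out.bonds = {
        (min(remap[a], remap[b]), max(remap[a], remap[b]))
        for a, b in out.bonds
        if a in remap and b in remap
    }
    return out


def add_bond(molecule: Molecule, history: EditHistory | None, i: int, j: int) -> Molecule:
    """Create a bond between two existing atoms; geometry untouched."""
    out = _begin(molecule, history)
    out.add_bond(i, j)
    return out


def delete_bond(molecule: Molecule, history: EditHistory | None, i: int, j: int) -> Molecule:
    """Remove an existing bond; geometry untouched."""
    molecule.check_index(i)
    molecule.check_index(j)
    out = _begin(molecule, history)
    out.remove_bond(i, j)
    return out


def rotate_fragment(
    molecule: Molecule,
    history: EditHistory | None,
    bond: tuple[int, int],
    angle_deg: float,
) -> Molecule:
    """Rotate one side of a non-ring bond about the bond axis.

    The smaller of the two fragments moves (tie: the fragment containing
    the second bond index); the rest of the molecule is fixed.
    """
    side_a, side_b = split_by_bond(molecule, bond)  # raises RingBondError
    i, j = bond
    if len(side_a) < len(side_b):
        moving, anchor_idx = side_a, j
    elif len(side_b) < len(side_a):
        moving, anchor_idx = side_b, i
    else:
        moving, anchor_idx = (side_a, j) if i in side_a else (side_b, i)
    out = _begin(molecule, history)
    axis = out.atoms[j].position - out.atoms[i].position
    axis = axis / np.linalg.norm(axis)
    spec = RotationSpec(axis=axis, angle=np.radians(angle_deg),
                        anchor=out.atoms[anchor_idx].position.copy())
    rotated = rotate(out, spec, subset=moving)
    rotated.title = out.title
    return rotated
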