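"""Measurement and rigid transformations.

Distances in Å, angles and dihedrals reported in degrees (radians
internal).  Whole-molecule axis rotations pivot about the centroid unless
an explicit anchor is given; bond-axis rotations pivot about their anchor
point.  Rotation matrices come from scipy's Rotation.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .elements import default_table
from .errors import DegenerateGeometryError
from .molecule import Molecule

__all__ = [
    "RotationSpec",
    "distance",
    "angle",
    "dihedral",
    "rotate",
    "translate",
    "mirror",
    "molecular_weight",
    "heavy_atom_coordinates",
]

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


@dataclass(frozen=True)
class RotationSpec:
    """Rotation by `angle` radians about a named axis or an arbitrary one.

    `axis` is "x"/"y"/"z" (anchor defaults to the molecular centroid) or a
    unit 3-vector with an explicit `anchor` point.
    """

    axis: str | np.ndarray
    angle: float  # radians
    anchor: np.ndarray | None = None

    def direction(self) -> np.ndarray:
        if isinstance(self.axis, str):
            try:
                return _AXES[self.axis]
            except KeyError:
                raise ValueError(f"axis must be x, y, z or a vector: {self.axis!r}")
        v = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError("bond-defined axis vector must have unit norm")
        return v


def distance(molecule: Molecule, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j in Å."""
    molecule.check_index(i)
    molecule.check_index(j)
    return float(np.linalg.norm(molecule.atoms[i].position - molecule.atoms[j].position))


def angle(molecule: Molecule, i: int, j: int, k: int) -> float:
    """Angle i–j–k (vertex j) in degrees, in [0, 180]."""
    for idx in (i, j, k):
        molecule.check_index(idx)
    a = molecule.atoms[i].position - molecule.atoms[j].position
    b = molecule.atoms[k].position - molecule.atoms[j].position
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("zero-length arm in angle measurement")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def dihedral(molecule: Molecule, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i–j–k–l in degrees, in (−180, 180].

    Sign follows the right-hand rule about the j→k axis; the value is the
    angle between plane (i,j,k) and plane (j,k,l).
    """
    for idx in (i, j, k, l):
        molecule.check_index(idx)
    p = [molecule.atoms[x].position for x in (i, j, k, l)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    deg = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if deg == -180.0 else deg


def rotate(
    molecule: Molecule,
    spec: RotationSpec,
    subset: Iterable[int] | None = None,
) -> Molecule:
    """Rotate `subset` atoms (default: all) per the spec; returns a new Molecule."""
    out = molecule.copy()
    if len(out) == 0:
        return out
    idx = list(range(len(out))) if subset is None else sorted(set(subset))
    for x in idx:
        out.check_index(x)
    if spec.anchor is not None:
        anchor = np.asarray(spec.anchor, dtype=float)
    else:
        anchor = out.coords.mean(axis=0)  # centroid pivot
    rot = Rotation.from_rotvec(spec.angle * spec.direction())
    coords = out.coords
    coords[idx] = rot.apply(coords[idx] - anchor) + anchor
    out.set_coords(coords)
    return out


def translate(molecule: Molecule, shift: np.ndarray) -> Molecule:
    """Translate every atom by `shift` (3-vector, Å)."""
    out = molecule.copy()
    shift = np.asarray(shift, dtype=float)
    for atom in out.atoms:
        atom.position = atom.position + shift
    return out


def mirror(molecule: Molecule, plane: str) -> Molecule:
    """Reflect through a coordinate plane ("xy", "xz" or "yz"); bonds unchanged."""
    normal_axis = {"xy": 2, "xz": 1, "yz": 0}
    if plane not in normal_axis:
        raise ValueError(f"plane must be one of xy, xz, yz: {plane!r}")
    out = molecule.copy()
    ax = normal_axis[plane]
    for atom in out.atoms:
        atom.position = atom.position.copy()
        atom.position[ax] = -atom.position[ax]
    return out


def molecular_weight(molecule: Molecule) -> float:
    """Sum of atomic masses in u."""
    table = default_table()
    return float(sum(table.lookup(s).mass for s in molecule.symbols))


def heavy_atom_coordinates(molecule: Molecule) -> list[tuple[str, np.ndarray]]:
    """(symbol, position) for all non-hydrogen atoms, original order."""
    return [(a.symbol, a.position.copy()) for a in molecule.atoms if a.symbol != "H"]
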