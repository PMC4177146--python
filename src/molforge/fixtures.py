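"""Programmatic ideal-geometry test molecules.

Every fixture is constructed from the shipped covalent-radii table, so
bond lengths equal radii sums exactly and bond-perception tests are
self-consistent whatever radii compilation the table carries.  Generation
is deterministic given (name, parameters, seed).
"""

from __future__ import annotations

import numpy as np

from .editing import Hybridization, _hydrogen_fill
from .elements import covalent_radius
from .errors import MolforgeError
from .molecule import Atom, Molecule

__all__ = ["FIXTURE_NAMES", "make"]

_TET = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)

_TET_ANGLE = np.degrees(np.arccos(-1.0 / 3.0))


class UnknownFixtureError(MolforgeError):
    pass


def _ch() -> float:
    return covalent_radius("C") + covalent_radius("H")


def _cc() -> float:
    return 2.0 * covalent_radius("C")


def _methane() -> Molecule:
    atoms = [Atom("C", [0.0, 0.0, 0.0])]
    atoms += [Atom("H", _ch() * d) for d in _TET]
    m = Molecule(atoms=atoms, title="methane (ideal)")
    for h in range(1, 5):
        m.bonds.add((0, h))
    return m


def _ethane(offset_deg: float, title: str) -> Molecule:
    """Two carbons along z; H azimuths on C2 shifted by `offset_deg`."""
    cc = _cc()
    theta = np.radians(_TET_ANGLE)
    atoms = [Atom("C", [0.0, 0.0, 0.0]), Atom("C", [0.0, 0.0, cc])]
    bonds = {(0, 1)}
    for az_deg in (0.0, 120.0, 240.0):  # C1 hydrogens fan downward
        az = np.radians(az_deg)
        d = np.array([np.sin(theta) * np.cos(az), np.sin(theta) * np.sin(az), np.cos(theta)])
        atoms.append(Atom("H", _ch() * d))
        bonds.add((0, len(atoms) - 1))
    for az_deg in (offset_deg, offset_deg + 120.0, offset_deg + 240.0):
        az = np.radians(az_deg)
        d = np.array([np.sin(theta) * np.cos(az), np.sin(theta) * np.sin(az), -np.cos(theta)])
        atoms.append(Atom("H", np.array([0.0, 0.0, cc]) + _ch() * d))
        bonds.add((1, len(atoms) - 1))
    return Molecule(atoms=atoms, bonds=bonds, title=title)


def _benzene() -> Molecule:
    cc = _cc()
    atoms, bonds = [], set()
    for k in range(6):
        a = np.radians(60.0 * k)
        atoms.append(Atom("C", [cc * np.cos(a), cc * np.sin(a), 0.0]))
    for k in range(6):
        a = np.radians(60.0 * k)
        r = cc + _ch()
        atoms.append(Atom("H", [r * np.cos(a), r * np.sin(a), 0.0]))
        bonds.add((k, (k + 1) % 6) if k < (k + 1) % 6 else ((k + 1) % 6, k))
        bonds.add((k, 6 + k))
    return Molecule(atoms=atoms, bonds=bonds, title="benzene (planar ideal)")


def _methylcyclohexane_skeleton() -> Molecule:
    """Seven carbons: planar hexagon plus a radial methyl carbon (no H)."""
    cc = _cc()
    atoms = []
    for k in range(6):
        a = np.radians(60.0 * k)
        atoms.append(Atom("C", [cc * np.cos(a), cc * np.sin(a), 0.0]))
    atoms.append(Atom("C", [2.0 * cc, 0.0, 0.0]))  # methyl on ring atom 0
    bonds = set()
    for k in range(6):
        j = (k + 1) % 6
        bonds.add((min(k, j), max(k, j)))
    bonds.add((0, 6))
    return Molecule(atoms=atoms, bonds=bonds, title="methylcyclohexane skeleton")


def _s_2_butanol() -> Molecule:
    """2-butanol with the S configuration at C2, ideal sp3 geometry.

    Heavy skeleton placed on tetrahedral directions about the chiral
    carbon, hydrogens completed at ideal angles.  Atom order: C2, O, C1,
    C3, H(C2), C4, then remaining hydrogens.
    """
    r_co = covalent_radius("C") + covalent_radius("O")
    cc, ch = _cc(), _ch()
    atoms = [
        Atom("C", [0.0, 0.0, 0.0]),  # C2, chiral center
        Atom("O", r_co * _TET[0]),  # hydroxyl O
        Atom("C", cc * _TET[2]),  # C1 methyl
        Atom("C", cc * _TET[1]),  # C3 methylene
        Atom("H", ch * _TET[3]),  # H on C2
    ]
    bonds = {(0, 1), (0, 2), (0, 3), (0, 4)}
    # C4 at the tetrahedral angle from the C3->C2 bond
    from .editing import ideal_fill_directions

    to_c2 = -atoms[3].position / np.linalg.norm(atoms[3].position)
    d4 = ideal_fill_directions(to_c2.reshape(1, 3), 1, Hybridization.SP3)[0]
    atoms.append(Atom("C", atoms[3].position + cc * d4))
    bonds.add((3, 5))
    m = Molecule(atoms=atoms, bonds=bonds, title="S-2-butanol (ideal)")
    for heavy in (1, 2, 3, 5):  # O-H, methyl/methylene hydrogens
        _hydrogen_fill(m, heavy, Hybridization.SP3)
    return m


def _cube_corners(n: int = 8, side: float = 3.0) -> Molecule:
    """Zinc atoms on the vertices of a cubic unit cell; no bonds."""
    if n != 8:
        raise UnknownFixtureError("cube_corners supports n=8 only")
    atoms = [
        Atom("Zn", [side * x, side * y, side * z])
        for x in (0, 1) for y in (0, 1) for z in (0, 1)
    ]
    return Molecule(atoms=atoms, title="unit-cell corner atoms")


def _random_cloud(n: int, seed: int, box: float = 4.0) -> Molecule:
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    atoms = [Atom("C", c) for c in coords]
    return Molecule(atoms=atoms, title=f"random cloud n={n} seed={seed}")


FIXTURE_NAMES = (
    "methane",
    "ethane_staggered",
    "ethane_eclipsed",
    "benzene",
    "methylcyclohexane_skeleton",
    "s_2_butanol",
    "cube_corners",
    "random_cloud",
)


def make(
    name: str,
    n: int | None = None,
    seed: int = 0,
    box: float = 4.0,
    perturbation: float = 0.0,
    perturbation_seed: int = 0,
) -> Molecule:
    """Build a named fixture; optional uniform coordinate noise (Å)."""
    if name == "methane":
        mol = _methane()
    elif name == "ethane_staggered":
        mol = _ethane(60.0, "ethane (staggered)")
    elif name == "ethane_eclipsed":
        mol = _ethane(0.0, "ethane (eclipsed)")
    elif name == "benzene":
        mol = _benzene()
    elif name == "methylcyclohexane_skeleton":
        mol = _methylcyclohexane_skeleton()
    elif name == "s_2_butanol":
        mol = _s_2_butanol()
    elif name == "cube_corners":
        mol = _cube_corners(8 if n is None else n)
    elif name == "random_cloud":
        mol = _random_cloud(12 if n is None else n, seed, box)
    else:
        raise UnknownFixtureError(f"unknown fixture: {name!r}")
    if perturbation > 0.0:
        rng = np.random.default_rng(perturbation_seed)
        noise = rng.uniform(-perturbation, perturbation, size=(len(mol), 3))
        mol.set_coords(mol.coords + noise)
    return mol
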