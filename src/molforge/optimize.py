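"""Crude, force-field-free geometry clean-up.

Not molecular mechanics: each iteration makes three damped correction
passes —

1. **bonds** — every bond length is moved toward the covalent-radii sum,
   both atoms displaced symmetrically along the bond axis;
2. **angles** — every bond angle at every center is moved toward the
   center's VSEPR ideal (sp3 109.471°, sp2 120°, sp 180°), the two arm
   atoms rotated in the plane of the angle;
3. **torsions** — every rotatable (non-ring) bond's substituent dihedrals
   are moved toward the staggered arrangement (60° + n·120°), the smaller
   fragment rotating about the bond.

Corrections are damped by ``step_fraction``; iteration stops when the
largest per-atom displacement in a full cycle falls below
``coordinate_tolerance`` or after ``max_iterations``.  Connectivity is
never altered.  The pass structure is deterministic: passes in the order
above, bonds/centers/pairs in ascending index order, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .editing import Hybridization
from .elements import default_table
from .molecule import Molecule
from .perception import bond_in_ring, split_by_bond

__all__ = ["OptimizeSettings", "optimize", "strain_energy"]


@dataclass(frozen=True)
class OptimizeSettings:
    max_iterations: int = 200
    coordinate_tolerance: float = 1e-4  # Å, max per-atom displacement per cycle
    step_fraction: float = 0.5  # fraction of each ideal correction applied

    def __post_init__(self):
        if self.max_iterations <= 0 or self.coordinate_tolerance <= 0:
            raise ValueError("max_iterations and coordinate_tolerance must be positive")
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step_fraction must be in (0, 1]")


def _hyb_of(hyb_assignments, i: int) -> Hybridization:
    if hyb_assignments and i in hyb_assignments:
        return hyb_assignments[i]
    return Hybridization.SP3


def _ideal_lengths(molecule: Molecule) -> dict[tuple[int, int], float]:
    table = default_table()
    radii = [table.lookup(s).covalent_radius for s in molecule.symbols]
    return {(i, j): radii[i] + radii[j] for i, j in molecule.bonds}


def strain_energy(molecule: Molecule, hyb_assignments=None) -> float:
    """Surrogate objective Σ(len − ideal)² + Σ(θ − ideal)².

    Lengths in Å, angles in radians (comparable magnitudes).  Used only to
    monitor descent; the optimizer itself is a geometric relaxation, not a
    minimizer of this quantity per se.
    """
    from .geometry import angle as angle_of

    coords = molecule.coords
    e = 0.0
    for (i, j), ideal in _ideal_lengths(molecule).items():
        e += (np.linalg.norm(coords[i] - coords[j]) - ideal) ** 2
    for j in range(len(molecule)):
        nbrs = molecule.neighbors(j)
        ideal = _hyb_of(hyb_assignments, j).ideal_angle
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                dev = np.radians(angle_of(molecule, nbrs[a], j, nbrs[b]) - ideal)
                e += dev ** 2
    return e


def _bond_pass(mol: Molecule, ideals: dict, step: float) -> None:
    for (i, j), ideal in sorted(ideals.items()):
        pi, pj = mol.atoms[i].position, mol.atoms[j].position
        d = pj - pi
        length = np.linalg.norm(d)
        if length < 1e-12:
            continue
        u = d / length
        shift = 0.5 * step * (ideal - length)
        mol.atoms[i].position = pi - shift * u
        mol.atoms[j].position = pj + shift * u


def _rotate_about(p: np.ndarray, center: np.ndarray, axis: np.ndarray, phi: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(phi * axis).apply(p - center) + center


def _angle_pass(mol: Molecule, hyb_assignments, step: float) -> None:
    # Jacobi-style: corrections for every angle pair are computed against
    # the same starting coordinates and each atom then moves by the mean of
    # its accumulated corrections.  Applying pair rotations sequentially is
    # unstable when centers share arm atoms (corrections pump each other).
    n = len(mol)
    delta = np.zeros((n, 3))
    counts = np.zeros(n)
    for j in range(n):
        nbrs = mol.neighbors(j)
        if len(nbrs) < 2:
            continue
        ideal = np.radians(_hyb_of(hyb_assignments, j).ideal_angle)
        pj = mol.atoms[j].position
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                a = mol.atoms[i].position - pj
                b = mol.atoms[k].position - pj
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na < 1e-12 or nb < 1e-12:
                    continue
                cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
                theta = np.arccos(cos)
                axis = np.cross(a, b)
                norm = np.linalg.norm(axis)
                if norm < 1e-9:  # collinear arms: any perpendicular axis
                    axis = np.cross(a, [0.0, 0.0, 1.0])
                    if np.linalg.norm(axis) < 1e-9:
                        axis = np.cross(a, [1.0, 0.0, 0.0])
                    norm = np.linalg.norm(axis)
                axis /= norm
                # rotating arm a by +phi about the axis closes the angle
                half = 0.5 * step * (ideal - theta)
                delta[i] += _rotate_about(mol.atoms[i].position, pj, axis, -half) - mol.atoms[i].position
                delta[k] += _rotate_about(mol.atoms[k].position, pj, axis, +half) - mol.atoms[k].position
                counts[i] += 1
                counts[k] += 1
    for i in range(n):
        if counts[i]:
            mol.atoms[i].position = mol.atoms[i].position + delta[i] / counts[i]


def _staggered_deviation(dihedral_deg: float) -> float:
    """Signed offset from the nearest staggered value (60° + n·120°), in (−60, 60]."""
    dev = (dihedral_deg - 60.0) % 120.0
    return dev - 120.0 if dev > 60.0 else dev


def _torsion_pass(mol: Molecule, step: float) -> None:
    from .geometry import dihedral as dihedral_of

    for i, j in sorted(mol.bonds):
        left = [n for n in mol.neighbors(i) if n != j]
        right = [n for n in mol.neighbors(j) if n != i]
        if not left or not right:
            continue
        if bond_in_ring(mol, (i, j)):
            continue
        devs = []
        for a in left:
            for b in right:
                try:
                    devs.append(_staggered_deviation(dihedral_of(mol, a, i, j, b)))
                except Exception:
                    continue  # collinear substituent: skip this pair
        if not devs:
            continue
        correction = -step * float(np.mean(devs))
        if abs(correction) < 1e-12:
            continue
        side_i, side_j = split_by_bond(mol, (i, j))
        # rotating the j-side by +phi about the i->j axis subtracts phi
        # from every a-i-j-b dihedral (right-hand sign convention)
        axis = mol.atoms[j].position - mol.atoms[i].position
        axis /= np.linalg.norm(axis)
        if len(side_j) <= len(side_i):
            moving, phi = side_j, -np.radians(correction)
        else:
            moving, phi = side_i, np.radians(correction)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(phi * axis)
        anchor = mol.atoms[i].position.copy()
        for idx in moving:
            mol.atoms[idx].position = rot.apply(mol.atoms[idx].position - anchor) + anchor


def optimize(
    molecule: Molecule,
    settings: OptimizeSettings = OptimizeSettings(),
    hyb_assignments: dict[int, Hybridization] | None = None,
) -> tuple[Molecule, int, bool]:
    """Relax bond lengths, angles and torsions toward their crude ideals.

    Returns ``(optimized molecule, iterations used, converged flag)``.
    Atoms without an entry in `hyb_assignments` default to sp3.
    Non-convergence is reported via the flag, never raised.
    """
    if len(molecule) == 0:
        raise ValueError("cannot optimize an empty molecule")
    mol = molecule.copy()
    ideals = _ideal_lengths(mol)
    converged = False
    iterations = 0
    for iterations in range(1, settings.max_iterations + 1):
        before = mol.coords
        _bond_pass(mol, ideals, settings.step_fraction)
        _angle_pass(mol, hyb_assignments, settings.step_fraction)
        _torsion_pass(mol, settings.step_fraction)
        max_disp = float(np.max(np.linalg.norm(mol.coords - before, axis=1))) if len(mol) else 0.0
        if max_disp < settings.coordinate_tolerance:
            converged = True
            break
    return mol, iterations, converged
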