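"""Distance-based bond perception and ring/fragment queries.

A bond is perceived between atoms i and j when their separation is
strictly less than ``factor × (r_i + r_j)`` with covalent radii from the
element table; the default factor is 1.2.  Equality at the cutoff yields
no bond.  Ring membership is answered per-query by a connectivity check
after edge removal — molecules here are small, so no ring set is cached.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .elements import default_table
from .errors import NoSuchBondError, RingBondError
from .molecule import Molecule

__all__ = ["BondRule", "perceive_bonds", "bond_in_ring", "split_by_bond"]


@dataclass(frozen=True)
class BondRule:
    """Multiplier on the covalent-radii sum defining the bond cutoff."""

    factor: float = 1.2

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("bond factor must be positive")


def perceive_bonds(molecule: Molecule, rule: BondRule = BondRule()) -> Molecule:
    """Replace the bond set from geometry: {i,j} iff dist < factor·(r_i+r_j).

    All atom pairs are examined; the input molecule is not mutated.
    """
    table = default_table()
    out = molecule.copy()
    n = len(out)
    out.bonds = set()
    if n < 2:
        return out
    radii = np.array([table.lookup(s).covalent_radius for s in out.symbols])
    dists = squareform(pdist(out.coords))
    cutoff = rule.factor * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(dists < cutoff)
    for i, j in zip(ii, jj):
        if i < j:
            out.bonds.add((int(i), int(j)))
    return out


def _graph(molecule: Molecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(molecule)))
    g.add_edges_from(molecule.bonds)
    return g


def bond_in_ring(molecule: Molecule, bond: tuple[int, int]) -> bool:
    """True iff the bond lies on a cycle.

    Equivalent test: after deleting the edge its endpoints remain
    connected by some other path.
    """
    i, j = bond
    if not molecule.has_bond(i, j):
        raise NoSuchBondError(f"no bond between atoms {i} and {j}")
    g = _graph(molecule)
    g.remove_edge(i, j)
    return nx.has_path(g, i, j)


def split_by_bond(molecule: Molecule, bond: tuple[int, int]) -> tuple[set[int], set[int]]:
    """Connected components on either side of a non-ring bond.

    Returns (component containing bond[0], component containing bond[1]);
    raises :class:`RingBondError` if the bond lies on a cycle.
    """
    i, j = bond
    if bond_in_ring(molecule, bond):
        raise RingBondError(f"bond ({i}, {j}) is part of a ring")
    g = _graph(molecule)
    g.remove_edge(i, j)
    side_i = set(nx.node_connected_component(g, i))
    side_j = set(nx.node_connected_component(g, j))
    return side_i, side_j
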