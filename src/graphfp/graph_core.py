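"""Distance matrices, exhaustive DFS path enumeration and canonicalization.

Shared engine for all encoders:

* the topological distance matrix ``T`` of shortest-path bond counts
  (Floyd–Warshall; disconnected pairs hold ``inf``),
* the binned geometrical distance matrix ``G`` with entries
  ``floor(|c_i - c_j| * s)`` for a scaling factor ``s``,
* enumeration of all simple paths of 1..d bonds from a root atom,
* string canonicalization of labeled paths (the lexicographically greater of
  the two reading directions is kept).

Bond symbols inside pattern strings: ``-`` for single *and* aromatic bonds
(so aromaticity-perception differences cannot change path strings), ``=`` for
double and ``#`` for triple bonds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from scipy.spatial.distance import cdist

from .chem_model import Bond, Molecule

__all__ = [
    "BOND_SYMBOLS",
    "bond_symbol",
    "LabeledPath",
    "topo_matrix",
    "geom_matrix",
    "dfs_paths",
    "render_path",
    "canonical_string",
]

BOND_SYMBOLS = {1: "-", 2: "=", 3: "#"}


def bond_symbol(bond: Bond) -> str:
    if bond.aromatic:
        return "-"
    return BOND_SYMBOLS[bond.order]


@dataclass(frozen=True)
class LabeledPath:
    """A simple path: atom indices, per-atom labels, per-step bond symbols."""

    atoms: tuple[int, ...]
    labels: tuple[str, ...]
    bond_symbols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.bond_symbols)

    @property
    def root(self) -> int:
        return self.atoms[0]

    @property
    def last(self) -> int:
        return self.atoms[-1]


def topo_matrix(mol: Molecule) -> np.ndarray:
    """Shortest-path bond-count matrix (n x n, ``inf`` between fragments)."""
    n = mol.n_atoms
    adj = np.zeros((n, n))
    for b in mol.bonds:
        adj[b.i, b.j] = adj[b.j, b.i] = 1
    if n == 1:
        return np.zeros((1, 1))
    return floyd_warshall(adj, directed=False, unweighted=True)


def geom_matrix(mol: Molecule, s: float = 1.0) -> np.ndarray:
    """Binned scaled Euclidean distance matrix: ``floor(dist * s)``, int."""
    if s <= 0:
        raise ValueError("scaling factor s must be positive")
    if not mol.has_coords:
        raise ValueError(
            f"no 3D information for record {mol.title or '<untitled>'}"
        )
    coords = mol.coord_array()
    return np.floor(cdist(coords, coords) * s).astype(int)


def dfs_paths(
    mol: Molecule,
    root: int,
    d: int,
    labels: Sequence[str],
) -> List[LabeledPath]:
    """All simple paths of 1..d bonds starting at ``root``, exhaustively."""
    if d < 1:
        raise ValueError("depth d must be >= 1")
    adj = mol.adjacency()
    out: List[LabeledPath] = []
    path_atoms = [root]
    path_labels = [labels[root]]
    path_bonds: list[str] = []
    visited = {root}

    def _extend(current: int) -> None:
        for nbr, bond in adj[current]:
            if nbr in visited:
                continue
            path_atoms.append(nbr)
            path_labels.append(labels[nbr])
            path_bonds.append(bond_symbol(bond))
            visited.add(nbr)
            out.append(
                LabeledPath(tuple(path_atoms), tuple(path_labels), tuple(path_bonds))
            )
            if len(path_bonds) < d:
                _extend(nbr)
            visited.discard(nbr)
            path_atoms.pop()
            path_labels.pop()
            path_bonds.pop()

    _extend(root)
    return out


def render_path(labels: Sequence[str], bond_symbols: Sequence[str]) -> str:
    """Root-anchored rendering: label, bond symbol, label, ..."""
    parts = [labels[0]]
    for sym, lbl in zip(bond_symbols, labels[1:]):
        parts.append(sym)
        parts.append(lbl)
    return "".join(parts)


def canonical_string(path: LabeledPath) -> str:
    """The lexicographically greater of the two reading directions."""
    forward = render_path(path.labels, path.bond_symbols)
    backward = render_path(path.labels[::-1], path.bond_symbols[::-1])
    return forward if forward >= backward else backward
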