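"""Hydrogen-depleted molecule model and MDL SD file input.

All fingerprint encoders in this package operate on a hydrogen-depleted
heavy-atom graph.  Explicit hydrogens present in the input connection table
are folded into the per-atom ``h_count`` attribute at parse time, before any
typing or distance computation.  Ring and aromaticity perception is delegated
to RDKit's default sanitization model.

Heavy atoms keep their input-file order; every encoder is required to be
invariant under permutation of that order (tested in the encoder suite).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "EmptyInputError",
    "read_sdf",
    "read_sdf_text",
    "get_label",
    "build_molecule",
]


class EmptyInputError(ValueError):
    """Raised when an SD input contains records but none of them parse."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a hydrogen-depleted molecular graph.

    ``heavy_valence`` is the atom's total valence minus the number of attached
    hydrogens, i.e. the number of connections to heavy atoms counted with bond
    order (the third field of the Daylight invariant label).
    """

    index: int
    element: str
    atomic_number: int
    charge: int
    h_count: int
    mass: int
    in_ring: bool
    in_aromatic_ring: bool
    heavy_degree: int
    heavy_valence: int
    coords: Optional[np.ndarray] = None


@dataclass(frozen=True)
class Bond:
    """Undirected bond between two heavy atoms; order is 1, 2 or 3."""

    i: int
    j: int
    order: int
    aromatic: bool = False

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class Molecule:
    """Hydrogen-depleted heavy-atom graph with SD record properties."""

    atoms: list[Atom]
    bonds: list[Bond]
    properties: dict[str, str] = field(default_factory=dict)
    title: str = ""
    _adjacency: Optional[list[list[tuple[int, Bond]]]] = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_coords(self) -> bool:
        return all(a.coords is not None for a in self.atoms)

    def adjacency(self) -> list[list[tuple[int, Bond]]]:
        """Neighbor lists: ``adjacency()[i]`` is a list of ``(j, bond)``."""
        if self._adjacency is None:
            adj: list[list[tuple[int, Bond]]] = [[] for _ in self.atoms]
            for b in self.bonds:
                adj[b.i].append((b.j, b))
                adj[b.j].append((b.i, b))
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, i: int) -> list[tuple[int, Bond]]:
        return self.adjacency()[i]

    def coord_array(self) -> np.ndarray:
        """(n, 3) coordinate array; raises if any atom lacks coordinates."""
        if not self.has_coords:
            raise ValueError(
                f"no 3D information for record {self.title or '<untitled>'}"
            )
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    @classmethod
    def from_rdkit(cls, rdmol) -> "Molecule":
        """Convert an RDKit mol (hydrogens already removed) to a Molecule."""
        from rdkit import Chem

        conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
        atoms = []
        for a in rdmol.GetAtoms():
            coords = None
            if conf is not None:
                p = conf.GetAtomPosition(a.GetIdx())
                coords = np.array([p.x, p.y, p.z], dtype=float)
            atoms.append(
                Atom(
                    index=a.GetIdx(),
                    element=a.GetSymbol(),
                    atomic_number=a.GetAtomicNum(),
                    charge=a.GetFormalCharge(),
                    h_count=a.GetTotalNumHs(),
                    mass=int(round(a.GetMass())),
                    in_ring=a.IsInRing(),
                    in_aromatic_ring=a.GetIsAromatic() and a.IsInRing(),
                    heavy_degree=a.GetDegree(),
                    heavy_valence=a.GetTotalValence() - a.GetTotalNumHs(),
                    coords=coords,
                )
            )
        bonds = []
        for b in rdmol.GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC or b.GetIsAromatic():
                order = 1
                aromatic = True
            else:
                order = int(b.GetBondTypeAsDouble())
                aromatic = False
            bonds.append(
                Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, aromatic)
            )
        props = {}
        for name in rdmol.GetPropNames():
            props[name] = rdmol.GetProp(name)
        title = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        return cls(atoms=atoms, bonds=bonds, properties=props, title=title)


# -- construction without a connection-table backend -------------------------

_STANDARD_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1,
                     "Cl": 1, "Br": 1, "I": 1, "B": 3, "H": 1}


def build_molecule(
    elements: Sequence[str],
    bonds: Iterable[tuple[int, int] | tuple[int, int, int]],
    *,
    charges: Optional[Sequence[int]] = None,
    h_counts: Optional[Sequence[Optional[int]]] = None,
    coords: Optional[Sequence[Sequence[float]]] = None,
    properties: Optional[dict[str, str]] = None,
    title: str = "",
) -> Molecule:
    """Build a Molecule directly from element symbols and a bond list.

    Hydrogen counts default to the element's standard valence minus the sum of
    heavy bond orders (floored at 0).  Ring membership is perceived from the
    cycle space of the graph; aromaticity is not assigned here.
    """
    import networkx as nx
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    n = len(elements)
    bond_objs = []
    order_sum = [0] * n
    degree = [0] * n
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for spec in bonds:
        i, j = spec[0], spec[1]
        order = spec[2] if len(spec) > 2 else 1
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
        bond_objs.append(Bond(i, j, order))
        order_sum[i] += order
        order_sum[j] += order
        degree[i] += 1
        degree[j] += 1
        g.add_edge(i, j)

    ring_atoms: set[int] = set()
    for cycle in nx.cycle_basis(g):
        ring_atoms.update(cycle)

    charges = list(charges) if charges is not None else [0] * n
    atoms = []
    for idx, sym in enumerate(elements):
        if h_counts is not None and h_counts[idx] is not None:
            hc = h_counts[idx]
        else:
            hc = max(_STANDARD_VALENCE.get(sym, 0) - order_sum[idx] - abs(charges[idx]), 0)
        xyz = None
        if coords is not None:
            xyz = np.asarray(coords[idx], dtype=float)
        atoms.append(
            Atom(
                index=idx,
                element=sym,
                atomic_number=pt.GetAtomicNumber(sym),
                charge=charges[idx],
                h_count=hc,
                mass=int(round(pt.GetAtomicWeight(sym))),
                in_ring=idx in ring_atoms,
                in_aromatic_ring=False,
                heavy_degree=degree[idx],
                heavy_valence=order_sum[idx],
                coords=xyz,
            )
        )
    return Molecule(atoms=atoms, bonds=bond_objs,
                    properties=dict(properties or {}), title=title)


# -- SD file input ------------------------------------------------------------

def _supplier_to_molecules(supplier, source: str) -> list[Molecule]:
    mols: list[Molecule] = []
    n_records = 0
    for idx, rdmol in enumerate(supplier):
        n_records += 1
        if rdmol is None:
            logger.warning("skipping unparseable record %d in %s", idx, source)
            continue
        mols.append(Molecule.from_rdkit(rdmol))
    if n_records > 0 and not mols:
        raise EmptyInputError(f"empty input: no parsable records in {source}")
    return mols


def read_sdf(path: Union[str, Path]) -> list[Molecule]:
    """Read a V2000 MDL SD file into a list of hydrogen-depleted Molecules.

    Explicit hydrogens are removed and folded into ``h_count``.  Records that
    fail to parse are skipped with a logged warning; a file whose records all
    fail raises :class:`EmptyInputError`.  An empty file yields ``[]``.
    """
    from rdkit import Chem

    path = Path(path)
    text = path.read_text()  # raises OSError for unreadable files
    if not text.strip():
        return []
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=True, removeHs=True)
    return _supplier_to_molecules(supplier, str(path))


def read_sdf_text(text: str) -> list[Molecule]:
    """Parse SD-format text (as shipped by the fixtures module)."""
    from rdkit import Chem

    if not text.strip():
        return []
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=True, removeHs=True)
    return _supplier_to_molecules(supplier, "<string>")


def get_label(mol: Molecule, property_name: str) -> Union[float, str, None]:
    """Learning label from an SD property: numeric if it parses, else text.

    A missing property returns ``None`` (the missing marker), never raises.
    """
    if property_name not in mol.properties:
        return None
    raw = mol.properties[property_name]
    try:
        value = float(raw)
    except ValueError:
        return raw
    if math.isnan(value):
        return raw
    return value
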