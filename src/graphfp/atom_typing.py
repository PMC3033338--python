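"""Atom labeling schemes and potential pharmacophore point (PPP) assignment.

The labeling function maps each heavy atom to a discrete string label that is
embedded in every fingerprint pattern.  Five schemes are supported, from the
bare element symbol up to full Daylight invariants.  The HYBRID scheme is a
hybridization-based approximation of expert-system atom types (e.g. ``C.sp2``)
and is not promised to be identical to any particular expert system.

PPPs follow the five CATS interaction classes — donor (D), acceptor (A),
positive (P), negative (N), lipophilic (L) — assigned by direct neighborhood
searches.  An atom carries a (possibly empty) *set* of PPPs; e.g. a hydroxyl
oxygen is both donor and acceptor.
"""

from __future__ import annotations

import enum
from typing import FrozenSet, List

from .chem_model import Molecule

__all__ = ["LabelScheme", "PPP", "label_atoms", "assign_ppps"]


class LabelScheme(enum.Enum):
    """Atom labeling (typing) schemes."""

    ELEMENT = "E"
    ELEMENT_NEIGHBOR = "EN"
    ELEMENT_RING_NEIGHBOR = "ERN"
    DAYLIGHT_INVARIANT = "DIR"
    HYBRID = "HYB"

    @classmethod
    def from_name(cls, name: str) -> "LabelScheme":
        key = name.strip().upper()
        for member in cls:
            if key in (member.name, member.value):
                return member
        raise ValueError(
            f"unknown atom typing scheme {name!r}; choose from "
            + ", ".join(m.value for m in cls)
        )


class PPP(str, enum.Enum):
    """Potential pharmacophore point classes."""

    D = "D"  # hydrogen-bond donor
    A = "A"  # hydrogen-bond acceptor
    P = "P"  # positively charged / ionizable
    N = "N"  # negatively charged / ionizable
    L = "L"  # lipophilic

    def __str__(self) -> str:  # render as bare letter inside patterns
        return self.value


def _hybridization_tag(mol: Molecule, idx: int) -> str:
    atom = mol.atoms[idx]
    if atom.in_aromatic_ring:
        return "ar"
    orders = [b.order for _, b in mol.neighbors(idx)]
    if 3 in orders or orders.count(2) >= 2:
        return "sp"
    if 2 in orders:
        return "sp2"
    return "sp3"


def label_atoms(mol: Molecule, scheme: LabelScheme) -> List[str]:
    """Apply a labeling scheme; returns one label string per heavy atom."""
    labels = []
    for atom in mol.atoms:
        if scheme is LabelScheme.ELEMENT:
            lbl = atom.element
        elif scheme is LabelScheme.ELEMENT_NEIGHBOR:
            lbl = f"{atom.element}.{atom.heavy_degree}"
        elif scheme is LabelScheme.ELEMENT_RING_NEIGHBOR:
            if atom.in_aromatic_ring:
                lbl = f"{atom.element}.a.{atom.heavy_degree}"
            elif atom.in_ring:
                lbl = f"{atom.element}.r.{atom.heavy_degree}"
            else:
                lbl = f"{atom.element}.{atom.heavy_degree}"
        elif scheme is LabelScheme.DAYLIGHT_INVARIANT:
            lbl = ".".join(
                str(v)
                for v in (
                    atom.atomic_number,
                    atom.heavy_degree,
                    atom.heavy_valence,
                    atom.mass,
                    atom.charge,
                    atom.h_count,
                    int(atom.in_ring),
                )
            )
        elif scheme is LabelScheme.HYBRID:
            lbl = f"{atom.element}.{_hybridization_tag(mol, atom.index)}"
            if atom.charge > 0:
                lbl += "+"
            elif atom.charge < 0:
                lbl += "-"
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown scheme {scheme!r}")
        labels.append(lbl)
    return labels


def _is_acid_center(mol: Molecule, idx: int) -> bool:
    """COOH/SOOH/POOH center: C/S/P with a =O neighbor and an -OH neighbor."""
    atom = mol.atoms[idx]
    if atom.element not in ("C", "S", "P"):
        return False
    has_dbl_o = False
    has_oh = False
    for j, bond in mol.neighbors(idx):
        nbr = mol.atoms[j]
        if nbr.element != "O":
            continue
        if bond.order == 2:
            has_dbl_o = True
        elif bond.order == 1 and nbr.h_count >= 1:
            has_oh = True
    return has_dbl_o and has_oh


def assign_ppps(mol: Molecule) -> List[FrozenSet[PPP]]:
    """Assign the set of potential pharmacophore points to every atom.

    Rules (direct graph searches):

    * D — oxygen of an OH group; nitrogen of an NH or NH2 group.
    * A — any oxygen; nitrogen with no attached hydrogen.
    * P — atom with positive formal charge; nitrogen of an NH2 group.
    * N — atom with negative formal charge; the central C/S/P of a
      COOH/SOOH/POOH group.
    * L — Cl/Br/I; sulfur bonded to exactly two carbons; carbon whose heavy
      neighbors are at least one and all carbon.
    """
    result: List[FrozenSet[PPP]] = []
    for atom in mol.atoms:
        ppps: set[PPP] = set()
        idx = atom.index
        elem = atom.element
        nbr_elems = [mol.atoms[j].element for j, _ in mol.neighbors(idx)]

        if elem == "O" and atom.h_count >= 1:
            ppps.add(PPP.D)
        if elem == "N" and atom.h_count >= 1:
            ppps.add(PPP.D)

        if elem == "O":
            ppps.add(PPP.A)
        if elem == "N" and atom.h_count == 0:
            ppps.add(PPP.A)

        if atom.charge > 0:
            ppps.add(PPP.P)
        if elem == "N" and atom.h_count == 2:
            ppps.add(PPP.P)

        if atom.charge < 0:
            ppps.add(PPP.N)
        if _is_acid_center(mol, idx):
            ppps.add(PPP.N)

        if elem in ("Cl", "Br", "I"):
            ppps.add(PPP.L)
        if elem == "S" and len(nbr_elems) == 2 and all(e == "C" for e in nbr_elems):
            ppps.add(PPP.L)
        if elem == "C" and nbr_elems and all(e == "C" for e in nbr_elems):
            ppps.add(PPP.L)

        result.append(frozenset(ppps))
    return result
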