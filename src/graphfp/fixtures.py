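"""Deterministic in-repo test molecules; nothing here needs a download.

The centerpiece is Oxaceprol (N-acetyl-4-hydroxyproline, 12 heavy atoms),
shipped as an embedded SD text block with a fixed 3D conformer.  Its atom
numbering is the one used throughout the worked examples: 1 acetyl CH3,
2 acetyl carbonyl C, 3 amide N, 4/5/7/8 ring carbons (5 bears the hydroxyl
O 6, 7 bears the carboxyl group 10/11/12), 9 acetyl O.  On that numbering
the pharmacophore points are 1=L, 3=A, 6={D,A}, 8=L, 9=A, 10=N, 11=A,
12={D,A}, and the acceptor-acceptor topological distance spectrum is
{2: 2 pairs, 3: 3 pairs, 5: 5 pairs}.

Parametric all-carbon chains and rings (1.54 A edges) cover the generic
graph shapes the encoders must handle.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .chem_model import Molecule, build_molecule, read_sdf_text

__all__ = [
    "OXACEPROL_SDF",
    "oxaceprol",
    "make_chain",
    "make_ring",
    "chain_sdf_text",
    "permute_molecule",
]

# Fixed conformer (MMFF-relaxed); any reasonable geometry serves, the
# geometric-encoder tests assert structural properties, not exact bins.
OXACEPROL_SDF = """oxaceprol
     graphfp        3D

 12 12  0  0  0  0  0  0  0  0999 V2000
   -2.3246    1.3586    0.6957 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5348    0.1740    1.1915 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4067   -0.1742    0.4845 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.3404   -1.3695    0.8209 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8737   -1.8576   -0.5207 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0560   -2.6277   -0.4046 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0708    0.4099   -0.7786 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.1590   -0.5572   -1.2624 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9019   -0.4485    2.1879 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.6924    1.8035   -0.6678 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0614    2.4862   -1.6119 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.8638    2.2480    0.5918 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  2  9  2  0
  3  4  1  0
  3  7  1  0
  4  5  1  0
  5  6  1  0
  5  8  1  0
  7  8  1  0
  7 10  1  0
 10 11  2  0
 10 12  1  0
M  END

$$$$
"""

BOND_LENGTH = 1.54  # Angstrom, C-C single bond


def oxaceprol() -> Molecule:
    """The Oxaceprol fixture molecule (12 heavy atoms, 3D coordinates)."""
    return read_sdf_text(OXACEPROL_SDF)[0]


def make_chain(n: int, element: str = "C") -> Molecule:
    """All-carbon chain of n atoms, single bonds, on a line (1.54 A steps)."""
    if n < 1:
        raise ValueError("chain needs n >= 1")
    coords = [(i * BOND_LENGTH, 0.0, 0.0) for i in range(n)]
    return build_molecule(
        [element] * n,
        [(i, i + 1) for i in range(n - 1)],
        coords=coords,
        title=f"chain{n}",
    )


def make_ring(n: int, element: str = "C") -> Molecule:
    """All-carbon ring of n atoms on a regular polygon with 1.54 A edges."""
    if n < 3:
        raise ValueError("ring needs n >= 3")
    radius = BOND_LENGTH / (2 * math.sin(math.pi / n))
    coords = [
        (radius * math.cos(2 * math.pi * i / n),
         radius * math.sin(2 * math.pi * i / n),
         0.0)
        for i in range(n)
    ]
    return build_molecule(
        [element] * n,
        [(i, (i + 1) % n) for i in range(n)],
        coords=coords,
        title=f"ring{n}",
    )


def _chain_molblock(n: int, title: str) -> str:
    lines = [title, "     graphfp        3D", ""]
    lines.append(f"{n:3d}{n - 1:3d}  0  0  0  0  0  0  0  0999 V2000")
    for i in range(n):
        x = i * BOND_LENGTH
        lines.append(
            f"{x:10.4f}{0.0:10.4f}{0.0:10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i in range(1, n):
        lines.append(f"{i:3d}{i + 1:3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines)


def chain_sdf_text(
    lengths: Sequence[int],
    labels: Optional[Sequence[str]] = None,
    label_property: str = "label",
) -> str:
    """SD text with one all-carbon chain record per requested length.

    Optionally attaches a label value as an SD property to each record, so
    exporter and CLI tests have a learning label to read.
    """
    records = []
    for idx, n in enumerate(lengths):
        block = _chain_molblock(n, title=f"chain{n}")
        if labels is not None:
            block += f"\n\n>  <{label_property}>\n{labels[idx]}\n"
        records.append(block + "\n$$$$\n")
    return "".join(records)


def permute_molecule(mol: Molecule, perm: Sequence[int]) -> Molecule:
    """Relabel atom input order by ``perm`` (new index of old atom i).

    Utility for the permutation-invariance tests: every encoder must produce
    the identical feature multiset on the permuted molecule.
    """
    from dataclasses import replace

    n = mol.n_atoms
    if sorted(perm) != list(range(n)):
        raise ValueError("perm must be a permutation of range(n)")
    new_atoms: list = [None] * n
    for old, atom in enumerate(mol.atoms):
        new_atoms[perm[old]] = replace(atom, index=perm[old])
    new_bonds = [
        replace(b, i=min(perm[b.i], perm[b.j]), j=max(perm[b.i], perm[b.j]))
        for b in mol.bonds
    ]
    return Molecule(
        atoms=new_atoms,
        bonds=new_bonds,
        properties=dict(mol.properties),
        title=mol.title,
    )
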