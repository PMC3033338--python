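"""Shared fixtures and pattern-canonicalization helpers for the suite."""

from __future__ import annotations

import itertools
import random
import re

import pytest

from graphfp.chem_model import Molecule, build_molecule
from graphfp.fixtures import oxaceprol


@pytest.fixture(scope="session")
def oxa() -> Molecule:
    return oxaceprol()


def random_molecule(
    rng: random.Random,
    n_min: int = 2,
    n_max: int = 10,
    elements: tuple[str, ...] = ("C", "C", "C", "C", "N", "O", "S", "Cl"),
    p_extra_edge: float = 0.25,
    with_coords: bool = True,
) -> Molecule:
    """Random connected molecule-like graph: spanning tree plus chords."""
    n = rng.randint(n_min, n_max)
    bonds: list[tuple[int, int, int]] = []
    edges = set()
    for i in range(1, n):
        j = rng.randrange(i)
        order = 2 if rng.random() < 0.15 else 1
        bonds.append((j, i, order))
        edges.add((j, i))
    extra = int(p_extra_edge * n)
    for _ in range(extra):
        i, j = rng.sample(range(n), 2) if n > 1 else (0, 0)
        i, j = min(i, j), max(i, j)
        if i != j and (i, j) not in edges:
            edges.add((i, j))
            bonds.append((i, j, 1))
    elems = [rng.choice(elements) for _ in range(n)]
    # terminal-only elements must not get high degrees; force carbon there
    degree = [0] * n
    for i, j, _ in bonds:
        degree[i] += 1
        degree[j] += 1
    for idx in range(n):
        if elems[idx] in ("Cl", "O") and degree[idx] > 2:
            elems[idx] = "C"
    coords = None
    if with_coords:
        coords = [
            (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(-5, 5))
            for _ in range(n)
        ]
    return build_molecule(elems, bonds, coords=coords, title="random")


# -- canonical equivalents of printed pattern strings ------------------------

def canon_sequence(pattern: str) -> str:
    """Canonical form of a path or pair pattern: the lexicographically
    greater of the two reading directions (spaces around bond symbols are
    ignored)."""
    s = pattern.replace(" ", "")
    tokens = re.split(r"([-=#])", s)
    rev = "".join(reversed(tokens))
    return s if s >= rev else rev


def canon_triplet(pattern: str) -> str:
    """Canonical form of a printed triplet pattern: the lexicographic
    maximum over the six rendering orders."""
    s = pattern.replace(" ", "")
    tok = s.split("-")
    assert len(tok) == 6, pattern
    la, dab, lb, dbc, lc, dca = tok
    dist = {
        frozenset((0, 1)): dab,
        frozenset((1, 2)): dbc,
        frozenset((0, 2)): dca,
    }
    lbl = {0: la, 1: lb, 2: lc}
    best = None
    for a, b, c in itertools.permutations(range(3)):
        cand = (
            f"{lbl[a]}-{dist[frozenset((a, b))]}-{lbl[b]}-"
            f"{dist[frozenset((b, c))]}-{lbl[c]}-{dist[frozenset((c, a))]}"
        )
        if best is None or cand > best:
            best = cand
    return best
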