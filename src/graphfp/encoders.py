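"""The fingerprint encodings: molecular graph -> multiset of features.

Seventeen encodings are provided, split into topological (shortest-path
distances) and geometrical (binned scaled Euclidean distances) families:

========== ===============================================================
DFS        all simple paths up to depth d (all-path fingerprint)
ASP        the subset of DFS paths that are shortest paths
AP2D/AP3D  atom pairs: label-distance-label
AT2D/AT3D  atom triplets: three labels and three pairwise distances
CATS2D/3D  pharmacophore pair autocorrelation, fixed (d+1)*15 vector
PHAP2PT*   pharmacophore pairs (all PPPs of both atoms)
PHAP3PT*   pharmacophore triplets
SHED       15-entry vector: perplexity of each PPP-pair distance spectrum
ECFP       circular substructures grown around each atom (explicit graph)
RAD2D/3D   cumulative radial shells of neighbor labels (Molprint-like)
LSTAR      radial shells of root-anchored path strings
========== ===============================================================

Multiset encoders return a ``collections.Counter`` over pattern strings
(recurrence counting: re-generating a pattern increments its count); CATS and
SHED return a :class:`FixedVector`.  Every encoder is invariant under
permutation of the atom input order.
"""

from __future__ import annotations

import enum
import itertools
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np

from .atom_typing import PPP, LabelScheme, assign_ppps, label_atoms
from .chem_model import Molecule
from .graph_core import (
    LabeledPath,
    bond_symbol,
    canonical_string,
    dfs_paths,
    geom_matrix,
    render_path,
    topo_matrix,
)

__all__ = [
    "Metric",
    "EncodingConfig",
    "FixedVector",
    "PAIR_BLOCKS",
    "cats_flat_index",
    "encode_dfs",
    "encode_asp",
    "encode_atom_pairs",
    "encode_atom_triplets",
    "encode_cats",
    "encode_pharm_pairs",
    "encode_pharm_triplets",
    "encode_shed",
    "encode_ecfp",
    "encode_radial_shells",
    "encode_lstar",
    "ENCODINGS",
    "DEFAULT_CONFIGS",
    "get_config",
    "encode",
]


class Metric(enum.Enum):
    TOPO = "topological"
    GEOM = "geometrical"


#: The 15 unordered PPP pair types in their fixed block order.
PAIR_BLOCKS = (
    "AA", "AD", "AL", "AN", "AP",
    "DD", "DL", "DN", "DP",
    "LL", "LN", "LP",
    "NN", "NP", "PP",
)
_BLOCK_INDEX = {name: i for i, name in enumerate(PAIR_BLOCKS)}


def _pair_block(a: PPP, b: PPP) -> str:
    x, y = sorted((a.value, b.value))
    return x + y


def cats_flat_index(pair: str, distance: int, d: int) -> int:
    """Flat CATS vector index of ``pair`` (e.g. "DN") at a distance.

    The vector has ``(d + 1) * 15`` entries; each pair block owns ``d + 1``
    consecutive cells, distance 0 first.  With d=9 the DN cell at distance 6
    is index 76.
    """
    key = "".join(sorted(pair))
    if key not in _BLOCK_INDEX:
        raise ValueError(f"unknown PPP pair {pair!r}")
    if not 0 <= distance <= d:
        raise ValueError(f"distance {distance} outside [0, {d}]")
    return _BLOCK_INDEX[key] * (d + 1) + distance


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of one encoding: depth/cut-off, scaling, labeling scheme."""

    name: str
    d: int
    scheme: Optional[LabelScheme] = None  # None => PPP-typed encoding
    s: float = 1.0  # geometric scaling factor (3D encodings only)

    def __post_init__(self) -> None:
        minimum = 0 if self.name == "ECFP" else 1
        if self.d < minimum:
            raise ValueError(f"{self.name}: d must be >= {minimum}")


@dataclass(frozen=True)
class FixedVector:
    """Fixed-dimension real vector laid out in 15 PPP-pair blocks."""

    values: np.ndarray
    bins_per_block: int  # d + 1 for CATS, 1 for SHED

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, idx):
        return self.values[idx]

    def block(self, pair: str) -> np.ndarray:
        i = _BLOCK_INDEX["".join(sorted(pair))]
        return self.values[i * self.bins_per_block:(i + 1) * self.bins_per_block]


# ---------------------------------------------------------------------------
# helpers

def _labels(mol: Molecule, cfg: EncodingConfig) -> List[str]:
    scheme = cfg.scheme if cfg.scheme is not None else LabelScheme.ELEMENT_NEIGHBOR
    return label_atoms(mol, scheme)


def _distance_matrix(mol: Molecule, cfg: EncodingConfig, metric: Metric) -> np.ndarray:
    if metric is Metric.TOPO:
        return topo_matrix(mol)
    return geom_matrix(mol, cfg.s)


def _canonical_pair(la: str, dist: int, lb: str) -> str:
    fwd = f"{la}-{dist}-{lb}"
    bwd = f"{lb}-{dist}-{la}"
    return fwd if fwd >= bwd else bwd


def _canonical_triplet(
    labels: Sequence[str], dists: Dict[tuple[int, int], int], triple: tuple[int, int, int]
) -> str:
    """Lexicographic maximum over the six rendering orders of a triplet."""
    best = None
    for a, b, c in itertools.permutations(triple):
        s = (
            f"{labels[a]}-{dists[min(a, b), max(a, b)]}-"
            f"{labels[b]}-{dists[min(b, c), max(b, c)]}-"
            f"{labels[c]}-{dists[min(c, a), max(c, a)]}"
        )
        if best is None or s > best:
            best = s
    return best


def _pair_iter(dmat: np.ndarray, d: int):
    """Upper-half pairs with distance within [1, d]."""
    n = dmat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dist = dmat[i, j]
            if 1 <= dist <= d:
                yield i, j, int(dist)


# ---------------------------------------------------------------------------
# path encodings

def encode_dfs(mol: Molecule, cfg: EncodingConfig) -> Counter:
    """All-path fingerprint: canonical strings of every DFS path, counted."""
    labels = _labels(mol, cfg)
    features: Counter = Counter()
    for root in range(mol.n_atoms):
        for path in dfs_paths(mol, root, cfg.d, labels):
            features[canonical_string(path)] += 1
    return features


def encode_asp(mol: Molecule, cfg: EncodingConfig) -> Counter:
    """All-shortest-path fingerprint: DFS paths whose length equals t_ij."""
    labels = _labels(mol, cfg)
    tmat = topo_matrix(mol)
    features: Counter = Counter()
    for root in range(mol.n_atoms):
        for path in dfs_paths(mol, root, cfg.d, labels):
            if len(path) == tmat[path.root, path.last]:
                features[canonical_string(path)] += 1
    return features


# ---------------------------------------------------------------------------
# pair / triplet encodings

def encode_atom_pairs(
    mol: Molecule, cfg: EncodingConfig, metric: Metric = Metric.TOPO
) -> Counter:
    """Atom pairs label-distance-label for all pairs with distance in [1, d]."""
    labels = _labels(mol, cfg)
    dmat = _distance_matrix(mol, cfg, metric)
    features: Counter = Counter()
    for i, j, dist in _pair_iter(dmat, cfg.d):
        features[_canonical_pair(labels[i], dist, labels[j])] += 1
    return features


def encode_atom_triplets(
    mol: Molecule, cfg: EncodingConfig, metric: Metric = Metric.TOPO
) -> Counter:
    """Atom triplets with all three pairwise distances in [1, d]."""
    labels = _labels(mol, cfg)
    dmat = _distance_matrix(mol, cfg, metric)
    n = mol.n_atoms
    features: Counter = Counter()
    for i, j, k in itertools.combinations(range(n), 3):
        dists = {}
        ok = True
        for a, b in ((i, j), (j, k), (i, k)):
            dist = dmat[a, b]
            if not 1 <= dist <= cfg.d:
                ok = False
                break
            dists[a, b] = int(dist)
        if ok:
            features[_canonical_triplet(labels, dists, (i, j, k))] += 1
    return features


# ---------------------------------------------------------------------------
# pharmacophore encodings

def _ppp_pair_observations(mol: Molecule, cfg: EncodingConfig, metric: Metric):
    """Yield (block, distance) for every PPP pair within the cut-off."""
    ppps = assign_ppps(mol)
    dmat = _distance_matrix(mol, cfg, metric)
    for i, j, dist in _pair_iter(dmat, cfg.d):
        for a in ppps[i]:
            for b in ppps[j]:
                yield _pair_block(a, b), dist


def encode_cats(
    mol: Molecule, cfg: EncodingConfig, metric: Metric = Metric.TOPO
) -> FixedVector:
    """Pharmacophore pair autocorrelation vector of ``(d+1) * 15`` counts.

    The distance-0 cell of a block counts single atoms bearing both PPPs of
    the pair; cells 1..d count unordered atom pairs at that distance, with
    every PPP of each atom participating.
    """
    d = cfg.d
    vec = np.zeros((d + 1) * 15, dtype=int)
    ppps = assign_ppps(mol)
    for pset in ppps:
        for a, b in itertools.combinations_with_replacement(sorted(pset), 2):
            vec[cats_flat_index(_pair_block(a, b), 0, d)] += 1
    for block, dist in _ppp_pair_observations(mol, cfg, metric):
        vec[cats_flat_index(block, dist, d)] += 1
    return FixedVector(vec, bins_per_block=d + 1)


def encode_pharm_pairs(
    mol: Molecule, cfg: EncodingConfig, metric: Metric = Metric.TOPO
) -> Counter:
    """Pharmacophore pairs: every PPP of atom i against every PPP of atom j."""
    features: Counter = Counter()
    ppps = assign_ppps(mol)
    dmat = _distance_matrix(mol, cfg, metric)
    for i, j, dist in _pair_iter(dmat, cfg.d):
        for a in ppps[i]:
            for b in ppps[j]:
                features[_canonical_pair(a.value, dist, b.value)] += 1
    return features


def encode_pharm_triplets(
    mol: Molecule, cfg: EncodingConfig, metric: Metric = Metric.TOPO
) -> Counter:
    """Pharmacophore triplets over all PPP combinations of three atoms."""
    features: Counter = Counter()
    ppps = assign_ppps(mol)
    dmat = _distance_matrix(mol, cfg, metric)
    n = mol.n_atoms
    for i, j, k in itertools.combinations(range(n), 3):
        dists = {}
        ok = True
        for a, b in ((i, j), (j, k), (i, k)):
            dist = dmat[a, b]
            if not 1 <= dist <= cfg.d:
                ok = False
                break
            dists[a, b] = int(dist)
        if not ok:
            continue
        for pa in ppps[i]:
            for pb in ppps[j]:
                for pc in ppps[k]:
                    lbls = {i: pa.value, j: pb.value, k: pc.value}
                    features[
                        _canonical_triplet_ppp(lbls, dists, (i, j, k))
                    ] += 1
    return features


def _canonical_triplet_ppp(lbls, dists, triple) -> str:
    best = None
    for a, b, c in itertools.permutations(triple):
        s = (
            f"{lbls[a]}-{dists[min(a, b), max(a, b)]}-"
            f"{lbls[b]}-{dists[min(b, c), max(b, c)]}-"
            f"{lbls[c]}-{dists[min(c, a), max(c, a)]}"
        )
        if best is None or s > best:
            best = s
    return best


def encode_shed(mol: Molecule, cfg: EncodingConfig) -> FixedVector:
    """SHED key: per PPP pair type, the perplexity of its distance spectrum.

    For each of the 15 pair types the counts of atom pairs at topological
    distances 1..d form a probability distribution; the entry stored is
    ``exp(H)`` of its Shannon entropy ``H`` in nats (so a pair type observed
    at a single distance scores 1.0 and one spread evenly over k distances
    scores k).  A pair type never observed scores 0.
    """
    counts: Dict[str, Counter] = {name: Counter() for name in PAIR_BLOCKS}
    for block, dist in _ppp_pair_observations(mol, cfg, Metric.TOPO):
        counts[block][dist] += 1
    values = np.zeros(15)
    for idx, name in enumerate(PAIR_BLOCKS):
        total = sum(counts[name].values())
        if total == 0:
            continue
        entropy = 0.0
        for c in counts[name].values():
            p = c / total
            entropy -= p * math.log(p)
        values[idx] = math.exp(entropy)
    return FixedVector(values, bins_per_block=1)


# ---------------------------------------------------------------------------
# circular substructures (ECFP)

def _wl_ranks(
    sub: frozenset[int],
    labels: Sequence[str],
    ext: Dict[int, int],
    adj_syms: Dict[tuple[int, int], str],
    neighbors: Dict[int, list[int]],
) -> Dict[int, int]:
    """Permutation-invariant atom ranks inside a substructure.

    Iterative label refinement on (label, open-attachment count) seeds; used
    only to fix the traversal order of the canonical renderer, so atoms that
    remain tied are structurally interchangeable.
    """
    key = {a: (labels[a], ext[a]) for a in sub}
    for _ in range(len(sub)):
        ranks = {k: r for r, k in enumerate(sorted(set(key.values())))}
        new_key = {}
        for a in sub:
            nbr_sig = tuple(
                sorted((adj_syms[a, b], ranks[key[b]]) for b in neighbors[a])
            )
            new_key[a] = (ranks[key[a]], nbr_sig)
        if len(set(new_key.values())) == len(set(key.values())):
            key = new_key
            break
        key = new_key
    final = {k: r for r, k in enumerate(sorted(set(key.values())))}
    return {a: final[key[a]] for a in sub}


def _render_substructure(
    mol: Molecule,
    labels: Sequence[str],
    center: int,
    sub: frozenset[int],
) -> str:
    """Canonical linear notation of the induced substructure around center.

    Unfilled attachment points (bonds leaving the substructure) are rendered
    as ``([*])``; ring-closure bonds as paired ``%k`` markers.  Branch order
    is fixed by bond symbol and refinement rank, which depend only on the
    substructure, never on atom input order.
    """
    neighbors: Dict[int, list[int]] = {a: [] for a in sub}
    adj_syms: Dict[tuple[int, int], str] = {}
    ext = {a: 0 for a in sub}
    for a in sub:
        for b, bond in mol.neighbors(a):
            if b in sub:
                neighbors[a].append(b)
                adj_syms[a, b] = bond_symbol(bond)
            else:
                ext[a] += 1
    ranks = _wl_ranks(sub, labels, ext, adj_syms, neighbors)

    def ordered(a: int, parent: Optional[int]) -> list[int]:
        nbrs = [b for b in neighbors[a] if b != parent]
        return sorted(nbrs, key=lambda b: (adj_syms[a, b], ranks[b], labels[b]))

    # pass 1: spanning tree + back edges in discovery order
    visited = {center}
    children: Dict[int, list[int]] = {a: [] for a in sub}
    closures_at: Dict[int, list[tuple[int, str]]] = {a: [] for a in sub}
    seen_back: set[frozenset[int]] = set()
    counter = itertools.count(1)

    def walk(a: int, parent: Optional[int]) -> None:
        for b in ordered(a, parent):
            edge = frozenset((a, b))
            if b in visited:
                if edge not in seen_back:
                    seen_back.add(edge)
                    cid = next(counter)
                    closures_at[a].append((cid, adj_syms[a, b]))
                    closures_at[b].append((cid, adj_syms[a, b]))
            else:
                visited.add(b)
                children[a].append(b)
                walk(b, a)

    walk(center, None)

    def render(a: int) -> str:
        s = labels[a]
        for cid, sym in sorted(closures_at[a]):
            s += f"{sym}%{cid}"
        s += "([*])" * ext[a]
        for child in children[a]:
            s += "(" + adj_syms[a, child] + render(child) + ")"
        return s

    return render(center)


def encode_ecfp(mol: Molecule, cfg: EncodingConfig) -> Counter:
    """Circular substructure fingerprint (explicit-graph ECFP variant).

    Iteration 0 emits each atom's initial identifier (its label); iteration k
    emits the canonical rendering of the full substructure induced by all
    atoms within k bonds of the center, with connectivity between layers kept
    and open attachment points marked.  Growth stops for a center once its
    sphere saturates.
    """
    labels = _labels(mol, cfg)
    tmat = topo_matrix(mol)
    features: Counter = Counter()
    n = mol.n_atoms
    for center in range(n):
        features[labels[center]] += 1
        prev: Optional[frozenset[int]] = None
        for radius in range(1, cfg.d + 1):
            sub = frozenset(
                j for j in range(n) if tmat[center, j] <= radius
            )
            if sub == prev or len(sub) == 1:
                break
            prev = sub
            features[_render_substructure(mol, labels, center, sub)] += 1
    return features


# ---------------------------------------------------------------------------
# radial shell encodings

def encode_radial_shells(
    mol: Molecule, cfg: EncodingConfig, metric: Metric = Metric.TOPO
) -> Counter:
    """Molprint-like cumulative shells of sorted neighbor labels.

    For every atom and every l in 1..d one feature
    ``0[center]1[...]...l[...]`` is emitted; empty shells are retained as
    ``k[]`` so cumulative features stay aligned across molecules.
    """
    labels = _labels(mol, cfg)
    dmat = _distance_matrix(mol, cfg, metric)
    n = mol.n_atoms
    features: Counter = Counter()
    for i in range(n):
        shells = {
            k: sorted(labels[j] for j in range(n) if dmat[i, j] == k)
            for k in range(1, cfg.d + 1)
        }
        prefix = f"0[{labels[i]}]"
        for l in range(1, cfg.d + 1):
            prefix += f"{l}[{' '.join(shells[l])}]"
            features[prefix] += 1
    return features


def encode_lstar(mol: Molecule, cfg: EncodingConfig) -> Counter:
    """Local path environments: per root and length l, the sorted shell of
    root-anchored path strings of exactly l bonds, as one bracketed feature.
    """
    labels = _labels(mol, cfg)
    features: Counter = Counter()
    for root in range(mol.n_atoms):
        by_len: Dict[int, list[str]] = {}
        for path in dfs_paths(mol, root, cfg.d, labels):
            by_len.setdefault(len(path), []).append(
                render_path(path.labels, path.bond_symbols)
            )
        for l in range(1, cfg.d + 1):
            if l not in by_len:
                continue
            shell = ", ".join(sorted(by_len[l]))
            features[f"[{shell}]"] += 1
    return features


# ---------------------------------------------------------------------------
# registry

EN = LabelScheme.ELEMENT_NEIGHBOR
DIR = LabelScheme.DAYLIGHT_INVARIANT

#: Default parameterization of every encoding (depth d, labeling scheme).
DEFAULT_CONFIGS: Dict[str, EncodingConfig] = {
    "DFS": EncodingConfig("DFS", d=8, scheme=EN),
    "ASP": EncodingConfig("ASP", d=8, scheme=EN),
    "AP2D": EncodingConfig("AP2D", d=8, scheme=EN),
    "AT2D": EncodingConfig("AT2D", d=5, scheme=EN),
    "CATS2D": EncodingConfig("CATS2D", d=9),
    "PHAP2PT2D": EncodingConfig("PHAP2PT2D", d=8),
    "PHAP3PT2D": EncodingConfig("PHAP3PT2D", d=5),
    "SHED": EncodingConfig("SHED", d=8),
    "ECFP": EncodingConfig("ECFP", d=4, scheme=DIR),
    "RAD2D": EncodingConfig("RAD2D", d=3, scheme=EN),
    "LSTAR": EncodingConfig("LSTAR", d=6, scheme=EN),
    "AP3D": EncodingConfig("AP3D", d=10, scheme=EN),
    "AT3D": EncodingConfig("AT3D", d=6, scheme=EN),
    "CATS3D": EncodingConfig("CATS3D", d=9),
    "PHAP2PT3D": EncodingConfig("PHAP2PT3D", d=10),
    "PHAP3PT3D": EncodingConfig("PHAP3PT3D", d=6),
    "RAD3D": EncodingConfig("RAD3D", d=4, scheme=EN),
}

ENCODINGS: Dict[str, Callable] = {
    "DFS": encode_dfs,
    "ASP": encode_asp,
    "AP2D": lambda m, c: encode_atom_pairs(m, c, Metric.TOPO),
    "AT2D": lambda m, c: encode_atom_triplets(m, c, Metric.TOPO),
    "CATS2D": lambda m, c: encode_cats(m, c, Metric.TOPO),
    "PHAP2PT2D": lambda m, c: encode_pharm_pairs(m, c, Metric.TOPO),
    "PHAP3PT2D": lambda m, c: encode_pharm_triplets(m, c, Metric.TOPO),
    "SHED": encode_shed,
    "ECFP": encode_ecfp,
    "RAD2D": lambda m, c: encode_radial_shells(m, c, Metric.TOPO),
    "LSTAR": encode_lstar,
    "AP3D": lambda m, c: encode_atom_pairs(m, c, Metric.GEOM),
    "AT3D": lambda m, c: encode_atom_triplets(m, c, Metric.GEOM),
    "CATS3D": lambda m, c: encode_cats(m, c, Metric.GEOM),
    "PHAP2PT3D": lambda m, c: encode_pharm_pairs(m, c, Metric.GEOM),
    "PHAP3PT3D": lambda m, c: encode_pharm_triplets(m, c, Metric.GEOM),
    "RAD3D": lambda m, c: encode_radial_shells(m, c, Metric.GEOM),
}

FIXED_VECTOR_ENCODINGS = frozenset({"CATS2D", "CATS3D", "SHED"})


def get_config(
    name: str,
    d: Optional[int] = None,
    s: Optional[float] = None,
    scheme: Optional[LabelScheme] = None,
) -> EncodingConfig:
    """Default configuration of an encoding, with optional overrides."""
    key = name.upper()
    if key not in DEFAULT_CONFIGS:
        raise KeyError(
            f"unknown encoding {name!r}; choose from {', '.join(DEFAULT_CONFIGS)}"
        )
    cfg = DEFAULT_CONFIGS[key]
    kwargs = {}
    if d is not None:
        kwargs["d"] = d
    if s is not None:
        kwargs["s"] = s
    if scheme is not None and cfg.scheme is not None:
        kwargs["scheme"] = scheme
    return replace(cfg, **kwargs) if kwargs else cfg


def encode(
    mol: Molecule,
    name: str,
    d: Optional[int] = None,
    s: Optional[float] = None,
    scheme: Optional[LabelScheme] = None,
) -> Union[Counter, FixedVector]:
    """Run a named encoding with its defaults (optionally overridden)."""
    cfg = get_config(name, d=d, s=s, scheme=scheme)
    return ENCODINGS[cfg.name](mol, cfg)
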