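"""Feature identity, feature maps, hashed fingerprints and similarity.

A feature is a pattern string plus a 32-bit id that is a pure function of the
string (a portable polynomial rolling hash, multiplier 31).  Two features are
equal iff their ids are equal; molecular similarity is computed on multisets
of feature ids with counts (feature maps), either exactly (MinMax, Tanimoto)
or after folding into a fixed-size binary vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .encoders import FixedVector

__all__ = [
    "feature_id",
    "Feature",
    "FeatureMap",
    "build_feature_map",
    "HashedFingerprint",
    "fold",
    "similarity",
    "similarity_matrix",
]

_MASK32 = 0xFFFFFFFF
_SCRAMBLE = 2654435761  # Knuth multiplicative constant


def feature_id(nom: str) -> int:
    """32-bit id of a pattern string: rolling hash, multiplier 31.

    ``id = sum(31^(k-1-i) * codepoint_i) mod 2^32`` — deterministic across
    platforms and runs.
    """
    if not nom:
        raise ValueError("feature string must be non-empty")
    h = 0
    for ch in nom:
        h = (31 * h + ord(ch)) & _MASK32
    return h


@dataclass(frozen=True)
class Feature:
    """Pattern string, its 32-bit id, and an occurrence count."""

    nom: str
    id: int
    count: int = 1


class FeatureMap:
    """Multiset of features for one molecule, keyed by feature id.

    Counts are positive; for fixed-vector encodings they may be real-valued.
    An optional learning label travels with the map into the exporters.
    """

    __slots__ = ("entries", "label")

    def __init__(
        self,
        entries: Optional[Dict[int, Tuple[str, float]]] = None,
        label: Union[float, str, None] = None,
    ) -> None:
        self.entries: Dict[int, Tuple[str, float]] = entries or {}
        self.label = label

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, nom: str) -> bool:
        return feature_id(nom) in self.entries

    def count(self, nom: str) -> float:
        entry = self.entries.get(feature_id(nom))
        return entry[1] if entry else 0

    def ids(self) -> frozenset:
        return frozenset(self.entries)

    def counts_by_id(self) -> Dict[int, float]:
        return {fid: c for fid, (_, c) in self.entries.items()}

    def features(self) -> List[Feature]:
        return [
            Feature(nom, fid, count)
            for fid, (nom, count) in sorted(self.entries.items())
        ]

    def total(self) -> float:
        return sum(c for _, c in self.entries.values())


def build_feature_map(
    features: Union[Mapping[str, float], Iterable[str], FixedVector],
    label: Union[float, str, None] = None,
) -> FeatureMap:
    """Aggregate encoder output into a FeatureMap.

    Accepts a Counter/mapping of pattern -> count, a plain iterable of
    pattern strings, or a FixedVector (whose non-zero cells become features
    named by their flat index).
    """
    entries: Dict[int, Tuple[str, float]] = {}

    def _add(nom: str, count: float) -> None:
        fid = feature_id(nom)
        if fid in entries:
            entries[fid] = (entries[fid][0], entries[fid][1] + count)
        else:
            entries[fid] = (nom, count)

    if isinstance(features, FixedVector):
        for idx, value in enumerate(features.values):
            if value != 0:
                _add(str(idx), float(value))
    elif isinstance(features, Mapping):
        for nom, count in features.items():
            _add(nom, count)
    else:
        for nom in features:
            _add(nom, 1)
    return FeatureMap(entries, label=label)


@dataclass(frozen=True)
class HashedFingerprint:
    """Binary fingerprint: hash-space size h and the sorted set-bit positions."""

    h: int
    bits: Tuple[int, ...]

    def __len__(self) -> int:
        return self.h

    @property
    def n_set(self) -> int:
        return len(self.bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.h, dtype=np.uint8)
        arr[list(self.bits)] = 1
        return arr


def fold(fmap: FeatureMap, h: int = 2 ** 14) -> HashedFingerprint:
    """Project a feature map onto a binary vector of power-of-two size h.

    The bit of a feature is ``((id * 2654435761) mod 2^32) mod h`` — a fixed
    multiplicative scrambling of the id, so identical features set identical
    bits across molecules, runs and platforms.
    """
    if h < 1 or h & (h - 1):
        raise ValueError(f"hash-space size must be a power of two, got {h}")
    bits = sorted({((fid * _SCRAMBLE) & _MASK32) % h for fid in fmap.entries})
    return HashedFingerprint(h=h, bits=tuple(bits))


def similarity(a: FeatureMap, b: FeatureMap, metric: str = "minmax") -> float:
    """MinMax or Tanimoto similarity of two feature maps, in [0, 1].

    MinMax compares counts (sum of elementwise minima over sum of maxima);
    Tanimoto compares the distinct-id sets.  Two empty maps score 0 by
    convention.
    """
    metric = metric.lower()
    if metric == "minmax":
        ca, cb = a.counts_by_id(), b.counts_by_id()
        num = den = 0.0
        for fid in set(ca) | set(cb):
            x, y = ca.get(fid, 0), cb.get(fid, 0)
            num += min(x, y)
            den += max(x, y)
        return num / den if den else 0.0
    if metric == "tanimoto":
        ia, ib = a.ids(), b.ids()
        union = len(ia | ib)
        return len(ia & ib) / union if union else 0.0
    raise ValueError(f"unknown similarity metric {metric!r}")


def similarity_matrix(maps: Sequence[FeatureMap], metric: str = "minmax") -> np.ndarray:
    """Symmetric pairwise similarity matrix over a list of feature maps."""
    if not maps:
        raise ValueError("need at least one feature map")
    n = len(maps)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mat[i, j] = mat[j, i] = similarity(maps[i], maps[j], metric)
    return mat
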