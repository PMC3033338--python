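"""Write fingerprints and similarity matrices for machine-learning toolboxes.

Supported formats: sparse SVM-light/LIBSVM lines of folded fingerprints, the
LIBSVM precomputed-kernel matrix dialect, sparse WEKA ARFF, and two CSV
layouts (string features with counts, and dense hashed bits).  Sequential
exporters consume their input lazily so only one feature map needs to be in
memory at a time.
"""

from __future__ import annotations

import logging
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .feature_store import FeatureMap, fold, similarity_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExportFormat",
    "format_label",
    "write_svm_sparse",
    "write_svm_sparse_vectors",
    "write_kernel_matrix",
    "write_arff",
    "write_csv_string",
    "write_csv_hashed",
    "read_svm_sparse",
]


class ExportFormat(IntEnum):
    """Output format codes (``-ff`` on the command line; 0 is the default)."""

    SVM_SPARSE_HASHED = 0
    SVM_PRECOMPUTED_MATRIX = 1
    ARFF_HASHED = 2
    CSV_STRING_FEATURES = 3
    CSV_HASHED = 4


FORMAT_SUFFIX = {
    ExportFormat.SVM_SPARSE_HASHED: "LIBSVM_SPARSE",
    ExportFormat.SVM_PRECOMPUTED_MATRIX: "LIBSVM_MATRIX",
    ExportFormat.ARFF_HASHED: "ARFF",
    ExportFormat.CSV_STRING_FEATURES: "CSV",
    ExportFormat.CSV_HASHED: "CSV_HASHED",
}


def format_label(label: Union[float, str, None]) -> str:
    """Render a learning label; missing labels become 0 with a warning."""
    if label is None:
        logger.warning("missing label; writing 0")
        return "0"
    if isinstance(label, float) and label.is_integer():
        return str(int(label))
    return str(label)


def write_svm_sparse(
    maps: Iterable[FeatureMap], h: int, path: Union[str, Path]
) -> int:
    """Sparse SVM-light lines: label then ascending 1-based ``index:1`` pairs.

    Streams over ``maps`` (works with a generator); returns the number of
    lines written.
    """
    n = 0
    with open(path, "w") as fh:
        for fmap in maps:
            fp = fold(fmap, h)
            cells = " ".join(f"{b + 1}:1" for b in fp.bits)
            line = format_label(fmap.label)
            if cells:
                line += " " + cells
            fh.write(line + "\n")
            n += 1
    return n


def write_svm_sparse_vectors(
    vectors: Iterable[Sequence[float]],
    labels: Iterable[Union[float, str, None]],
    path: Union[str, Path],
) -> int:
    """Sparse SVM lines for fixed-position vectors (CATS/SHED): non-zero
    cells are written as 1-based ``index:value``."""
    n = 0
    with open(path, "w") as fh:
        for vec, label in zip(vectors, labels):
            arr = np.asarray(vec, dtype=float)
            cells = " ".join(
                f"{i + 1}:{_num(v)}" for i, v in enumerate(arr) if v != 0
            )
            line = format_label(label)
            if cells:
                line += " " + cells
            fh.write(line + "\n")
            n += 1
    return n


def _num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_kernel_matrix(
    maps: Sequence[FeatureMap], metric: str, path: Union[str, Path]
) -> np.ndarray:
    """LIBSVM precomputed-kernel dialect: label, ``0:i`` row id, ``j:K_ij``.

    All maps are held in memory (matrix mode).  Returns the matrix.
    """
    mat = similarity_matrix(maps, metric)
    with open(path, "w") as fh:
        for i, fmap in enumerate(maps):
            cells = " ".join(f"{j + 1}:{mat[i, j]:.6f}" for j in range(len(maps)))
            fh.write(f"{format_label(fmap.label)} 0:{i + 1} {cells}\n")
    return mat


def write_arff(
    maps: Sequence[FeatureMap],
    h: int,
    path: Union[str, Path],
    relation: str = "graphfp",
    class_threshold: int = 5,
) -> None:
    """Sparse WEKA ARFF with h binary attributes plus a class attribute.

    The class is nominal when the number of distinct labels is at most
    ``class_threshold`` (default five), numeric otherwise.
    """
    labels = [format_label(m.label) for m in maps]
    distinct = sorted(set(labels))
    nominal = len(distinct) <= class_threshold
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for i in range(h):
            fh.write(f"@attribute bit{i} {{0,1}}\n")
        if nominal:
            fh.write(f"@attribute class {{{','.join(distinct)}}}\n")
        else:
            fh.write("@attribute class numeric\n")
        fh.write("\n@data\n")
        for fmap, label in zip(maps, labels):
            fp = fold(fmap, h)
            cells = [f"{b} 1" for b in fp.bits]
            cells.append(f"{h} {label}")
            fh.write("{" + ", ".join(cells) + "}\n")


def write_csv_string(maps: Iterable[FeatureMap], path: Union[str, Path]) -> int:
    """CSV rows: label column, then quoted ``nom:count`` cells."""
    n = 0
    with open(path, "w") as fh:
        for fmap in maps:
            cells = [format_label(fmap.label)]
            for feat in fmap.features():
                cells.append(f'"{feat.nom}:{_num(feat.count)}"')
            fh.write(",".join(cells) + "\n")
            n += 1
    return n


def write_csv_hashed(
    maps: Iterable[FeatureMap], h: int, path: Union[str, Path]
) -> int:
    """CSV rows: label column, then h dense 0/1 columns of the folded bits."""
    n = 0
    with open(path, "w") as fh:
        fh.write("label," + ",".join(f"bit{i}" for i in range(h)) + "\n")
        for fmap in maps:
            arr = fold(fmap, h).to_array()
            fh.write(format_label(fmap.label) + "," +
                     ",".join(str(int(v)) for v in arr) + "\n")
            n += 1
    return n


def read_svm_sparse(path: Union[str, Path]) -> list[tuple[str, dict[int, float]]]:
    """Parse a sparse SVM file back into (label, {0-based index: value}).

    Round-trip check utility: recovers exactly the folded bit sets written by
    :func:`write_svm_sparse`.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        label = parts[0]
        cells = {}
        for cell in parts[1:]:
            idx, val = cell.split(":")
            cells[int(idx) - 1] = float(val)
        rows.append((label, cells))
    return rows
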