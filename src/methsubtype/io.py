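"""Delimited-text I/O for beta matrices and subtype label tables.

Matrices are one header row of sample ids plus one probe-id column
(canonical probes-as-rows orientation; ``orientation="samples_as_rows"``
reads the transpose).  The delimiter is inferred from the extension:
``.csv`` is comma, anything else tab.  Empty cells and the tokens ``NA`` /
``NaN`` (case-insensitive) parse as missing.  Id matching everywhere is
exact string match — fuzzy matching would hide data errors silently.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, SubtypeVocabulary

_MISSING_TOKENS = {"", "na", "nan"}


def _delimiter_for(path: str) -> str:
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def _find_duplicate(ids) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def read_beta_matrix(path, orientation: str = "probes_as_rows") -> BetaMatrix:
    """Read a delimited beta-value matrix into the canonical layout.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with one header row and one id column.
    orientation : {"probes_as_rows", "samples_as_rows"}
        Layout of the file on disk.  The returned matrix is always
        probes x samples.
    """
    if orientation not in ("probes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    sep = _delimiter_for(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty matrix file: {path}")
    col_ids = [c.strip() for c in header.rstrip("\n").split(sep)][1:]
    dup = _find_duplicate(col_ids)
    if dup is not None:
        axis = "sample" if orientation == "probes_as_rows" else "probe"
        raise ValueError(f"duplicate {axis} id in {path}: {dup!r}")

    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"matrix file has no data cells: {path}")
    row_ids = [str(i).strip() for i in frame.index]
    dup = _find_duplicate(row_ids)
    if dup is not None:
        axis = "probe" if orientation == "probes_as_rows" else "sample"
        raise ValueError(f"duplicate {axis} id in {path}: {dup!r}")

    raw = frame.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in _MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"unparseable cell at row {row_ids[i]!r}, "
                        f"column {col_ids[j]!r}: {cell!r}"
                    ) from None

    if orientation == "samples_as_rows":
        return BetaMatrix(col_ids, row_ids, values.T)
    return BetaMatrix(row_ids, col_ids, values)


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Write a matrix in canonical orientation; missing entries become ``NA``."""
    sep = _delimiter_for(path)
    frame = pd.DataFrame(matrix.values, index=matrix.cpg_ids, columns=matrix.sample_ids)
    frame.index.name = "cpg_id"
    frame.to_csv(path, sep=sep, na_rep="NA")


def read_labels(path, vocabulary: SubtypeVocabulary | None = None):
    """Read a two-column sample/subtype table.

    Returns a ``(sample_id -> class index, SubtypeVocabulary)`` pair.  With
    ``vocabulary=None`` the vocabulary is built from the distinct subtype
    names in first-appearance order; otherwise every name must already be
    in the given vocabulary.  A header row is expected (and skipped).
    """
    sep = _delimiter_for(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError(f"label file needs two columns (sample_id, subtype): {path}")
    pairs = [(str(s).strip(), str(t).strip()) for s, t in zip(frame.iloc[:, 0], frame.iloc[:, 1])]

    assignment: dict[str, str] = {}
    order: list[str] = []
    for sample, subtype in pairs:
        if sample in assignment and assignment[sample] != subtype:
            raise ValueError(
                f"sample {sample!r} listed with conflicting subtypes: "
                f"{assignment[sample]!r} and {subtype!r}"
            )
        assignment[sample] = subtype
        if subtype not in order:
            order.append(subtype)

    if vocabulary is None:
        if len(order) < 2:
            raise ValueError(
                f"label file {path} defines {len(order)} subtype(s); "
                "at least 2 are required to train"
            )
        vocabulary = SubtypeVocabulary(tuple(order))
    else:
        known = set(vocabulary.names)
        unknown = sorted({t for t in order if t not in known})
        if unknown:
            raise ValueError(f"subtype name(s) not in vocabulary: {unknown}")
    labels = {s: vocabulary.index_of(t) for s, t in assignment.items()}
    return labels, vocabulary


def write_labels(labels: dict, vocabulary: SubtypeVocabulary, path) -> None:
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(f"sample_id{sep}subtype\n")
        for sample, idx in labels.items():
            fh.write(f"{sample}{sep}{vocabulary.names[int(idx)]}\n")


def align_to_features(matrix: BetaMatrix, cpg_ids) -> BetaMatrix:
    """Restrict and reorder ``matrix`` to exactly ``cpg_ids``.

    The prediction-time guard: a saved model's ordered feature list must be
    matched exactly by any new matrix before the model may score it.
    """
    return matrix.select_probes(list(cpg_ids))
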