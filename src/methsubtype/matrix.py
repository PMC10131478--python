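"""Core containers: beta-value matrices and labeled/unlabeled datasets.

The canonical in-memory layout is probes x samples — the orientation in
which public array matrices (GEO series-matrix exports) ship.  Downstream
math transposes internally to the samples x features layout that learning
code expects.  Missing entries are represented as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_unique(ids: list[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {axis} id: {i!r}")
        seen.add(i)


class BetaMatrix:
    """A probes x samples matrix of methylation beta values in [0, 1].

    Parameters
    ----------
    cpg_ids : sequence of str
        Ordered, unique probe identifiers (one per row).
    sample_ids : sequence of str
        Ordered, unique sample identifiers (one per column).
    values : ndarray of shape (n_probes, n_samples)
        Beta values; NaN marks a missing measurement.  Non-missing entries
        must lie in [0, 1].
    """

    def __init__(self, cpg_ids, sample_ids, values):
        cpg_ids = [str(c) for c in cpg_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={values.ndim}")
        if values.shape != (len(cpg_ids), len(sample_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(cpg_ids)} probes x {len(sample_ids)} samples"
            )
        _check_unique(cpg_ids, "probe")
        _check_unique(sample_ids, "sample")
        observed = values[~np.isnan(values)]
        if observed.size and (observed.min() < 0.0 or observed.max() > 1.0):
            bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 1)))
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0, 1]: probe {cpg_ids[i]!r}, "
                f"sample {sample_ids[j]!r}, value {values[i, j]}"
            )
        self.cpg_ids = cpg_ids
        self.sample_ids = sample_ids
        self.values = values

    @property
    def n_probes(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def samples_by_features(self) -> np.ndarray:
        """Return the samples x probes view used by the learning code."""
        return self.values.T.copy()

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(list(self.cpg_ids), list(self.sample_ids), self.values.copy())

    def select_probes(self, cpg_ids) -> "BetaMatrix":
        """Restrict and reorder to the given probe ids (all must exist)."""
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpg_ids if c not in index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing}")
        rows = [index[c] for c in cpg_ids]
        return BetaMatrix(list(cpg_ids), list(self.sample_ids), self.values[rows, :])

    def equals(self, other: "BetaMatrix") -> bool:
        return (
            self.cpg_ids == other.cpg_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples, "
            f"{self.n_missing} missing)"
        )


@dataclass(frozen=True)
class SubtypeVocabulary:
    """Ordered list of distinct subtype names; order fixes the output-unit index."""

    names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        _check_unique(list(self.names), "subtype")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown subtype name: {name!r}") from None

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class LabeledDataset:
    """A beta matrix plus one subtype-index label per sample."""

    matrix: BetaMatrix
    labels: np.ndarray
    vocabulary: SubtypeVocabulary

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.matrix.n_samples,):
            raise ValueError(
                f"need one label per sample: {self.labels.shape[0]} labels "
                f"for {self.matrix.n_samples} samples"
            )
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.vocabulary)):
            raise ValueError("label index out of range for the vocabulary")

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples


@dataclass
class UnlabeledDataset:
    """A beta matrix for a cohort without subtype annotations."""

    matrix: BetaMatrix

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples
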