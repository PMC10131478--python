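"""Methylation preprocessing: probe intersection, missingness filter, imputation.

The pipeline mirrors how multi-cohort array studies are harmonized: 27K
probe sets are (nearly) subsets of 450K, so cohorts are first restricted to
their common probes; CpGs with more than ``max_missing_frac`` missing values
(strictly more — an exactly-at-threshold probe survives) are removed; the
remaining missing entries are imputed.  Median imputation is the default.
The imputer is fitted on the pooled labeled cohorts only and then applied
everywhere, so no fill statistic leaks information from unlabeled or test
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.impute import KNNImputer

from .matrix import BetaMatrix

VALID_STRATEGIES = ("median", "mean", "knn")


@dataclass
class ImputationModel:
    """Fitted per-probe fill statistics (median/mean) or KNN donor data.

    For ``knn`` the model stores the training cohort (samples x probes, NaN
    for missing); a missing entry in new data is filled with the unweighted
    mean of the entry's probe over the ``k_neighbors`` most similar training
    samples, similarity being nan-aware Euclidean distance over mutually
    observed probes.
    """

    strategy: str
    cpg_ids: list
    fill_values: np.ndarray | None = None  # (n_probes,) for median/mean
    train_data: np.ndarray | None = None  # (n_samples, n_probes) for knn
    k_neighbors: int = 5

    def save(self, path) -> None:
        meta = {"strategy": self.strategy, "cpg_ids": list(self.cpg_ids), "k_neighbors": self.k_neighbors}
        arrays = {"meta": np.array(json.dumps(meta))}
        if self.fill_values is not None:
            arrays["fill_values"] = self.fill_values
        if self.train_data is not None:
            arrays["train_data"] = self.train_data
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ImputationModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            fill = data["fill_values"] if "fill_values" in data else None
            train = data["train_data"] if "train_data" in data else None
        return cls(
            strategy=meta["strategy"],
            cpg_ids=meta["cpg_ids"],
            fill_values=fill,
            train_data=train,
            k_neighbors=int(meta["k_neighbors"]),
        )


@dataclass
class PreprocessReport:
    """Feature accounting across the pipeline stages."""

    n_common_features: int
    n_removed_by_missing_filter: int
    n_final_features: int
    strategy: str

    def __post_init__(self):
        assert self.n_final_features == self.n_common_features - self.n_removed_by_missing_filter

    def to_dict(self) -> dict:
        return {
            "n_common_features": self.n_common_features,
            "n_removed_by_missing_filter": self.n_removed_by_missing_filter,
            "n_final_features": self.n_final_features,
            "strategy": self.strategy,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key}\t{value}\n")


def intersect_features(matrices: list[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict every matrix to the probes present in all of them.

    Probe order follows the first matrix; sample axes are untouched.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].cpg_ids)
    for m in matrices[1:]:
        common &= set(m.cpg_ids)
    if not common:
        raise ValueError("no probes are shared by all cohorts")
    ordered = [c for c in matrices[0].cpg_ids if c in common]
    return [m.select_probes(ordered) for m in matrices]


def filter_missing_cpgs(matrix: BetaMatrix, max_missing_frac: float = 0.2):
    """Drop probes whose missing fraction strictly exceeds ``max_missing_frac``.

    Returns ``(filtered matrix, list of removed probe ids)``.  Survivor
    order is preserved.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError(f"max_missing_frac must be in [0, 1), got {max_missing_frac}")
    frac = np.isnan(matrix.values).mean(axis=1)
    keep_mask = frac <= max_missing_frac
    removed = [c for c, k in zip(matrix.cpg_ids, keep_mask) if not k]
    if not keep_mask.any():
        raise ValueError("missingness filter removed every probe")
    kept = [c for c, k in zip(matrix.cpg_ids, keep_mask) if k]
    return matrix.select_probes(kept), removed


def fit_imputer(
    matrix: BetaMatrix, strategy: str = "median", k_neighbors: int = 5
) -> ImputationModel:
    """Fit an imputation model on a (pooled) training matrix."""
    if strategy not in VALID_STRATEGIES:
        raise ValueError(f"strategy must be one of {VALID_STRATEGIES}, got {strategy!r}")
    observed_counts = (~np.isnan(matrix.values)).sum(axis=1)
    if (observed_counts == 0).any():
        bad = [c for c, n in zip(matrix.cpg_ids, observed_counts) if n == 0]
        raise ValueError(f"probe(s) with zero observed values cannot be imputed: {bad}")
    if strategy == "knn":
        return ImputationModel(
            strategy="knn",
            cpg_ids=list(matrix.cpg_ids),
            train_data=matrix.samples_by_features(),
            k_neighbors=int(k_neighbors),
        )
    stat = np.nanmedian if strategy == "median" else np.nanmean
    fills = stat(matrix.values, axis=1)
    return ImputationModel(strategy=strategy, cpg_ids=list(matrix.cpg_ids), fill_values=fills)


def apply_imputer(model: ImputationModel, matrix: BetaMatrix) -> BetaMatrix:
    """Fill every missing entry; observed entries are returned bit-identical."""
    index = {c: i for i, c in enumerate(model.cpg_ids)}
    absent = [c for c in matrix.cpg_ids if c not in index]
    if absent:
        raise KeyError(f"probes absent from the imputation model: {absent}")
    if matrix.n_missing == 0:
        return matrix
    positions = [index[c] for c in matrix.cpg_ids]
    values = matrix.values.copy()
    mask = np.isnan(values)
    if model.strategy == "knn":
        donors = model.train_data[:, positions]
        imputer = KNNImputer(n_neighbors=model.k_neighbors, weights="uniform")
        imputer.fit(donors)
        filled = imputer.transform(values.T).T
        values[mask] = filled[mask]
    else:
        fills = model.fill_values[positions]
        values[mask] = np.broadcast_to(fills[:, None], values.shape)[mask]
    return BetaMatrix(list(matrix.cpg_ids), list(matrix.sample_ids), values)


def preprocess_cohorts(
    labeled: list[BetaMatrix],
    unlabeled: list[BetaMatrix] | None = None,
    max_missing_frac: float = 0.2,
    strategy: str = "median",
    k_neighbors: int = 5,
):
    """Run the full preprocessing pipeline over labeled and unlabeled cohorts.

    Stage order: (1) intersect probes across all cohorts; (2) apply the
    missingness filter per cohort and keep only probes that survive in every
    cohort; (3) fit the imputer on the pooled labeled cohorts; (4) impute
    every cohort with that one model.

    Returns ``(processed labeled, processed unlabeled, ImputationModel,
    PreprocessReport)``.
    """
    if not labeled:
        raise ValueError("need at least one labeled cohort")
    unlabeled = list(unlabeled or [])
    cohorts = intersect_features(list(labeled) + unlabeled)
    n_common = cohorts[0].n_probes

    surviving = set(cohorts[0].cpg_ids)
    for cohort in cohorts:
        filtered, _ = filter_missing_cpgs(cohort, max_missing_frac)
        surviving &= set(filtered.cpg_ids)
    ordered = [c for c in cohorts[0].cpg_ids if c in surviving]
    if not ordered:
        raise ValueError("missingness filter removed every shared probe")
    cohorts = [m.select_probes(ordered) for m in cohorts]

    n_labeled = len(labeled)
    pooled_values = np.concatenate([m.values for m in cohorts[:n_labeled]], axis=1)
    pooled = BetaMatrix(
        ordered,
        [f"pooled_{i}" for i in range(pooled_values.shape[1])],
        pooled_values,
    )
    model = fit_imputer(pooled, strategy=strategy, k_neighbors=k_neighbors)
    processed = [apply_imputer(model, m) for m in cohorts]

    report = PreprocessReport(
        n_common_features=n_common,
        n_removed_by_missing_filter=n_common - len(ordered),
        n_final_features=len(ordered),
        strategy=strategy,
    )
    return processed[:n_labeled], processed[n_labeled:], model, report
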