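"""Class-conditional synthetic methylome cohorts.

Array beta values are bimodal, so both background and subtype-informative
CpGs are drawn from Beta distributions: background Beta(2, 2), and each
subtype owns a disjoint block of informative CpGs that its members draw
from a hypermethylated Beta(8, 2) (even class indices) or hypomethylated
Beta(2, 8) (odd class indices) instead.  Missingness is injected completely
at random; the unlabeled cohort can receive an additive mean shift (clipped
back to [0, 1]) as a deliberately crude batch-effect proxy.

The generator emulates the data regime of multi-cohort subtype studies —
a small labeled cohort, a larger unlabeled cohort from a different batch,
and a held-out labeled test cohort — without any array download.  Ground
truth for the unlabeled cohort is returned separately and never stored in
the UnlabeledDataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import BetaMatrix, LabeledDataset, SubtypeVocabulary, UnlabeledDataset


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults give a moderately separated 3-subtype problem: 200 CpGs of
    which 30 per subtype are informative, 40 labeled + 400 unlabeled + 200
    test samples, no missingness, and a 0.05 additive shift on the
    unlabeled cohort.
    """

    n_classes: int = 3
    n_cpgs: int = 200
    n_informative_per_class: int = 30
    background_params: tuple[float, float] = (2.0, 2.0)
    hyper_params: tuple[float, float] = (8.0, 2.0)
    hypo_params: tuple[float, float] = (2.0, 8.0)
    class_proportions: tuple[float, ...] | None = None  # None = uniform
    n_labeled: int = 40
    n_unlabeled: int = 400
    n_test: int = 200
    missing_rate: float = 0.0
    cohort_shift: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 subtypes")
        if self.n_classes * self.n_informative_per_class > self.n_cpgs:
            raise ValueError(
                f"{self.n_classes} x {self.n_informative_per_class} informative CpGs "
                f"exceed n_cpgs={self.n_cpgs}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.cohort_shift < 0:
            raise ValueError("cohort_shift must be nonnegative")
        for name in ("background_params", "hyper_params", "hypo_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must be positive Beta parameters")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.size != self.n_classes or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("class_proportions must be a length-C probability vector")

    @property
    def vocabulary(self) -> SubtypeVocabulary:
        return SubtypeVocabulary(tuple(f"subtype_{i}" for i in range(self.n_classes)))


def _informative_block(spec: SyntheticSpec, cls: int) -> slice:
    start = cls * spec.n_informative_per_class
    return slice(start, start + spec.n_informative_per_class)


def _draw_cohort(spec: SyntheticSpec, n: int, rng: np.random.Generator):
    """Probes x samples values plus per-sample class indices."""
    p = spec.class_proportions
    classes = rng.choice(spec.n_classes, size=n, p=p)
    a0, b0 = spec.background_params
    values = rng.beta(a0, b0, size=(spec.n_cpgs, n))
    for cls in range(spec.n_classes):
        members = np.flatnonzero(classes == cls)
        if members.size == 0:
            continue
        a, b = spec.hyper_params if cls % 2 == 0 else spec.hypo_params
        block = _informative_block(spec, cls)
        values[block, members] = rng.beta(
            a, b, size=(spec.n_informative_per_class, members.size)
        )
    return values, classes


def _cohort_matrix(prefix: str, cpg_ids, values) -> BetaMatrix:
    sample_ids = [f"{prefix}{i:04d}" for i in range(values.shape[1])]
    return BetaMatrix(cpg_ids, sample_ids, values)


def generate(spec: SyntheticSpec):
    """Draw one synthetic study, reproducibly from ``spec.seed``.

    Returns ``(labeled, unlabeled, test, unlabeled_truth)`` where
    ``unlabeled_truth`` is the ground-truth class index array of the
    unlabeled cohort, kept outside the UnlabeledDataset so it can never
    leak into training.
    """
    rng = np.random.default_rng(spec.seed)
    cpg_ids = [f"cg{i:08d}" for i in range(spec.n_cpgs)]
    vocab = spec.vocabulary

    values_l, y_l = _draw_cohort(spec, spec.n_labeled, rng)
    values_u, y_u = _draw_cohort(spec, spec.n_unlabeled, rng)
    values_t, y_t = _draw_cohort(spec, spec.n_test, rng)

    if spec.cohort_shift > 0:
        values_u = np.clip(values_u + spec.cohort_shift, 0.0, 1.0)

    if spec.missing_rate > 0:
        for values in (values_l, values_u, values_t):
            mask = rng.random(values.shape) < spec.missing_rate
            values[mask] = np.nan

    labeled = LabeledDataset(_cohort_matrix("L", cpg_ids, values_l), y_l, vocab)
    unlabeled = UnlabeledDataset(_cohort_matrix("U", cpg_ids, values_u))
    test = LabeledDataset(_cohort_matrix("T", cpg_ids, values_t), y_t, vocab)
    return labeled, unlabeled, test, y_u


def inject_missing(matrix: BetaMatrix, rate: float, seed: int = 0) -> BetaMatrix:
    """Replace each entry by NaN independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    values[rng.random(values.shape) < rate] = np.nan
    return BetaMatrix(list(matrix.cpg_ids), list(matrix.sample_ids), values)
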