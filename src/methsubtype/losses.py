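"""Training losses and the ramped unlabeled-loss weight.

Pre-training minimizes the mean cross-entropy over labeled samples.
Fine-tuning adds a second cross-entropy term over pseudo-labeled unlabeled
samples, weighted by a coefficient alpha(t) that stays at 0 for the first
T1 fine-tuning epochs, then rises linearly to alpha_f between T1 and T2 —
ramping slowly so the unlabeled term cannot swamp the labeled signal early,
when pseudo-labels are still unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import UnlabeledDataset
from .model import ModelParams, predict_proba

LOG_EPS = 1e-12  # clamp for log() so saturated posteriors cannot produce -inf


@dataclass(frozen=True)
class RampSchedule:
    """Piecewise-linear ramp: 0 before t1, alpha_f from t2 on."""

    t1: int = 100
    t2: int = 200
    alpha_f: float = 0.05

    def __post_init__(self):
        if not 0 <= self.t1 < self.t2:
            raise ValueError(f"need 0 <= t1 < t2, got t1={self.t1}, t2={self.t2}")
        if self.alpha_f < 0:
            raise ValueError(f"alpha_f must be nonnegative, got {self.alpha_f}")


@dataclass
class PseudoLabels:
    """Hard pseudo-subtype assignments for an unlabeled cohort.

    ``mask`` flags the samples admitted to the unlabeled loss term; with a
    confidence threshold active, samples whose maximum posterior does not
    strictly exceed it are masked out.
    """

    labels: np.ndarray  # (m,) class indices
    mask: np.ndarray  # (m,) bool
    source_epoch: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must have equal length")

    @property
    def n_included(self) -> int:
        return int(self.mask.sum())


def cross_entropy(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Mean over samples of -log(posterior of the true class)."""
    posteriors = np.asarray(posteriors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if posteriors.ndim != 2:
        raise ValueError("posteriors must be 2-D (samples x classes)")
    n, C = posteriors.shape
    if n < 1:
        raise ValueError("need at least one sample")
    if labels.shape != (n,):
        raise ValueError(f"need one label per sample, got {labels.shape} for n={n}")
    if labels.size and (labels.min() < 0 or labels.max() >= C):
        raise ValueError(f"label index out of range for {C} classes")
    p = np.clip(posteriors[np.arange(n), labels], LOG_EPS, None)
    return float(-np.log(p).mean())


def alpha_schedule(t: int, schedule: RampSchedule = RampSchedule()) -> float:
    """Unlabeled-loss weight at fine-tuning epoch ``t``."""
    if t < 0:
        raise ValueError(f"epoch must be nonnegative, got {t}")
    if t < schedule.t1:
        return 0.0
    if t < schedule.t2:
        return (t - schedule.t1) / (schedule.t2 - schedule.t1) * schedule.alpha_f
    return schedule.alpha_f


def finetune_loss(
    labeled_posteriors: np.ndarray,
    labels: np.ndarray,
    unlabeled_posteriors: np.ndarray,
    pseudo: PseudoLabels,
    alpha: float,
):
    """Weighted sum of labeled and pseudo-labeled cross-entropies.

    The unlabeled term is the mean over mask-included samples only (with
    thresholding off the mask is all-true and this is the plain mean over
    the unlabeled cohort).  Returns ``(total, labeled_term, unlabeled_term)``
    where ``total = labeled_term + alpha * unlabeled_term``.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    labeled_term = cross_entropy(labeled_posteriors, labels)
    included = pseudo.mask
    if included.sum() == 0:
        return labeled_term, labeled_term, 0.0
    unlabeled_term = cross_entropy(
        np.asarray(unlabeled_posteriors, dtype=float)[included],
        pseudo.labels[included],
    )
    return labeled_term + alpha * unlabeled_term, labeled_term, unlabeled_term


def assign_pseudo_labels(
    params: ModelParams,
    unlabeled: UnlabeledDataset | np.ndarray,
    confidence_threshold: float | None = None,
    epoch: int = 0,
) -> PseudoLabels:
    """Assign each unlabeled sample the subtype with the highest posterior.

    Runs in inference mode (no dropout) so the targets are stable.  With a
    confidence threshold tau, only samples whose maximum posterior is
    strictly greater than tau are admitted to the unlabeled loss; masks are
    recomputed on every call, so an excluded sample re-enters as soon as the
    model becomes confident about it.
    """
    if isinstance(unlabeled, UnlabeledDataset):
        X = unlabeled.matrix.samples_by_features()
    else:
        X = np.asarray(unlabeled, dtype=float)
    result = predict_proba(params, X)
    if confidence_threshold is None:
        mask = np.ones(X.shape[0], dtype=bool)
    else:
        mask = result.max_prob > confidence_threshold
    return PseudoLabels(labels=result.predicted, mask=mask, source_epoch=epoch)
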