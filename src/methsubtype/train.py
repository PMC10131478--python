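"""Two-phase semi-supervised training: supervised pre-training, then
pseudo-label fine-tuning.

Pre-training runs Adam on the labeled cross-entropy (learning rate 1e-5 for
1500 epochs by default).  Fine-tuning (1e-3, 3000 epochs) recomputes
pseudo-labels from the current parameters before every weight update and
minimizes the labeled cross-entropy plus alpha(t) times the pseudo-labeled
cross-entropy, with alpha(t) ramping from 0 to alpha_f between epochs T1
and T2 of the fine-tuning clock.  Training is full-batch by default, so one
epoch is one weight update and the ramp's epoch counter and the update
counter coincide; with ``batch_size`` set, pseudo-labels are refreshed
before every batch step while alpha(t) still advances per epoch.

Dropout and the L2 weight penalty are active in both phases.  All
randomness (weight init, dropout masks, batch shuffling) flows from the
config seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import align_to_features
from .losses import LOG_EPS, PseudoLabels, RampSchedule, alpha_schedule, assign_pseudo_labels
from .matrix import BetaMatrix, LabeledDataset, SubtypeVocabulary, UnlabeledDataset
from .model import ModelParams, backward, forward_cached, init_params, predict_proba, softmax


@dataclass
class TrainingConfig:
    """All training hyperparameters with their published defaults."""

    lr_pretrain: float = 1e-5
    epochs_pretrain: int = 1500
    lr_finetune: float = 1e-3
    epochs_finetune: int = 3000
    dropout_rate: float = 0.7
    l2_coefficient: float = 1e-4
    ramp: RampSchedule = field(default_factory=RampSchedule)
    confidence_threshold: float | None = None
    batch_size: int | None = None  # None = full batch
    hidden_sizes: tuple[int, ...] = (1000, 500)
    class_oversample: dict | None = None  # class index -> replication factor
    seed: int = 0

    def __post_init__(self):
        if self.lr_pretrain <= 0 or self.lr_finetune <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs_pretrain < 0 or self.epochs_finetune < 0:
            raise ValueError("epoch counts must be nonnegative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be nonnegative")


@dataclass
class TrainingHistory:
    """Per-epoch training log."""

    records: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append(record)

    def extend(self, other: "TrainingHistory") -> None:
        self.records.extend(other.records)
        self.warnings.extend(other.warnings)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        columns = ["epoch", "phase", "labeled_loss", "unlabeled_loss", "alpha", "n_pseudo_included"]
        return pd.DataFrame(self.records, columns=columns)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class AdamOptimizer:
    """Adam with the conventional moment defaults; state per parameter array."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(a) for a in arrays]
            self._v = [np.zeros_like(a) for a in arrays]
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for a, g, m, v in zip(arrays, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_arrays(labeled) -> tuple[np.ndarray, np.ndarray, SubtypeVocabulary | None]:
    if isinstance(labeled, LabeledDataset):
        return labeled.matrix.samples_by_features(), labeled.labels, labeled.vocabulary
    X, y = labeled
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int), None


def _check_complete(X: np.ndarray, what: str) -> None:
    if np.isnan(X).any():
        raise ValueError(f"{what} contains missing values; run preprocessing first")


def _oversample(X: np.ndarray, y: np.ndarray, factors: dict | None):
    """Replicate samples of small classes by an integer factor (a simple
    stand-in for generative augmentation of rare subtypes)."""
    if not factors:
        return X, y
    blocks_X, blocks_y = [X], [y]
    for cls, factor in factors.items():
        idx = np.flatnonzero(y == int(cls))
        for _ in range(int(factor) - 1):
            blocks_X.append(X[idx])
            blocks_y.append(y[idx])
    return np.concatenate(blocks_X, axis=0), np.concatenate(blocks_y, axis=0)


def loss_and_grads(
    params: ModelParams,
    X_labeled: np.ndarray,
    y_labeled: np.ndarray,
    X_unlabeled: np.ndarray | None,
    pseudo: PseudoLabels | None,
    alpha: float,
    config: TrainingConfig,
    rng: np.random.Generator | None,
    training_mode: bool = True,
):
    """Training loss terms and parameter gradients for one update.

    The batch stacks labeled rows (per-sample weight 1/n) with the
    mask-included pseudo-labeled rows (weight alpha / n_included).  When
    alpha is 0 or no pseudo-labeled sample is included, the unlabeled rows
    are left out entirely, so the computation — including dropout-mask
    draws — is identical to plain supervised training.
    """
    n = X_labeled.shape[0]
    use_unlabeled = (
        alpha > 0 and pseudo is not None and X_unlabeled is not None and pseudo.n_included > 0
    )
    if use_unlabeled:
        included = np.flatnonzero(pseudo.mask)
        X = np.concatenate([X_labeled, X_unlabeled[included]], axis=0)
        targets = np.concatenate([y_labeled, pseudo.labels[included]])
        weights = np.concatenate(
            [np.full(n, 1.0 / n), np.full(included.size, alpha / included.size)]
        )
    else:
        X = X_labeled
        targets = y_labeled
        weights = np.full(n, 1.0 / n)

    logits, cache = forward_cached(
        params, X, config.dropout_rate, training_mode=training_mode, rng=rng
    )
    probs = softmax(logits)
    picked = np.clip(probs[np.arange(X.shape[0]), targets], LOG_EPS, None)
    neglog = -np.log(picked)
    labeled_loss = float(neglog[:n].mean())
    unlabeled_loss = float(neglog[n:].mean()) if use_unlabeled else 0.0

    onehot = np.zeros_like(probs)
    onehot[np.arange(X.shape[0]), targets] = 1.0
    dlogits = (probs - onehot) * weights[:, None]
    grads_w, grads_b = backward(params, cache, dlogits)
    if config.l2_coefficient > 0:
        for gw, w in zip(grads_w, params.weights):
            gw += 2.0 * config.l2_coefficient * w
    return labeled_loss, unlabeled_loss, grads_w, grads_b


def _run_phase(
    params: ModelParams,
    X_labeled: np.ndarray,
    y_labeled: np.ndarray,
    X_unlabeled: np.ndarray | None,
    config: TrainingConfig,
    phase: str,
) -> tuple[ModelParams, TrainingHistory]:
    finetuning = phase == "finetune"
    lr = config.lr_finetune if finetuning else config.lr_pretrain
    epochs = config.epochs_finetune if finetuning else config.epochs_pretrain
    params = params.copy()
    history = TrainingHistory()
    if epochs == 0:
        return params, history

    rng = np.random.default_rng(config.seed)
    adam = AdamOptimizer(lr)
    arrays = params.weights + params.biases
    n = X_labeled.shape[0]
    batch = config.batch_size if config.batch_size else n

    for epoch in range(epochs):
        alpha = alpha_schedule(epoch, config.ramp) if finetuning else 0.0
        labeled_losses, unlabeled_losses = [], []
        n_included = 0
        if batch >= n:
            starts = [0]
            order = np.arange(n)
        else:
            order = rng.permutation(n)
            starts = list(range(0, n, batch))
        for s in starts:
            idx = order[s : s + batch]
            pseudo = None
            if finetuning and X_unlabeled is not None and X_unlabeled.shape[0] > 0:
                pseudo = assign_pseudo_labels(
                    params, X_unlabeled, config.confidence_threshold, epoch=epoch
                )
                n_included = pseudo.n_included
            ll, ul, gw, gb = loss_and_grads(
                params, X_labeled[idx], y_labeled[idx], X_unlabeled, pseudo, alpha, config, rng
            )
            adam.step(arrays, gw + gb)
            labeled_losses.append(ll)
            unlabeled_losses.append(ul)
        history.append(
            epoch=epoch,
            phase=phase,
            labeled_loss=float(np.mean(labeled_losses)),
            unlabeled_loss=float(np.mean(unlabeled_losses)),
            alpha=alpha,
            n_pseudo_included=n_included,
        )
    return params, history


def pretrain(params: ModelParams, labeled, config: TrainingConfig):
    """Supervised phase: Adam on the labeled cross-entropy plus L2.

    ``labeled`` is a LabeledDataset or an ``(X, y)`` pair in samples x
    features layout.  Returns updated parameters and the per-epoch history;
    with ``epochs_pretrain=0`` the parameters come back unchanged.
    """
    X, y, vocab = _as_arrays(labeled)
    _check_complete(X, "labeled data")
    X, y = _oversample(X, y, config.class_oversample)
    history = TrainingHistory()
    if vocab is not None:
        absent = [name for i, name in enumerate(vocab.names) if not (y == i).any()]
        if absent:
            history.warnings.append(f"vocabulary classes absent from labeled data: {absent}")
    params, phase_history = _run_phase(params, X, y, None, config, "pretrain")
    history.extend(phase_history)
    return params, history


def finetune(params: ModelParams, labeled, unlabeled, config: TrainingConfig):
    """Semi-supervised phase: pseudo-labels refreshed before every update.

    ``unlabeled`` is an UnlabeledDataset, a samples x features array, or
    None.  With no unlabeled samples (or alpha_f = 0) the trajectory is
    bit-identical to supervised training at the fine-tuning rate.
    """
    X, y, _ = _as_arrays(labeled)
    _check_complete(X, "labeled data")
    X, y = _oversample(X, y, config.class_oversample)
    if unlabeled is None:
        Xu = None
    elif isinstance(unlabeled, UnlabeledDataset):
        Xu = unlabeled.matrix.samples_by_features()
    else:
        Xu = np.asarray(unlabeled, dtype=float)
    if Xu is not None:
        if Xu.shape[0] and Xu.shape[1] != params.n_features:
            raise ValueError(
                f"unlabeled data has {Xu.shape[1]} features, model expects {params.n_features}"
            )
        _check_complete(Xu, "unlabeled data")
    return _run_phase(params, X, y, Xu, config, "finetune")


@dataclass
class ModelBundle:
    """A trained model plus everything needed to score new cohorts.

    Bundles the parameters with the ordered CpG feature list and the
    subtype vocabulary, so prediction can align an incoming matrix to the
    training features and report named subtypes.
    """

    params: ModelParams
    cpg_ids: list
    vocabulary: SubtypeVocabulary

    def predict(self, matrix: BetaMatrix) -> pd.DataFrame:
        """Posteriors and the argmax subtype call for each sample."""
        aligned = align_to_features(matrix, self.cpg_ids)
        _check_complete(aligned.values, "matrix")
        result = predict_proba(self.params, aligned.samples_by_features())
        frame = pd.DataFrame(
            result.posteriors, index=aligned.sample_ids, columns=list(self.vocabulary.names)
        )
        frame.index.name = "sample_id"
        frame["predicted_subtype"] = [self.vocabulary.names[i] for i in result.predicted]
        frame["max_prob"] = result.max_prob
        return frame

    def save(self, path) -> None:
        meta = {
            "cpg_ids": list(self.cpg_ids),
            "subtypes": list(self.vocabulary.names),
            "hidden_sizes": list(self.params.hidden_sizes),
            "n_features": self.params.n_features,
            "n_classes": self.params.n_classes,
        }
        arrays = {"meta": np.array(json.dumps(meta))}
        for i, (w, b) in enumerate(zip(self.params.weights, self.params.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            n_layers = len(meta["hidden_sizes"]) + 1
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
        params = ModelParams(
            weights,
            biases,
            tuple(meta["hidden_sizes"]),
            int(meta["n_features"]),
            int(meta["n_classes"]),
        )
        return cls(params=params, cpg_ids=meta["cpg_ids"], vocabulary=SubtypeVocabulary(tuple(meta["subtypes"])))


def fit(
    labeled: LabeledDataset,
    unlabeled: UnlabeledDataset | None,
    config: TrainingConfig | None = None,
):
    """Full pipeline on datasets: init, pre-train, fine-tune; returns a bundle.

    Returns ``(ModelBundle, TrainingHistory)`` with the pre-training and
    fine-tuning records concatenated.
    """
    config = config or TrainingConfig()
    _check_complete(labeled.matrix.values, "labeled data")
    params = init_params(
        labeled.matrix.n_probes,
        config.hidden_sizes,
        len(labeled.vocabulary),
        seed=config.seed,
    )
    params, history = pretrain(params, labeled, config)
    params, ft_history = finetune(params, labeled, unlabeled, config)
    history.extend(ft_history)
    bundle = ModelBundle(
        params=params, cpg_ids=list(labeled.matrix.cpg_ids), vocabulary=labeled.vocabulary
    )
    return bundle, history
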