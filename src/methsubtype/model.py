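"""Feed-forward softmax classifier over methylation features.

The architecture is a stack of fully connected layers: each hidden layer is
an affine map followed by an ELU activation (default hidden sizes 1000 and
500), and the output is a final un-activated affine map to C subtype logits
passed through a softmax.  Dropout (inverted scaling) acts on hidden
activations during training only; inference — including pseudo-label
computation, which needs stable targets — is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ModelParams:
    """Affine-layer weights and biases of the classifier.

    ``weights[i]`` has shape (fan_in, fan_out); ``biases[i]`` has shape
    (fan_out,).  The last layer maps onto the C subtype logits.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_sizes: tuple[int, ...]
    n_features: int
    n_classes: int

    def __post_init__(self):
        dims = (self.n_features, *self.hidden_sizes, self.n_classes)
        if len(self.weights) != len(dims) - 1 or len(self.biases) != len(dims) - 1:
            raise ValueError("layer count does not match (n_features, hidden_sizes, n_classes)")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (dims[i], dims[i + 1]) or b.shape != (dims[i + 1],):
                raise ValueError(f"layer {i}: expected {(dims[i], dims[i + 1])}, got {w.shape}")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {i}: non-finite parameters")

    def copy(self) -> "ModelParams":
        return ModelParams(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            tuple(self.hidden_sizes),
            self.n_features,
            self.n_classes,
        )


@dataclass
class PredictionResult:
    """Posteriors plus the argmax subtype call per sample."""

    posteriors: np.ndarray  # (n_samples, C)
    predicted: np.ndarray  # (n_samples,) class indices
    max_prob: np.ndarray  # (n_samples,)


def elu(z):
    """ELU activation (unit scale): z for z > 0, exp(z) - 1 otherwise."""
    z = np.asarray(z, dtype=float)
    return np.where(z > 0, z, np.expm1(z))


def elu_grad(z):
    """Derivative of ELU: 1 for z > 0, exp(z) otherwise."""
    z = np.asarray(z, dtype=float)
    return np.where(z > 0, 1.0, np.exp(z))


def softmax(logits):
    """Row-wise numerically stable softmax."""
    logits = np.asarray(logits, dtype=float)
    squeeze = logits.ndim == 1
    if squeeze:
        logits = logits[None, :]
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=1, keepdims=True)
    return out[0] if squeeze else out


def init_params(
    n_features: int,
    hidden_sizes: tuple[int, ...] = (1000, 500),
    n_classes: int = 2,
    seed: int = 0,
) -> ModelParams:
    """He-style variance-scaled random weights, zero biases, seed-reproducible."""
    if n_features < 1 or n_classes < 2 or any(h < 1 for h in hidden_sizes):
        raise ValueError("layer sizes must be positive and n_classes >= 2")
    rng = np.random.default_rng(seed)
    dims = (n_features, *hidden_sizes, n_classes)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return ModelParams(weights, biases, tuple(hidden_sizes), n_features, n_classes)


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    # inverted dropout: scaling at train time keeps inference scale-free
    return (rng.random(shape) >= rate) / (1.0 - rate)


def forward_cached(
    params: ModelParams,
    X: np.ndarray,
    dropout_rate: float = 0.0,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward pass returning logits plus the per-layer cache for backprop.

    Cache entries per hidden layer: (input, pre-activation, dropout mask).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_features:
        raise ValueError(f"X must be (n_samples, {params.n_features}), got {X.shape}")
    if not 0 <= dropout_rate < 1:
        raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
    use_dropout = training_mode and dropout_rate > 0
    if use_dropout and rng is None:
        rng = np.random.default_rng(0)

    cache = []
    a = X
    n_hidden = len(params.hidden_sizes)
    for i in range(n_hidden):
        z = a @ params.weights[i] + params.biases[i]
        h = elu(z)
        mask = _dropout_mask(rng, h.shape, dropout_rate) if use_dropout else None
        cache.append((a, z, mask))
        a = h * mask if mask is not None else h
    logits = a @ params.weights[-1] + params.biases[-1]
    cache.append((a, None, None))
    return logits, cache


def forward(
    params: ModelParams,
    X: np.ndarray,
    dropout_rate: float = 0.0,
    training_mode: bool = False,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Compute subtype logits for a samples x features matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logits, _ = forward_cached(params, X, dropout_rate, training_mode, rng)
    return logits


def backward(params: ModelParams, cache, dlogits: np.ndarray):
    """Backpropagate a logit-space gradient through the cached forward pass.

    Returns (weight gradients, bias gradients) matching ``params`` layer by
    layer.  ``dlogits`` must already include any per-sample loss weights.
    """
    grads_w = [None] * len(params.weights)
    grads_b = [None] * len(params.biases)
    a_last = cache[-1][0]
    grads_w[-1] = a_last.T @ dlogits
    grads_b[-1] = dlogits.sum(axis=0)
    da = dlogits @ params.weights[-1].T
    for i in range(len(params.hidden_sizes) - 1, -1, -1):
        a_in, z, mask = cache[i]
        if mask is not None:
            da = da * mask
        dz = da * elu_grad(z)
        grads_w[i] = a_in.T @ dz
        grads_b[i] = dz.sum(axis=0)
        if i > 0:
            da = dz @ params.weights[i].T
    return grads_w, grads_b


def predict_proba(params: ModelParams, X: np.ndarray) -> PredictionResult:
    """Inference-mode posteriors; argmax ties break to the lowest class index."""
    logits = forward(params, X, dropout_rate=0.0, training_mode=False)
    posteriors = softmax(logits)
    predicted = np.argmax(posteriors, axis=1)
    max_prob = posteriors[np.arange(posteriors.shape[0]), predicted]
    return PredictionResult(posteriors=posteriors, predicted=predicted, max_prob=max_prob)


def l2_penalty(params: ModelParams, coefficient: float) -> float:
    """coefficient x sum of squared weight entries; biases are excluded."""
    if coefficient < 0:
        raise ValueError(f"L2 coefficient must be nonnegative, got {coefficient}")
    if coefficient == 0:
        return 0.0
    return float(coefficient * sum(float((w * w).sum()) for w in params.weights))
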