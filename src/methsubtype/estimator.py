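"""Scikit-learn estimator interface to the semi-supervised subtype classifier.

Follows the ``sklearn.semi_supervised`` convention: ``fit(X, y)`` treats
samples with ``y == -1`` as unlabeled.  The estimator composes with
pipelines, ``clone`` and model selection; the heavy lifting lives in the
functional training engine (:mod:`methsubtype.train`).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .losses import RampSchedule
from .model import init_params, predict_proba
from .train import TrainingConfig, finetune, pretrain


class SemiSupervisedSubtypeClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward softmax classifier trained with pseudo-label fine-tuning.

    A supervised pre-training phase on the labeled samples is followed by a
    fine-tuning phase in which unlabeled samples receive pseudo-labels —
    the class with the highest current posterior, refreshed before every
    weight update — and contribute a cross-entropy term weighted by a ramp
    alpha(t) that grows linearly from 0 to ``alpha_f`` between epochs
    ``t1`` and ``t2``.

    Parameters
    ----------
    hidden_sizes : tuple of int, default (1000, 500)
        Widths of the ELU hidden layers.
    lr_pretrain, epochs_pretrain : float, int
        Adam learning rate and epoch budget of the supervised phase
        (defaults 1e-5 and 1500).
    lr_finetune, epochs_finetune : float, int
        Same for the semi-supervised phase (defaults 1e-3 and 3000).
    dropout_rate : float, default 0.7
        Dropout on hidden activations during training.
    l2_coefficient : float, default 1e-4
        Weight-decay strength on the weight matrices.
    t1, t2, alpha_f : ramp of the unlabeled-loss weight (defaults 100,
        200, 0.05), on the fine-tuning epoch clock.
    confidence_threshold : float or None, default None
        If set, only pseudo-labeled samples whose maximum posterior
        strictly exceeds it join the unlabeled loss.
    batch_size : int or None, default None
        None trains full-batch (one update per epoch).
    random_state : int, default 0
        Seed for weight initialization, dropout and shuffling.

    Attributes
    ----------
    classes_ : ndarray of the distinct labels seen in ``y`` (excluding -1).
    params_ : the fitted layer weights and biases.
    history_ : per-epoch training log.
    n_features_in_ : number of features seen during fit.

    Examples
    --------
    >>> clf = SemiSupervisedSubtypeClassifier(hidden_sizes=(8, 4),
    ...     epochs_pretrain=50, epochs_finetune=0, lr_pretrain=1e-2)
    >>> X = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
    >>> clf.fit(X, [0, 0, 1, 1]).predict(X).tolist()
    [0, 0, 1, 1]
    """

    def __init__(
        self,
        hidden_sizes=(1000, 500),
        lr_pretrain=1e-5,
        epochs_pretrain=1500,
        lr_finetune=1e-3,
        epochs_finetune=3000,
        dropout_rate=0.7,
        l2_coefficient=1e-4,
        t1=100,
        t2=200,
        alpha_f=0.05,
        confidence_threshold=None,
        batch_size=None,
        random_state=0,
    ):
        self.hidden_sizes = hidden_sizes
        self.lr_pretrain = lr_pretrain
        self.epochs_pretrain = epochs_pretrain
        self.lr_finetune = lr_finetune
        self.epochs_finetune = epochs_finetune
        self.dropout_rate = dropout_rate
        self.l2_coefficient = l2_coefficient
        self.t1 = t1
        self.t2 = t2
        self.alpha_f = alpha_f
        self.confidence_threshold = confidence_threshold
        self.batch_size = batch_size
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            lr_pretrain=self.lr_pretrain,
            epochs_pretrain=self.epochs_pretrain,
            lr_finetune=self.lr_finetune,
            epochs_finetune=self.epochs_finetune,
            dropout_rate=self.dropout_rate,
            l2_coefficient=self.l2_coefficient,
            ramp=RampSchedule(t1=self.t1, t2=self.t2, alpha_f=self.alpha_f),
            confidence_threshold=self.confidence_threshold,
            batch_size=self.batch_size,
            hidden_sizes=tuple(self.hidden_sizes),
            seed=self.random_state if self.random_state is not None else 0,
        )

    def fit(self, X, y):
        """Fit on labeled samples; rows with ``y == -1`` are unlabeled."""
        X, y = check_X_y(X, y, dtype=float)
        y = np.asarray(y)
        labeled_mask = y != -1
        if not labeled_mask.any():
            raise ValueError("fit needs at least one labeled sample (y != -1)")
        self.classes_ = np.unique(y[labeled_mask])
        if self.classes_.size < 2:
            raise ValueError("need at least 2 labeled classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_enc = np.array([class_index[v] for v in y[labeled_mask]], dtype=int)
        X_labeled = X[labeled_mask]
        X_unlabeled = X[~labeled_mask]

        config = self._config()
        params = init_params(
            X.shape[1], config.hidden_sizes, self.classes_.size, seed=config.seed
        )
        params, history = pretrain(params, (X_labeled, y_enc), config)
        params, ft_history = finetune(
            params, (X_labeled, y_enc), X_unlabeled if X_unlabeled.shape[0] else None, config
        )
        history.extend(ft_history)
        self.params_ = params
        self.history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        return predict_proba(self.params_, X).posteriors

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        result = predict_proba(self.params_, X)
        return self.classes_[result.predicted]
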