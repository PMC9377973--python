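"""A linear-softmax classifier trained by mini-batch SGD with pluggable loss.

The estimator exists to isolate the effect of the loss function: the model
is deliberately minimal (multinomial logistic regression trained with the
package's own analytic gradients — no autodiff framework), so any difference
between runs is attributable to the loss, not the backbone.  The training
schedule follows the study that motivates the package: momentum 0.9, initial
learning rate 0.005, learning rate multiplied by 1/3 every 3 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .balance import BalanceParams, ClassCounts, WeightTable, build_weight_table
from .losses import LossConfig, batch_grad_logits, batch_loss, softmax
from .metrics import ConfusionMatrix, confusion, macro_fnr, macro_fpr, per_class_report

__all__ = [
    "SoftmaxClassifier",
    "TrainingDivergedError",
    "TrainConfig",
    "TrainResult",
    "train",
    "evaluate",
]


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class SoftmaxClassifier(ClassifierMixin, BaseEstimator):
    """Linear-softmax classifier with a selectable imbalance-aware loss.

    Parameters
    ----------
    loss : {"ce", "wce", "focal", "cb", "db"}
        Loss family. "db" is the double-balanced loss; "cb" the
        effective-sample-size-weighted cross-entropy; "wce" inverse-frequency
        weighting; "focal" the hard-example-modulated cross-entropy.
    beta, rho : float
        Balance hyperparameters for the weight table built from the training
        tallies (used by "cb" and "db").
    gamma : float
        Focal modulation exponent.
    variant : {"printed", "derived"}
        Double-balanced parenthesization.
    lr, momentum, epochs, batch_size : training schedule.
    lr_decay_every, lr_decay_factor : multiply lr by the factor every that
        many epochs (defaults: 1/3 every 3).
    class_counts : ClassCounts, optional
        Override for the weight-table counts; defaults to the tallies of the
        fitted ``y``.
    random_state : int or None
        Seed for batch shuffling; fitting is bit-reproducible given a seed.

    Attributes
    ----------
    classes_ : ndarray of shape (k,)
    coef_ : ndarray of shape (k, n_features)
    intercept_ : ndarray of shape (k,)
    loss_history_ : ndarray of shape (epochs,), mean per-sample training
        loss of each epoch.
    weight_table_ : WeightTable built from the training tallies.
    """

    def __init__(
        self,
        loss: str = "ce",
        beta: float = 0.99,
        rho: float = 0.25,
        gamma: float = 2.0,
        variant: str = "printed",
        eps: float = 1e-12,
        lr: float = 0.005,
        momentum: float = 0.9,
        epochs: int = 12,
        batch_size: int = 32,
        lr_decay_every: int = 3,
        lr_decay_factor: float = 1.0 / 3.0,
        class_counts: ClassCounts | None = None,
        random_state: int | None = None,
    ):
        self.loss = loss
        self.beta = beta
        self.rho = rho
        self.gamma = gamma
        self.variant = variant
        self.eps = eps
        self.lr = lr
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_decay_every = lr_decay_every
        self.lr_decay_factor = lr_decay_factor
        self.class_counts = class_counts
        self.random_state = random_state

    def _loss_config(self) -> LossConfig:
        return LossConfig(
            kind=self.loss, gamma=self.gamma, variant=self.variant, eps=self.eps
        )

    def fit(self, X, y) -> "SoftmaxClassifier":
        X, y = check_X_y(X, y)
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        cfg = self._loss_config()

        self.classes_ = unique_labels(y)
        k = self.classes_.shape[0]
        y_idx = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]

        counts = self.class_counts
        if counts is None:
            counts = ClassCounts(
                tuple(str(c) for c in self.classes_),
                tuple(int(t) for t in np.bincount(y_idx, minlength=k)),
            )
        self.weight_table_ = build_weight_table(
            counts, BalanceParams(beta=self.beta, rho=self.rho)
        )

        rng = np.random.default_rng(self.random_state)
        W = np.zeros((self.n_features_in_, k))
        b = np.zeros(k)
        vW = np.zeros_like(W)
        vb = np.zeros_like(b)
        n = X.shape[0]
        history = np.empty(self.epochs)

        for epoch in range(self.epochs):
            lr_e = self.lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb, yb = X[idx], y_idx[idx]
                Z = Xb @ W + b
                if not np.all(np.isfinite(Z)):
                    raise TrainingDivergedError(epoch)
                G = batch_grad_logits(cfg, Z, yb, self.weight_table_)
                gW = Xb.T @ G / idx.size
                gb = G.mean(axis=0)
                vW = self.momentum * vW - lr_e * gW
                vb = self.momentum * vb - lr_e * gb
                W = W + vW
                b = b + vb
                epoch_loss += batch_loss(cfg, softmax(Z), yb, self.weight_table_) * idx.size
            mean_loss = epoch_loss / n
            if not np.isfinite(mean_loss) or not np.all(np.isfinite(W)):
                raise TrainingDivergedError(epoch)
            history[epoch] = mean_loss

        self.coef_ = W.T
        self.intercept_ = b
        self.loss_history_ = history
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X)
        return X @ self.coef_.T + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


# -- thin functional wrappers around the estimator ---------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Functional-interface bundle of training settings plus a LossConfig."""

    loss: LossConfig = field(default_factory=LossConfig)
    beta: float = 0.99
    rho: float = 0.25
    lr: float = 0.005
    momentum: float = 0.9
    epochs: int = 12
    batch_size: int = 32
    lr_decay_every: int = 3
    lr_decay_factor: float = 1.0 / 3.0
    seed: int = 0


@dataclass(frozen=True)
class TrainResult:
    model: SoftmaxClassifier
    loss_history: np.ndarray
    weight_table: WeightTable


def train(train_ds, cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Fit a :class:`SoftmaxClassifier` on a LabeledDataset."""
    clf = SoftmaxClassifier(
        loss=cfg.loss.kind,
        beta=cfg.beta,
        rho=cfg.rho,
        gamma=cfg.loss.gamma,
        variant=cfg.loss.variant,
        eps=cfg.loss.eps,
        lr=cfg.lr,
        momentum=cfg.momentum,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr_decay_every=cfg.lr_decay_every,
        lr_decay_factor=cfg.lr_decay_factor,
        random_state=cfg.seed,
    )
    clf.fit(train_ds.features, train_ds.labels)
    return TrainResult(clf, clf.loss_history_, clf.weight_table_)


def evaluate(result: TrainResult | SoftmaxClassifier, test_ds) -> dict:
    """Confusion matrix, per-class precision/recall and macro FNR/FPR."""
    model = result.model if isinstance(result, TrainResult) else result
    y_pred = model.predict(test_ds.features)
    k = model.classes_.shape[0]
    cm: ConfusionMatrix = confusion(
        test_ds.labels, y_pred, k, labels=test_ds.spec.counts.labels
    )
    report = per_class_report(cm)
    return {
        "confusion": cm,
        "report": report,
        "accuracy": float(np.trace(cm.table) / max(cm.total, 1)),
        "macro_fnr": macro_fnr(cm),
        "macro_fpr": macro_fpr(cm),
    }
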