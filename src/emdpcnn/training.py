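"""Network optimisation and per-subject transfer learning.

Training minimises mean categorical cross-entropy plus an L2 weight
penalty with Adam (adaptive steps from the gradient's first and second
moments).  Each epoch visits every example once in a seeded random
order; validation early stopping halts when the validation loss has not
improved for ``patience`` epochs and restores the best-validation
weights.  Transfer learning initialises a fresh copy of a pretrained
network, optionally freezes the shared convolutional stem, and
fine-tunes on one subject's training split.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .pcnn import PCNNModel, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "split_data",
    "cross_entropy",
    "train",
    "transfer_finetune",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the reference recipe: learning rate 1e-3, batch size
    32, Adam with (0.9, 0.999, 1e-8) moments, L2 penalty 1e-4, dropout is
    part of the architecture.  ``val_fraction`` is the share of the
    *training* split carved out for early stopping.
    """

    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 20
    l2: float = 1e-4
    val_fraction: float = 0.2
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class SplitPlan:
    """Disjoint train/validation/test index sets covering the dataset."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    stratified: bool = True

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train, self.val, self.test])
        if len(set(allidx.tolist())) != allidx.size:
            raise ValueError("split indices overlap")


def split_data(
    labels: np.ndarray,
    fractions: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
    val_fraction: float = 0.2,
) -> SplitPlan:
    """Stratified 70/30-style split with a validation share inside train.

    ``fractions = (train, test)`` must sum to 1; ``val_fraction`` of the
    training share is further carved out (stratified) for early stopping.
    Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("train and test fractions must sum to 1")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials to stratify")
    outer = StratifiedShuffleSplit(n_splits=1, test_size=fractions[1], random_state=seed)
    train_all, test = next(outer.split(np.zeros_like(labels), labels))
    inner = StratifiedShuffleSplit(n_splits=1, test_size=val_fraction, random_state=seed)
    tr, va = next(inner.split(np.zeros(train_all.size), labels[train_all]))
    return SplitPlan(train=train_all[tr], val=train_all[va], test=test)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy of probability rows against labels."""
    p = np.clip(probs[np.arange(y.size), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


def _loss_and_backward(model: PCNNModel, x: np.ndarray, y: np.ndarray,
                       l2: float, train_mode: bool = True) -> float:
    """Forward + backward of cross-entropy + L2; fills layer gradients."""
    logits = model.forward_logits(x, train=train_mode)
    probs = softmax(logits)
    loss = cross_entropy(probs, y)
    if l2 > 0:
        loss += l2 * sum(
            float(np.sum(p**2))
            for p, pen in zip(model.parameters(), model.penalized_mask())
            if pen
        )
    g = probs.copy()
    g[np.arange(y.size), y] -= 1.0
    model.backward(g / y.size)
    if l2 > 0:
        for p, gr, pen in zip(model.parameters(), model.gradients(), model.penalized_mask()):
            if pen:
                gr += 2.0 * l2 * p
    return loss


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainConfig):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.cfg = cfg

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             trainable: list[bool]) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for p, g, m, v, ok in zip(params, grads, self.m, self.v, trainable):
            if not ok:
                continue
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g**2
            p -= c.lr * (m / b1t) / (np.sqrt(v / b2t) + c.eps)


def _evaluate(model: PCNNModel, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    probs = np.vstack([
        softmax(model.forward_logits(x[i : i + batch], train=False))
        for i in range(0, len(x), batch)
    ])
    return cross_entropy(probs, y), float(np.mean(probs.argmax(axis=1) == y))


def train(
    model: PCNNModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[PCNNModel, dict]:
    """Optimise in place; returns the model and a per-epoch history dict.

    Stops early when validation loss fails to improve for ``cfg.patience``
    epochs, restoring the best-validation weights.  Aborts with a
    diagnostic if the loss diverges to NaN.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters(), cfg)
    history: dict = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
                     "stopped_epoch": None, "seed": cfg.seed}
    best_loss = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = _loss_and_backward(model, x_train[idx], y_train[idx], cfg.l2)
            if np.isnan(loss):
                raise FloatingPointError(f"training loss diverged to NaN at epoch {epoch}")
            opt.step(model.parameters(), model.gradients(), model.trainable_mask())
            epoch_loss += loss
            n_batches += 1
        tr_loss, tr_acc = _evaluate(model, x_train, y_train)
        va_loss, va_acc = _evaluate(model, x_val, y_val)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        logger.debug("epoch %d: train %.4f/%.3f val %.4f/%.3f",
                     epoch, tr_loss, tr_acc, va_loss, va_acc)
        if va_loss < best_loss - 1e-12:
            best_loss = va_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history["stopped_epoch"] = epoch
                break
    model.set_weights(best_weights)
    return model, history


def transfer_finetune(
    pretrained: PCNNModel,
    x_subject: np.ndarray,
    y_subject: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    freeze_stem: bool = True,
    split_seed: int | None = None,
) -> tuple[PCNNModel, dict]:
    """Fine-tune a copy of ``pretrained`` on one subject's data.

    The subject's trials are split 70/30 (stratified; validation carved
    from the training share) and the copy is trained on the subject's
    training split, optionally with the shared convolutional stem frozen.
    With ``cfg.max_epochs == 0`` the returned model is weight-identical
    to the pretrained one.  The history dict records the split and the
    subject test accuracy of both the pretrained and fine-tuned weights.
    """
    model = copy.deepcopy(pretrained)
    if x_subject.shape[1:] != tuple(model.input_shape):
        raise ValueError("subject data shape does not match pretrained model input")
    model.freeze_stem(freeze_stem)
    if freeze_stem and not model.head:
        raise ValueError("cannot freeze the stem of a model without a trainable head")
    plan = split_data(
        y_subject, (0.7, 0.3),
        seed=cfg.seed if split_seed is None else split_seed,
        val_fraction=cfg.val_fraction,
    )
    _, pre_acc = _evaluate(pretrained, x_subject[plan.test], y_subject[plan.test])
    history: dict = {"pretrained_test_acc": pre_acc, "split": plan}
    if cfg.max_epochs > 0:
        model, fit_hist = train(
            model,
            x_subject[plan.train], y_subject[plan.train],
            x_subject[plan.val], y_subject[plan.val],
            cfg,
        )
        history["fit"] = fit_hist
    model.freeze_stem(False)
    _, post_acc = _evaluate(model, x_subject[plan.test], y_subject[plan.test])
    history["finetuned_test_acc"] = post_acc
    return model, history
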