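"""Supervised training of the model variants and confusion-matrix evaluation.

The optimization protocol is plain minibatch SGD on mean cross-entropy:
batches of 32 sampled with replacement, a constant learning rate of 0.001,
dropout 0.5 before FC2 during training only, and He-style initialization
(Normal(0, √(2/fan_in))) for every trainable weight.  The first convolution
layer holds the analytic filter bank and is frozen throughout.

Because the first block (conv1 → ReLU → pool → LRN in the shallow variants)
has no trainable parameters, its outputs for the training images are
precomputed once and minibatches are drawn from that feature cache, which
makes desk-scale training runs (tens of thousands of iterations) practical
on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .architectures import Conv2D, Dense, Model, softmax
from .stimuli import EXPRESSIONS, LabeledImageSet, prepare_input


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.001
    iterations: int = 240_000  # full protocol; desk-scale runs use ~20,000
    seed: int = 0
    eval_interval: int = 1000
    max_cache_bytes: int = 3_000_000_000

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainTrace:
    """Per-checkpoint loss and correct rates recorded during training."""

    iteration: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    train_correct_rate: list[float] = field(default_factory=list)
    val_correct_rate: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized 7×7 rates; rows are true labels, columns predictions."""

    rates: np.ndarray
    counts: np.ndarray
    labels: tuple = EXPRESSIONS

    @property
    def mean_correct_rate(self) -> float:
        """Unweighted mean of the per-expression correct rates."""
        return float(np.mean(np.diag(self.rates)))


def initialize_weights(model: Model, seed: int) -> Model:
    """Normal(0, √(2/N)) initialization of all trainable layers, N the total
    weight count of the layer; biases zero; conv1 stays untouched.

    Taking N as the layer's full weight count (rather than its fan-in) makes
    the initial output distribution near-uniform, so training starts from the
    chance-level loss ln 7 ≈ 1.946 and plain SGD at the protocol's constant
    learning rate is stable; fan-in scaling drives the final-layer ReLUs into
    permanent silence under this protocol (see the methods note).
    """
    rng = np.random.default_rng(seed)
    for lyr in model.trainable_layers():
        if not isinstance(lyr, (Conv2D, Dense)):  # pragma: no cover
            raise TypeError(f"unexpected trainable layer {type(lyr)}")
        lyr.W[...] = rng.normal(0.0, np.sqrt(2.0 / lyr.W.size), size=lyr.W.shape)
        lyr.b[...] = 0.0
    return model


def class_labels(dataset: LabeledImageSet) -> np.ndarray:
    return np.array([EXPRESSIONS.index(e) for e in dataset.expression])


def frozen_features(
    model: Model, dataset: LabeledImageSet, batch: int = 32
) -> tuple[np.ndarray, int]:
    """Outputs of the frozen prefix (all layers before the first trainable one)
    for every item, plus the layer index training resumes from."""
    start = model.first_trainable_index()
    feats = []
    for lo in range(0, len(dataset), batch):
        idx = range(lo, min(lo + batch, len(dataset)))
        x = model._check_batch(np.stack([prepare_input(dataset.image(i)) for i in idx]))
        for lyr in model.layers[:start]:
            x = lyr.forward(x)
        feats.append(x)
    return np.concatenate(feats), start


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def _accuracy(model: Model, feats: np.ndarray, labels: np.ndarray, start: int,
              batch: int = 256) -> float:
    correct = 0
    for lo in range(0, len(feats), batch):
        logits = model.logits(feats[lo : lo + batch], start=start)
        correct += int((logits.argmax(axis=1) == labels[lo : lo + batch]).sum())
    return correct / len(feats)


def train(
    model: Model,
    train_set: LabeledImageSet,
    val_set: Optional[LabeledImageSet],
    config: TrainConfig,
) -> TrainTrace:
    """Minibatch SGD with a frozen first convolution layer.

    Weights must already be initialized (see :func:`initialize_weights`);
    conv1 is never updated.  Aborts with a diagnostic on NaN loss.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    labels = class_labels(train_set)
    feats, start = frozen_features(model, train_set)
    if feats.nbytes > config.max_cache_bytes:
        raise MemoryError(
            f"frozen feature cache of {feats.nbytes} bytes exceeds the "
            f"{config.max_cache_bytes}-byte limit; reduce the training set"
        )
    val_feats = val_labels = None
    if val_set is not None and len(val_set):
        val_labels = class_labels(val_set)
        val_feats, _ = frozen_features(model, val_set)

    rng = np.random.default_rng(config.seed)
    trainables = model.trainable_layers()
    trace = TrainTrace()
    n = len(feats)
    for it in range(1, config.iterations + 1):
        idx = rng.integers(0, n, config.batch_size)
        x, y = feats[idx], labels[idx]
        logits = model.logits(x, train=True, rng=rng, start=start)
        loss, dlogits = cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at iteration {it}; "
                "check the learning rate and input scaling"
            )
        model.backward(dlogits, start=start)
        for lyr in trainables:
            for p, g in zip(lyr.params(), lyr.grads()):
                p -= config.learning_rate * g
        if it % config.eval_interval == 0:
            trace.iteration.append(it)
            trace.loss.append(loss)
            trace.train_correct_rate.append(float((logits.argmax(axis=1) == y).mean()))
            trace.val_correct_rate.append(
                _accuracy(model, val_feats, val_labels, start)
                if val_feats is not None
                else np.nan
            )
    return trace


def evaluate_confusion(
    model: Model, test_set: LabeledImageSet, batch: int = 128
) -> tuple[ConfusionMatrix, float]:
    """Argmax classification of the test set into the 7 expressions.

    Rows of the returned matrix are true labels (normalized to sum to 1);
    the mean correct rate is the unweighted mean of the 7 diagonal rates.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    labels = class_labels(test_set)
    k = len(EXPRESSIONS)
    if len(np.unique(labels)) < k:
        missing = set(range(k)) - set(labels)
        raise ValueError(f"test set lacks expressions {[EXPRESSIONS[i] for i in missing]}")
    feats, start = frozen_features(model, test_set, batch=min(batch, 32))
    preds = np.concatenate(
        [
            model.logits(feats[lo : lo + batch], start=start).argmax(axis=1)
            for lo in range(0, len(feats), batch)
        ]
    )
    counts = np.zeros((k, k), np.int64)
    np.add.at(counts, (labels, preds), 1)
    rates = counts / counts.sum(axis=1, keepdims=True)
    cm = ConfusionMatrix(rates=rates, counts=counts)
    return cm, cm.mean_correct_rate
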