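"""Softmax classification head over precomputed bottleneck features.

Transfer learning for food recognition: a frozen convolutional network (e.g.
an Inception variant) reduces each image to a "bottleneck" feature vector,
and only a new linear + softmax output layer is trained on those vectors.
This module implements that retraining stage from scratch: stratified
train/validation/test splitting (80/10/10 by default), minibatch SGD on the
softmax cross-entropy loss with the analytic gradient (the backpropagation
update for a single linear layer), per-step loss/accuracy traces, and
evaluation.  The convolutional feature extractor itself is out of scope;
features are consumed from files or from the synthetic generator.

Cross-entropy is reported in nats.  Weights initialise to zero: the problem
is convex in (W, b), so the optimum does not depend on the start point and
training is deterministic given the sampling seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import IO, Optional, Sequence, Union

import numpy as np

from .errors import DomainError

DEFAULT_SPLIT_RATIOS = (0.8, 0.1, 0.1)
DEFAULT_STEPS = 4000
DEFAULT_BATCH_SIZE = 10
DEFAULT_LEARNING_RATE = 0.01
DEFAULT_EVAL_INTERVAL = 100

#: Probability floor applied before taking logs.
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class BottleneckDataset:
    """Feature matrix with integer class labels and class names."""

    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) ints in [0, C)
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise DomainError("features must be a 2-D matrix with d >= 1")
        if self.labels.shape != (self.features.shape[0],):
            raise DomainError("labels must align with feature rows")
        if not np.isfinite(self.features).all():
            raise DomainError("features contain non-finite values")
        c = len(self.class_names)
        if c < 1:
            raise DomainError("at least one class required")
        counts = np.bincount(self.labels, minlength=c)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= c:
            raise DomainError("labels out of range")
        if (counts == 0).any():
            raise DomainError("every class must be non-empty")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/validation/test index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class SoftmaxHead:
    """The trainable output layer: logits = W^T x + b."""

    W: np.ndarray  # (d, C)
    b: np.ndarray  # (C,)

    @classmethod
    def zeros(cls, n_features: int, n_classes: int) -> "SoftmaxHead":
        return cls(W=np.zeros((n_features, n_classes)), b=np.zeros(n_classes))

    def to_json(self, target: Union[str, IO[str], None] = None):
        doc = {
            "n_features": int(self.W.shape[0]),
            "n_classes": int(self.W.shape[1]),
            "W": self.W.ravel().tolist(),
            "b": self.b.tolist(),
        }
        if target is None:
            return doc
        text = json.dumps(doc)
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(text)
        return doc

    @classmethod
    def from_json(cls, source: Union[str, IO[str], dict]) -> "SoftmaxHead":
        if isinstance(source, dict):
            doc = source
        elif hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        d, c = doc["n_features"], doc["n_classes"]
        return cls(W=np.asarray(doc["W"]).reshape(d, c), b=np.asarray(doc["b"]))


@dataclass(frozen=True)
class TrainingTrace:
    """Per-step loss/accuracy records plus periodic validation accuracy."""

    steps: np.ndarray  # step index, 1-based
    batch_cross_entropy: np.ndarray
    train_accuracy: np.ndarray  # running mean of batch accuracies
    validation_steps: np.ndarray
    validation_accuracy: np.ndarray

    def __len__(self) -> int:
        return len(self.steps)


def split_dataset(
    ds: BottleneckDataset,
    ratios: Sequence[float] = DEFAULT_SPLIT_RATIOS,
    seed: int = 0,
) -> SplitIndices:
    """Stratified shuffle split into train/validation/test.

    Per class: indices are shuffled with the seeded generator, then
    floor(r_train * n_c) go to train, floor(r_val * n_c) to validation, and
    the remainder to test.  The three sets are disjoint and cover the data.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise DomainError("ratios must be three non-negative numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise DomainError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in range(ds.n_classes):
        idx = np.flatnonzero(ds.labels == c)
        rng.shuffle(idx)
        n_c = len(idx)
        n_train = int(ratios[0] * n_c)
        n_val = int(ratios[1] * n_c)
        if (ratios[0] > 0 and n_train == 0) or (ratios[1] > 0 and n_val == 0) or (
            ratios[2] > 0 and n_c - n_train - n_val == 0
        ):
            warnings.warn(
                f"class {c}: only {n_c} samples, a requested split is empty",
                stacklevel=2,
            )
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return SplitIndices(
        train=np.concatenate(train),
        validation=np.concatenate(val),
        test=np.concatenate(test),
    )


def softmax_forward(head: SoftmaxHead, x: np.ndarray) -> np.ndarray:
    """Class probabilities softmax(W^T x + b), max-shifted for stability.

    Accepts a single feature vector (d,) or a batch (n, d); returns the
    matching (C,) or (n, C) probabilities.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise DomainError("non-finite input features")
    logits = x @ head.W + head.b
    shifted = logits - logits.max(axis=-1, keepdims=True)
    expv = np.exp(shifted)
    return expv / expv.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, label: int) -> float:
    """-ln p[label] in nats, with p clipped to >= 1e-12 before the log."""
    p = np.asarray(p, dtype=float)
    if label < 0 or label >= p.shape[-1]:
        raise DomainError("label out of range")
    return float(-np.log(max(p[label], PROB_CLIP)))


def batch_cross_entropy(p: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of a (n, C) probability batch."""
    picked = np.clip(p[np.arange(len(labels)), labels], PROB_CLIP, None)
    return float(-np.log(picked).mean())


def sgd_step(
    head: SoftmaxHead,
    x: np.ndarray,
    labels: np.ndarray,
    learning_rate: float = DEFAULT_LEARNING_RATE,
) -> float:
    """One minibatch gradient step on mean cross-entropy; returns the loss.

    The analytic softmax-CE gradient is dL/dlogits = p - onehot averaged over
    the batch, backpropagated into W and b.  Updates `head` in place.
    """
    if learning_rate <= 0:
        raise DomainError("learning rate must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    if len(labels) == 0:
        raise DomainError("empty minibatch")
    p = softmax_forward(head, x)
    loss = batch_cross_entropy(p, labels)
    delta = p.copy()
    delta[np.arange(len(labels)), labels] -= 1.0
    delta /= len(labels)
    head.W -= learning_rate * (x.T @ delta)
    head.b -= learning_rate * delta.sum(axis=0)
    return loss


def evaluate(
    head: SoftmaxHead, ds: BottleneckDataset, indices: np.ndarray
) -> tuple[float, float]:
    """(accuracy, mean cross-entropy) of the head over an index set."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise DomainError("empty evaluation set")
    p = softmax_forward(head, ds.features[indices])
    labels = ds.labels[indices]
    accuracy = float((p.argmax(axis=1) == labels).mean())
    return accuracy, batch_cross_entropy(p, labels)


def train(
    ds: BottleneckDataset,
    split: SplitIndices,
    steps: int = DEFAULT_STEPS,
    batch_size: int = DEFAULT_BATCH_SIZE,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    eval_interval: int = DEFAULT_EVAL_INTERVAL,
) -> tuple[SoftmaxHead, TrainingTrace]:
    """Train a fresh zero-initialised head by minibatch SGD.

    Each step samples `batch_size` training indices with replacement from the
    seeded generator, applies one gradient step, and records the batch loss
    and a running training accuracy; validation accuracy is recorded every
    `eval_interval` steps (and after the final step).
    """
    if steps < 1:
        raise DomainError("steps must be >= 1")
    if batch_size < 1:
        raise DomainError("batch size must be >= 1")
    if split.train.size == 0:
        raise DomainError("empty training split")
    rng = np.random.default_rng(seed)
    head = SoftmaxHead.zeros(ds.n_features, ds.n_classes)
    losses = np.empty(steps)
    train_acc = np.empty(steps)
    val_steps, val_acc = [], []
    correct = 0
    for step in range(1, steps + 1):
        batch_idx = rng.choice(split.train, size=batch_size, replace=True)
        x, y = ds.features[batch_idx], ds.labels[batch_idx]
        p = softmax_forward(head, x)
        correct += int((p.argmax(axis=1) == y).sum())
        losses[step - 1] = sgd_step(head, x, y, learning_rate)
        train_acc[step - 1] = correct / (step * batch_size)
        if split.validation.size and (step % eval_interval == 0 or step == steps):
            acc, _ = evaluate(head, ds, split.validation)
            val_steps.append(step)
            val_acc.append(acc)
    return head, TrainingTrace(
        steps=np.arange(1, steps + 1),
        batch_cross_entropy=losses,
        train_accuracy=train_acc,
        validation_steps=np.asarray(val_steps),
        validation_accuracy=np.asarray(val_acc),
    )


def classify(
    head: SoftmaxHead,
    class_names: Sequence[str],
    x: np.ndarray,
    recommendation_map: Optional[dict[str, bool]] = None,
) -> dict:
    """Predict a label with its confidence and a dietary recommendation flag.

    The recommendation map sends label -> True (recommended for a diabetic
    diet) or False; labels absent from the map get flag ``"unknown"``.
    """
    p = softmax_forward(head, np.asarray(x, dtype=float))
    if p.ndim != 1:
        raise DomainError("classify expects a single feature vector")
    idx = int(p.argmax())
    label = class_names[idx]
    confidence = float(p[idx])
    if recommendation_map is None or label not in recommendation_map:
        flag = "unknown"
    else:
        flag = "recommended" if recommendation_map[label] else "not_recommended"
    return {
        "label": label,
        "confidence": confidence,
        "confidence_pct": f"{100 * confidence:.2f}%",
        "recommendation": flag,
    }


def load_feature_file(
    source: Union[str, IO[str]],
    class_names: Optional[Sequence[str]] = None,
    delimiter: str = ",",
) -> BottleneckDataset:
    """Read a delimited numeric matrix, last column = integer label."""
    data = np.loadtxt(source, delimiter=delimiter, ndmin=2)
    if data.shape[1] < 2:
        raise DomainError("feature file needs at least one feature column plus labels")
    features = data[:, :-1]
    labels = data[:, -1].astype(int)
    if not np.allclose(data[:, -1], labels):
        raise DomainError("label column must hold integers")
    if class_names is None:
        class_names = tuple(f"class_{c}" for c in range(labels.max() + 1))
    return BottleneckDataset(
        features=features, labels=labels, class_names=tuple(class_names)
    )


def save_feature_file(
    ds: BottleneckDataset, target: Union[str, IO[str]], delimiter: str = ","
) -> None:
    """Write features with the label appended as the last column."""
    data = np.column_stack([ds.features, ds.labels])
    fmt = ["%.10g"] * ds.n_features + ["%d"]
    np.savetxt(target, data, delimiter=delimiter, fmt=fmt)
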