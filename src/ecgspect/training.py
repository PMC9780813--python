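"""Training loop (Adam + binary cross-entropy) and evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import SmallCnn
from .dataset import LabeledImage

__all__ = ["TrainConfig", "EvalMetrics", "train_model", "evaluate_model"]

POSITIVE_CLASS = "ASMI"


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults mirror the documented full-scale run (lr 0.001, batch 256,
    500 epochs, 10 steps per epoch); tests and examples pass scaled-down
    values.  ``steps_per_epoch=None`` means one full pass per epoch.
    """

    learning_rate: float = 0.001
    batch_size: int = 256
    epochs: int = 500
    steps_per_epoch: int | None = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")
        if self.steps_per_epoch is not None and self.steps_per_epoch < 1:
            raise ValueError("steps per epoch must be >= 1")


@dataclass
class EvalMetrics:
    """Validation metrics; ratios with empty denominators are None."""

    accuracy: float
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    loss: float | None
    tp: int
    fp: int
    tn: int
    fn: int


def _to_arrays(items) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of LabeledImage or an (X, y) pair."""
    if isinstance(items, tuple):
        x, y = items
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.float32)
    if not items:
        raise ValueError("empty image set")
    if not isinstance(items[0], LabeledImage):
        raise TypeError("expected LabeledImage items or an (X, y) tuple")
    x = np.stack([it.image for it in items]).astype(np.float32) / 255.0
    y = np.array(
        [1.0 if it.label == POSITIVE_CLASS else 0.0 for it in items],
        dtype=np.float32,
    )
    return x, y


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def train_model(
    model: SmallCnn,
    train_items,
    val_items,
    config: TrainConfig | None = None,
) -> tuple[pd.DataFrame, EvalMetrics]:
    """Train in place and evaluate on the validation set.

    ``train_items``/``val_items`` are lists of :class:`LabeledImage`
    (pixels are scaled to [0, 1], ASMI is the positive class) or ``(X, y)``
    arrays.  Shuffling and dropout are driven by ``config.seed``; equal
    seeds and data give identical results.

    Returns a per-epoch history (``epoch``, ``loss``, ``val_accuracy``)
    and the final :class:`EvalMetrics` at threshold 0.5.
    """
    config = config or TrainConfig()
    x_train, y_train = _to_arrays(train_items)
    x_val, y_val = _to_arrays(val_items)
    expected = model.spec.input_size
    for name, arr in (("train", x_train), ("validation", x_val)):
        if arr.shape[1:3] != expected:
            raise ValueError(
                f"{name} images of shape {arr.shape[1:3]} do not match the "
                f"model input {expected}"
            )
    for name, arr in (("train", y_train), ("validation", y_val)):
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"{name} labels must be binary")

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters, config.learning_rate)
    n = len(x_train)
    steps = config.steps_per_epoch or max(1, int(np.ceil(n / config.batch_size)))
    order = rng.permutation(n)
    cursor = 0
    history = []
    for epoch in range(config.epochs):
        losses = []
        for _ in range(steps):
            if cursor + config.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            take = min(config.batch_size, n)
            idx = order[cursor : cursor + take]
            cursor += take
            loss, grads = model.loss_and_gradients(
                x_train[idx], y_train[idx], rng=rng
            )
            model.set_parameters(opt.step(model.parameters, grads))
            losses.append(loss)
        val_probs = model.predict_proba(x_val)
        val_acc = float(np.mean((val_probs >= 0.5) == (y_val == 1.0)))
        history.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
            }
        )
    probs = model.predict_proba(x_val)
    metrics = evaluate_model(probs, y_val)
    eps = 1e-12
    metrics.loss = float(
        -np.mean(y_val * np.log(probs + eps) + (1 - y_val) * np.log(1 - probs + eps))
    )
    return pd.DataFrame(history), metrics


def evaluate_model(predictions: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> EvalMetrics:
    """Confusion-matrix metrics from probabilities and binary labels.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP), precision = TP/(TP+FP); a ratio with a zero denominator is
    reported as None rather than 0.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"got {len(predictions)} predictions for {len(labels)} labels"
        )
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    pred = predictions >= threshold
    pos = labels == 1.0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return EvalMetrics(
        accuracy=(tp + tn) / len(labels),
        precision=ratio(tp, tp + fp),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        loss=None,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
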