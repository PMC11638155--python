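"""Training protocol and evaluation metrics.

Full-batch Adam on unweighted cross-entropy for a fixed number of epochs
(default 100).  Training is transductive for the graph models: the forward
pass propagates over every node, but the loss is computed on
training-partition nodes only.  A grid search over learning rate and weight
decay retrains from the same seeded initialization for every combination and
selects by final-epoch validation accuracy (ties: weighted PPV, then the
smaller weight decay, then the smaller learning rate).

Metrics follow clinical reporting: per-class PPV (precision) and recall, plus
support-weighted aggregates.  Support-weighted recall is algebraically the
overall accuracy; the evaluator asserts that identity on every call.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .models import ModelSpec, forward, init_params

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EvalReport",
    "AdamState",
    "adam_step",
    "train_model",
    "grid_search",
    "evaluate",
    "confusion_matrix",
    "DEFAULT_GRID",
]

CLASS_NAMES = ("Control", "MCI", "AD")

# lr x wd grid; contains both winning study configurations
# (0.01, 0.0001) and (0.01, 0.0005).
DEFAULT_GRID = {
    "learning_rate": (0.1, 0.01, 0.001),
    "weight_decay": (0.0005, 0.0001, 0.00001),
}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    weight_decay: float = 0.0001
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_weighted_ppv: list[float] = field(default_factory=list)
    val_weighted_recall: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs,
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "val_wppv": self.val_weighted_ppv,
            "val_wrecall": self.val_weighted_recall,
        })


@dataclass
class EvalReport:
    confusion: np.ndarray            # rows = true class, cols = predicted
    accuracy: float
    weighted_ppv: float
    weighted_recall: float
    per_class_ppv: np.ndarray
    per_class_recall: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "weighted_ppv": self.weighted_ppv,
            "weighted_recall": self.weighted_recall,
            "per_class": {
                name: {"ppv": float(self.per_class_ppv[k]),
                       "recall": float(self.per_class_recall[k])}
                for k, name in enumerate(CLASS_NAMES)
            },
            "confusion_matrix": self.confusion.astype(int).tolist(),
        }


def confusion_matrix(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    """Counts: entry (r, c) = number of true-r subjects predicted c."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _report_from_confusion(cm: np.ndarray) -> EvalReport:
    n = int(cm.sum())
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    tp = np.diag(cm).astype(float)
    ppv = np.zeros(cm.shape[0])
    recall = np.zeros(cm.shape[0])
    for k in range(cm.shape[0]):
        if predicted[k] > 0:
            ppv[k] = tp[k] / predicted[k]
        elif support[k] > 0:
            warnings.warn(
                f"class {CLASS_NAMES[k]} never predicted; PPV defined as 0",
                stacklevel=3,
            )
        if support[k] > 0:
            recall[k] = tp[k] / support[k]
    accuracy = float(tp.sum() / n) if n else 0.0
    w = support / n if n else np.zeros_like(support, dtype=float)
    weighted_ppv = float((w * ppv).sum())
    weighted_recall = float((w * recall).sum())
    # Support-weighted recall is accuracy by construction; assert the identity.
    assert abs(weighted_recall - accuracy) < 1e-12
    return EvalReport(confusion=cm, accuracy=accuracy, weighted_ppv=weighted_ppv,
                      weighted_recall=weighted_recall, per_class_ppv=ppv,
                      per_class_recall=recall, n=n)


def evaluate_predictions(y_true, y_pred, n_classes: int = 3) -> EvalReport:
    return _report_from_confusion(confusion_matrix(y_true, y_pred, n_classes))


def evaluate(params: dict, spec: ModelSpec, x: np.ndarray,
             edge_index: np.ndarray | None, labels: np.ndarray,
             idx: np.ndarray) -> EvalReport:
    """Deterministic evaluation-mode metrics on the subset ``idx``."""
    idx = np.asarray(idx)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("evaluation partition is empty")
    logits = forward(spec, x, edge_index, params, training=False)
    preds = logits.data.argmax(axis=1)
    return evaluate_predictions(np.asarray(labels)[idx], preds[idx],
                                spec.n_classes)


@dataclass
class AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def init(cls, params: dict[str, np.ndarray]) -> "AdamState":
        return cls(m={k: np.zeros_like(v) for k, v in params.items()},
                   v={k: np.zeros_like(v) for k, v in params.items()})


def adam_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
              state: AdamState, lr: float, weight_decay: float = 0.0,
              beta1: float = 0.9, beta2: float = 0.999,
              eps: float = 1e-8) -> None:
    """One in-place Adam update (L2 weight decay added to the gradient)."""
    state.t += 1
    t = state.t
    for k, p in params.items():
        g = grads[k] + weight_decay * p
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * g * g
        m_hat = state.m[k] / (1 - beta1 ** t)
        v_hat = state.v[k] / (1 - beta2 ** t)
        p -= lr * m_hat / (np.sqrt(v_hat) + eps)


def train_model(spec: ModelSpec, params: dict[str, np.ndarray],
                x: np.ndarray, edge_index: np.ndarray | None,
                labels: np.ndarray, train_idx: np.ndarray,
                val_idx: np.ndarray, config: TrainConfig,
                ) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Full-batch Adam training with per-epoch validation tracking.

    Mutates a copy of ``params`` (the input dict is left untouched) and is
    deterministic under a fixed ``config.seed`` (which drives dropout).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= spec.n_classes):
        raise ValueError("labels outside class range")
    train_idx = np.asarray(train_idx)
    if train_idx.dtype == bool:
        train_idx = np.flatnonzero(train_idx)
    if train_idx.size == 0:
        raise ValueError("training partition is empty")
    val_idx = np.asarray(val_idx)
    if val_idx.dtype == bool:
        val_idx = np.flatnonzero(val_idx)
    params = {k: np.array(v, dtype=float) for k, v in params.items()}
    state = AdamState.init(params)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    for epoch in range(1, config.epochs + 1):
        tensors = {k: ad.Tensor(v, requires_grad=True) for k, v in params.items()}
        logits = forward(spec, x, edge_index, tensors, training=True, rng=rng)
        loss = ad.cross_entropy_with_logits(logits, labels, train_idx)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}")
        loss.backward()
        grads = {k: t.grad for k, t in tensors.items()}
        adam_step(params, grads, state, config.learning_rate,
                  config.weight_decay)
        history.epochs.append(epoch)
        history.train_loss.append(float(loss.data))
        if val_idx.size:
            eval_logits = forward(spec, x, edge_index, params, training=False)
            vloss = ad.cross_entropy_with_logits(eval_logits, labels, val_idx)
            report = evaluate(params, spec, x, edge_index, labels, val_idx)
            history.val_loss.append(float(vloss.data))
            history.val_accuracy.append(report.accuracy)
            history.val_weighted_ppv.append(report.weighted_ppv)
            history.val_weighted_recall.append(report.weighted_recall)
        else:
            history.val_loss.append(float("nan"))
            history.val_accuracy.append(float("nan"))
            history.val_weighted_ppv.append(float("nan"))
            history.val_weighted_recall.append(float("nan"))
    return params, history


def grid_search(spec: ModelSpec, x: np.ndarray,
                edge_index: np.ndarray | None, labels: np.ndarray,
                train_idx: np.ndarray, val_idx: np.ndarray,
                grid: dict | None = None, epochs: int = 100, seed: int = 0,
                ) -> tuple[TrainConfig, dict[str, np.ndarray],
                           dict[tuple, TrainHistory]]:
    """Exhaustive (lr, wd) search selected on final-epoch validation accuracy.

    Every combination starts from the same seeded initialization.  Returns the
    winning config, its trained parameters, and all histories keyed (lr, wd).
    """
    grid = grid or DEFAULT_GRID
    lrs, wds = grid["learning_rate"], grid["weight_decay"]
    if not lrs or not wds:
        raise ValueError("grid must be non-empty")
    init = init_params(spec, seed=seed)
    results = {}
    histories: dict[tuple, TrainHistory] = {}
    for lr, wd in itertools.product(lrs, wds):
        config = TrainConfig(learning_rate=lr, weight_decay=wd,
                             epochs=epochs, seed=seed)
        trained, hist = train_model(spec, init, x, edge_index, labels,
                                    train_idx, val_idx, config)
        histories[(lr, wd)] = hist
        results[(lr, wd)] = (hist.val_accuracy[-1], hist.val_weighted_ppv[-1],
                             trained, config)
    # argmax by accuracy, then wPPV, then smaller wd, then smaller lr
    best_key = max(
        results,
        key=lambda k: (results[k][0], results[k][1], -k[1], -k[0]))
    _, _, best_params, best_config = results[best_key]
    return best_config, best_params, histories
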