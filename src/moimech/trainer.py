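"""Multi-label training loop, hyperparameter grid, metrics and class rules.

Both tasks are optimized with binary cross-entropy over sigmoid outputs
(each label an independent Bernoulli), Adam with weight decay 5e-4, a
ReduceLROnPlateau schedule on validation loss, and early stopping that
restores the best-validation-loss parameters.  The hyperparameter grid
crosses five hidden sizes (128, 64, 32, 16, 8) with five learning rates
spanning 1e-2 to 5e-4, i.e. 25 configurations, selected by validation F1.

Metrics are per-label precision/recall/F1 macro-averaged over labels; a
label with neither positive truth nor positive prediction counts as 1.0
(nothing to get wrong).  The benchmark mode-of-inheritance rule converts a
dominant-probability into AD (> 0.6), AR (< 0.4) or ADAR (otherwise); the
inference rule uses both per-label probabilities at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autodiff import Tensor, bce_with_logits
from .gnn import GNNModel
from .graphs import AttributedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "PredictionSet", "NodeTaskData", "GraphTaskData",
    "Adam", "PlateauScheduler", "EarlyStopper",
    "train_model", "grid_search", "evaluate", "assign_moi_class",
]


@dataclass
class TrainConfig:
    hidden_sizes: tuple[int, ...] = (128, 64, 32, 16, 8)
    learning_rates: tuple[float, ...] = (1e-2, 5e-3, 2e-3, 1e-3, 5e-4)
    learning_rate: float = 1e-2  # used by train_model for a single fit
    hidden_size: int = 16
    weight_decay: float = 5e-4
    dropout: float = 0.3
    max_epochs: int = 100
    patience: int = 30
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes or not self.learning_rates:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class PredictionSet:
    ids: list[str]
    probs: np.ndarray  # (n, labels) in [0, 1]
    label_names: list[str]
    y_true: np.ndarray | None = None  # binary (n, labels)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true)
            if self.y_true.shape != self.probs.shape:
                raise ValueError("label matrix shape mismatch")


@dataclass
class NodeTaskData:
    """Transductive node classification: one graph, index masks per split."""

    graph: AttributedGraph
    y: np.ndarray  # (nodes, labels)
    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray | None = None


@dataclass
class GraphTaskData:
    """Graph classification: labelled graphs per split."""

    train: list[AttributedGraph]
    valid: list[AttributedGraph]
    test: list[AttributedGraph] = field(default_factory=list)


class Adam:
    """Adam with decoupled-from-nothing L2: weight decay is added to the
    gradient, matching the common framework behaviour."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Multiply the LR by `factor` after `patience` epochs without
    validation-loss improvement."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float):
        if metric < self.best:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


class EarlyStopper:
    """Stop after `patience` consecutive epochs without improvement and
    remember which epoch was best."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, epoch: int, metric: float) -> bool:
        """Record the epoch's validation metric; True means stop now."""
        if metric < self.best:
            self.best = metric
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _epoch_losses(model: GNNModel, data, training: bool):
    """(train_loss_tensor, valid_loss_float) for one epoch's forward passes."""
    if isinstance(data, NodeTaskData):
        adj = data.graph.adjacency()
        logits = model.forward(data.graph.X, adj, training=training)
        loss = bce_with_logits(logits.take_rows(data.train_idx), data.y[data.train_idx])
        val_logits = model.forward(data.graph.X, adj, training=False)
        val = bce_with_logits(val_logits.take_rows(data.valid_idx), data.y[data.valid_idx])
        return loss, float(val.data)
    # graph task: average per-graph loss
    losses = []
    for g in data.train:
        logits = model.forward(g.X, g.adjacency(), training=training)
        losses.append(bce_with_logits(logits, g.y.reshape(1, -1)))
    loss = losses[0]
    for l in losses[1:]:
        loss = loss + l
    loss = loss * (1.0 / len(losses))
    val_vals = []
    for g in data.valid:
        logits = model.forward(g.X, g.adjacency(), training=False)
        val_vals.append(float(bce_with_logits(logits, g.y.reshape(1, -1)).data))
    return loss, float(np.mean(val_vals))


def train_model(model: GNNModel, data, config: TrainConfig) -> dict:
    """Fit with Adam + BCE; early-stop on validation loss; restore best.

    Returns a history dict with per-epoch train/valid loss and learning
    rate, plus the best epoch index (0-based).
    """
    if isinstance(data, NodeTaskData):
        if len(data.valid_idx) == 0:
            raise ValueError("empty validation set")
        if set(data.train_idx) & set(data.valid_idx):
            raise ValueError("train and validation indices overlap")
    elif not data.valid:
        raise ValueError("empty validation set")
    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay)
    sched = PlateauScheduler(opt, config.scheduler_factor, config.scheduler_patience)
    stopper = EarlyStopper(config.patience)
    history = {"train_loss": [], "valid_loss": [], "lr": []}
    best_params = [p.data.copy() for p in model.parameters()]
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        loss, val = _epoch_losses(model, data, training=True)
        if not np.isfinite(loss.data) or not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: train={float(loss.data)}, valid={val}"
            )
        loss.backward()
        opt.step()
        history["train_loss"].append(float(loss.data))
        history["valid_loss"].append(val)
        history["lr"].append(opt.lr)
        improved = val < stopper.best
        stop = stopper.update(epoch, val)
        if improved:
            best_params = [p.data.copy() for p in model.parameters()]
        sched.step(val)
        if stop:
            break
    for p, best in zip(model.parameters(), best_params):
        p.data = best
    history["best_epoch"] = stopper.best_epoch
    history["best_valid_loss"] = float(stopper.best)
    return history


def _make_model(arch: str, data, hidden: int, config: TrainConfig, n_labels: int) -> GNNModel:
    if isinstance(data, NodeTaskData):
        return GNNModel(arch, data.graph.X.shape[1], hidden, n_labels, "node",
                        dropout=config.dropout, seed=config.seed)
    return GNNModel(arch, data.train[0].X.shape[1], hidden, n_labels, "graph",
                    dropout=config.dropout, seed=config.seed)


def _validation_predictions(model: GNNModel, data) -> PredictionSet:
    if isinstance(data, NodeTaskData):
        probs = model.predict_proba(data.graph.X, data.graph.adjacency())[data.valid_idx]
        ids = [data.graph.node_ids[i] for i in data.valid_idx]
        names = data.graph.label_names or [f"label{k}" for k in range(probs.shape[1])]
        return PredictionSet(ids, probs, list(names), data.y[data.valid_idx])
    probs = np.vstack([model.predict_proba(g.X, g.adjacency()) for g in data.valid])
    y = np.vstack([g.y.reshape(1, -1) for g in data.valid])
    names = data.valid[0].label_names or [f"label{k}" for k in range(probs.shape[1])]
    ids = [g.node_ids[0] for g in data.valid]
    return PredictionSet(ids, probs, list(names), y)


def grid_search(arch: str, data, config: TrainConfig, n_labels: int):
    """Train one model per (hidden size, learning rate) cell.

    Returns ``(best_model, best_row, table)``; the table has exactly one row
    per grid cell with validation loss and validation macro-F1.  The winner
    has the highest validation F1, ties broken by lower validation loss,
    then smaller hidden size.  Failed cells are kept in the table with NaN
    metrics; if every cell fails, an error is raised.
    """
    rows = []
    best = None
    for hidden in config.hidden_sizes:
        for lr in config.learning_rates:
            cell = replace(config, hidden_size=hidden, learning_rate=lr)
            try:
                model = _make_model(arch, data, hidden, cell, n_labels)
                history = train_model(model, data, cell)
                preds = _validation_predictions(model, data)
                metrics = evaluate(preds)
                row = {"hidden_size": hidden, "learning_rate": lr,
                       "valid_loss": history["best_valid_loss"],
                       "valid_f1": metrics["F1"], "failed": False}
                key = (-row["valid_f1"], row["valid_loss"], hidden)
                if best is None or key < best[0]:
                    best = (key, model, row)
            except (FloatingPointError, ValueError) as err:
                logger.warning("grid cell (%d, %g) failed: %s", hidden, lr, err)
                row = {"hidden_size": hidden, "learning_rate": lr,
                       "valid_loss": np.nan, "valid_f1": np.nan, "failed": True}
            rows.append(row)
    if best is None:
        raise RuntimeError("every grid cell failed")
    return best[1], best[2], pd.DataFrame(rows)


def evaluate(preds: PredictionSet, threshold: float = 0.5) -> dict:
    """Macro-averaged F1 / precision / recall at a binarization threshold.

    Per label: if neither truth nor prediction contains a positive, that
    label scores 1.0 on all three metrics; otherwise empty denominators
    score 0.
    """
    if preds.y_true is None:
        raise ValueError("evaluate requires true labels")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    yhat = (preds.probs >= threshold).astype(int)
    y = preds.y_true.astype(int)
    per_label = {"precision": [], "recall": [], "F1": []}
    for k in range(y.shape[1]):
        tp = int(np.sum((y[:, k] == 1) & (yhat[:, k] == 1)))
        fp = int(np.sum((y[:, k] == 0) & (yhat[:, k] == 1)))
        fn = int(np.sum((y[:, k] == 1) & (yhat[:, k] == 0)))
        if tp == fp == fn == 0:
            p = r = f = 1.0
        else:
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
        per_label["precision"].append(p)
        per_label["recall"].append(r)
        per_label["F1"].append(f)
    return {m: float(np.mean(v)) for m, v in per_label.items()}


def assign_moi_class(p_ad: float, p_ar: float | None = None, rule: str = "benchmark") -> str:
    """Mode-of-inheritance call from per-label probabilities.

    ``benchmark``: AD if p_AD > 0.6, AR if p_AD < 0.4, else ADAR (the rule
    used when scoring a dominant-probability baseline).  ``inference``: both
    labels at 0.5 — AD only, AR only, ADAR when both clear it, otherwise
    the larger of the two.
    """
    if not (0 <= p_ad <= 1) or (p_ar is not None and not (0 <= p_ar <= 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if rule == "benchmark":
        if p_ad > 0.6:
            return "AD"
        if p_ad < 0.4:
            return "AR"
        return "ADAR"
    if rule == "inference":
        if p_ar is None:
            raise ValueError("inference rule needs both probabilities")
        ad, ar = p_ad >= 0.5, p_ar >= 0.5
        if ad and ar:
            return "ADAR"
        if ad:
            return "AD"
        if ar:
            return "AR"
        return "AD" if p_ad >= p_ar else "AR"
    raise ValueError(f"unknown rule {rule!r}")
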