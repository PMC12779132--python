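"""Mini-batch training with the joint multi-task objective.

The optimizer is adaptive moment estimation (Adam) on the weighted sum
of the coding cross-entropy, the cross-modal InfoNCE contrastive loss
and the severity cross-entropy.  Training early-stops when validation
subset accuracy fails to improve for ``patience`` epochs and restores
the best-epoch parameters.  Every random draw (init, shuffling) is
driven by the configured seed, so a fixed seed reproduces the run
exactly under single-threaded execution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .lora import (MultiTaskObjective, TaskSpec, contrastive_loss,
                   cross_entropy, severity_loss, total_loss)
from .metrics import subset_accuracy
from .model import CodingNetwork
from .records import CaseRecord, severity_index
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "train", "predict_labels"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0
    lambda_contrastive: float = 0.3
    lambda_severity: float = 0.3
    temperature: float = 0.1
    multi_label: bool = False

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -np.inf
    stop_reason: str = ""

    def append(self, row: dict) -> None:
        self.epochs.append(row)


def _objective(cfg: TrainConfig, use_mtl: bool) -> MultiTaskObjective:
    lam_c = cfg.lambda_contrastive if use_mtl else 0.0
    lam_s = cfg.lambda_severity if use_mtl else 0.0
    return MultiTaskObjective((
        TaskSpec("coding", 1.0),
        TaskSpec("contrastive", lam_c, "info_nce"),
        TaskSpec("severity", lam_s),
    ))


def _binary_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise sigmoid BCE, numerically stable, mean over entries."""
    y = Tensor(np.asarray(targets, dtype=np.float64))
    absx = logits.relu() + (-logits).relu()
    # max(x,0) - x*y + log(1 + exp(-|x|))
    loss = logits.relu() - logits * y + ((-absx).exp() + 1.0).log()
    return loss.mean()


def _coding_loss(logits: Tensor, records: list[CaseRecord],
                 multi_label: bool) -> Tensor:
    labels = np.stack([r.labels for r in records])
    if multi_label:
        return _binary_cross_entropy(logits, labels)
    return cross_entropy(logits, labels.argmax(axis=1))


def _batch_loss(network: CodingNetwork, records: list[CaseRecord],
                cfg: TrainConfig, objective: MultiTaskObjective):
    logits, sev_logits, views = network.forward(records)
    weights = objective.weights
    losses: dict[str, Tensor | float] = {
        "coding": _coding_loss(logits, records, cfg.multi_label)}
    if weights.get("contrastive", 0.0) > 0 and len(views) >= 2 and len(records) >= 2:
        losses["contrastive"] = contrastive_loss(
            list(views.values()), temperature=cfg.temperature)
    else:
        losses["contrastive"] = 0.0
    if weights.get("severity", 0.0) > 0:
        sev = np.asarray([severity_index(r.severity) for r in records])
        losses["severity"] = severity_loss(sev_logits, sev)
    else:
        losses["severity"] = 0.0
    return total_loss(objective, losses), losses


def predict_labels(network: CodingNetwork, records: list[CaseRecord],
                   multi_label: bool = False,
                   threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Scores and hard label matrix (argmax one-hot, or thresholded)."""
    scores = network.predict_scores(records)
    if multi_label:
        return scores, (scores >= threshold).astype(np.int64)
    yhat = np.zeros_like(scores, dtype=np.int64)
    yhat[np.arange(len(records)), scores.argmax(axis=1)] = 1
    return scores, yhat


def _validation_accuracy(network: CodingNetwork, records: list[CaseRecord],
                         multi_label: bool) -> float:
    truth = np.stack([r.labels for r in records])
    _, yhat = predict_labels(network, records, multi_label)
    return subset_accuracy(truth, yhat)


def _signature_batches(records: list[CaseRecord], order: np.ndarray,
                       batch_size: int):
    """Yield seeded mini-batches, each homogeneous in modality signature."""
    by_sig: dict[tuple, list[int]] = {}
    for i in order:
        by_sig.setdefault(records[i].modality_signature, []).append(i)
    for idx_list in by_sig.values():
        for lo in range(0, len(idx_list), batch_size):
            yield [records[i] for i in idx_list[lo:lo + batch_size]]


def train(network: CodingNetwork, dataset: SyntheticDataset,
          cfg: TrainConfig) -> TrainHistory:
    """Optimize the joint objective; early-stop on validation subset accuracy."""
    train_records = dataset.split("train")
    val_records = dataset.split("val")
    if not train_records or not val_records:
        raise ValueError("dataset must provide non-empty train and val splits")
    objective = _objective(cfg, network.config.use_mtl)
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(network.parameters(), lr=cfg.learning_rate)
    logger.info("training start: %d train / %d val records, config=%s",
                len(train_records), len(val_records), cfg)

    history = TrainHistory()
    best_state = network.state()
    epochs_since_best = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_records))
        sums = {"total": 0.0, "coding": 0.0, "contrastive": 0.0, "severity": 0.0}
        n_batches = 0
        for batch in _signature_batches(train_records, order, cfg.batch_size):
            optimizer.zero_grad()
            loss, parts = _batch_loss(network, batch, cfg, objective)
            loss.backward()
            optimizer.step()
            sums["total"] += float(loss.data)
            for name in ("coding", "contrastive", "severity"):
                term = parts[name]
                sums[name] += float(term.data) if isinstance(term, Tensor) else term
            n_batches += 1
        val_acc = _validation_accuracy(network, val_records, cfg.multi_label)
        row = {"epoch": epoch,
               **{k: v / max(n_batches, 1) for k, v in sums.items()},
               "val_subset_accuracy": val_acc}
        history.append(row)
        logger.info("epoch %d: loss=%.4f val_subset_accuracy=%.4f",
                    epoch, row["total"], val_acc)
        if val_acc > history.best_val_accuracy:
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_state = network.state()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                history.stop_reason = "early_stop"
                break
    if not history.stop_reason:
        history.stop_reason = "max_epochs"
    network.load_state(best_state)
    return history
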