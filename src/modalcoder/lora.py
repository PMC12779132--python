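"""Low-rank adaptation and the weighted multi-task objective.

A LoRA adapter keeps a frozen base weight ``W0`` and learns a rank-r
update ``dW = B @ A`` (``B`` zero-initialized, ``A`` random), so the
adapted map ``h = W0 x + B (A x)`` equals the base map exactly at
initialization and trains only ``r (d_in + d_out)`` parameters.  The
update is applied factor-by-factor; ``dW`` is never materialized in the
forward pass.  :func:`merge_adapter` folds ``B @ A`` into ``W0`` for
inference.

The multi-task objective combines the primary coding loss with two
auxiliary tasks — a symmetric InfoNCE contrastive loss that aligns
per-modality embeddings of the same case, and a 3-class severity
cross-entropy — as a weighted sum ``sum_k lambda_k L_k`` over shared
parameters.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, log_softmax
from .layers import Linear

__all__ = [
    "LoRAAdapter", "LoRALinear", "lora_forward", "merge_adapter",
    "TaskSpec", "MultiTaskObjective", "contrastive_loss", "severity_loss",
    "total_loss", "save_adapters", "load_adapters",
]


@dataclass
class LoRAAdapter:
    """Frozen base ``W0`` (d_out x d_in) plus trainable factors ``B, A``."""

    W0: np.ndarray
    B_lr: Tensor
    A_lr: Tensor
    rank: int

    @classmethod
    def create(cls, W0: np.ndarray, rank: int, rng: np.random.Generator,
               init_scale: float | None = None) -> "LoRAAdapter":
        W0 = np.asarray(W0, dtype=np.float64)
        d_out, d_in = W0.shape
        if rank < 1 or rank >= min(d_in, d_out):
            raise ValueError("rank must satisfy 1 <= r < min(d_in, d_out)")
        if init_scale is None:
            init_scale = 1.0 / np.sqrt(d_in)
        B = Tensor(np.zeros((d_out, rank)), requires_grad=True)
        A = Tensor(rng.normal(0.0, init_scale, size=(rank, d_in)), requires_grad=True)
        return cls(W0=W0.copy(), B_lr=B, A_lr=A, rank=rank)

    @property
    def n_trainable(self) -> int:
        """r * (d_in + d_out): the parameter count of the two factors."""
        return self.B_lr.data.size + self.A_lr.data.size

    def parameters(self) -> list[Tensor]:
        return [self.B_lr, self.A_lr]


def lora_forward(adapter: LoRAAdapter, x) -> Tensor:
    """``h = W0 x + B (A x)`` for row-stacked inputs ``x`` of shape (..., d_in)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.shape[-1] != adapter.W0.shape[1]:
        raise ValueError("input feature dim does not match adapter d_in")
    base = x @ Tensor(adapter.W0).swapaxes(-1, -2)
    low = x @ adapter.A_lr.swapaxes(-1, -2)          # (..., r)
    update = low @ adapter.B_lr.swapaxes(-1, -2)     # (..., d_out)
    return base + update


def merge_adapter(adapter: LoRAAdapter) -> np.ndarray:
    """Fold the low-rank update into the base: ``W0 + B @ A``."""
    return adapter.W0 + adapter.B_lr.data @ adapter.A_lr.data


class LoRALinear:
    """A :class:`~modalcoder.layers.Linear` with its weight under adaptation.

    The wrapped layer's weight becomes the frozen base; only the factors
    and the bias remain trainable.
    """

    def __init__(self, base: Linear, rank: int, rng: np.random.Generator):
        self.adapter = LoRAAdapter.create(base.weight.data, rank, rng)
        self.bias = base.bias
        self.d_in, self.d_out = base.d_in, base.d_out

    def __call__(self, x: Tensor) -> Tensor:
        y = lora_forward(self.adapter, x)
        if self.bias is not None:
            y = y + self.bias
        return y

    def parameters(self) -> list[Tensor]:
        return self.adapter.parameters() + ([self.bias] if self.bias is not None else [])


# -- multi-task objective ------------------------------------------------------

TASK_NAMES = ("coding", "contrastive", "severity")


@dataclass(frozen=True)
class TaskSpec:
    name: str
    weight: float
    loss_kind: str = "cross_entropy"

    def __post_init__(self):
        if self.name not in TASK_NAMES:
            raise ValueError(f"unknown task {self.name!r}")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("task weight must be finite and non-negative")


@dataclass(frozen=True)
class MultiTaskObjective:
    """Weighted joint loss ``sum_k lambda_k L_k`` over shared parameters."""

    tasks: tuple[TaskSpec, ...] = field(default_factory=lambda: (
        TaskSpec("coding", 1.0),
        TaskSpec("contrastive", 0.3, "info_nce"),
        TaskSpec("severity", 0.3),
    ))

    def __post_init__(self):
        if not self.tasks:
            raise ValueError("at least one task required")
        primary = [t for t in self.tasks if t.name == "coding"]
        if not primary or primary[0].weight <= 0:
            raise ValueError("primary coding task must have positive weight")

    @property
    def weights(self) -> dict[str, float]:
        return {t.name: t.weight for t in self.tasks}


def _normalize_rows(e: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((e * e).sum(axis=-1, keepdims=True) + eps) ** 0.5
    return e / norm


def contrastive_loss(embeddings: list[Tensor | np.ndarray],
                     temperature: float = 0.1) -> Tensor:
    """Symmetric InfoNCE across modality views of the same cases.

    ``embeddings`` holds one N x d matrix per modality, rows aligned by
    case.  For every ordered pair of distinct modalities the loss is the
    cross-entropy of matching case i to its counterpart among all N
    candidates under cosine similarity / temperature; the result is the
    mean over pairs and directions.
    """
    views = [e if isinstance(e, Tensor) else Tensor(e) for e in embeddings]
    if len(views) < 2:
        raise ValueError("need at least two modality views")
    n = views[0].shape[0]
    if n < 2:
        raise ValueError("insufficient batch: contrastive loss needs N >= 2")
    if any(v.shape[0] != n for v in views):
        raise ValueError("views must be row-aligned by case")
    normed = [_normalize_rows(v) for v in views]
    target = np.arange(n)
    losses: list[Tensor] = []
    for a in range(len(normed)):
        for b in range(len(normed)):
            if a == b:
                continue
            logits = (normed[a] @ normed[b].swapaxes(-1, -2)) * (1.0 / temperature)
            logp = log_softmax(logits, axis=-1)
            losses.append(-(logp[target, target].mean()))
    out = losses[0]
    for term in losses[1:]:
        out = out + term
    return out * (1.0 / len(losses))


def cross_entropy(logits: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer class labels."""
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    logp = log_softmax(logits, axis=-1)
    return -(logp[np.arange(len(labels)), labels].mean())


def severity_loss(logits: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the three severity grades (as plain classes)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 2:
        raise ValueError("severity labels must be in {0, 1, 2}")
    return cross_entropy(logits, labels)


def total_loss(objective: MultiTaskObjective,
               losses: dict[str, Tensor | float]) -> Tensor:
    """Weighted sum ``sum_k lambda_k L_k`` over the objective's tasks."""
    if set(losses) != {t.name for t in objective.tasks}:
        raise ValueError("per-task losses must match the objective's tasks")
    out: Tensor | None = None
    for task in objective.tasks:
        term = losses[task.name]
        term = term if isinstance(term, Tensor) else Tensor(term)
        weighted = term * task.weight
        out = weighted if out is None else out + weighted
    assert out is not None
    return out


# -- adapter persistence -------------------------------------------------------

def save_adapters(adapters: dict[str, LoRAAdapter], directory: str) -> None:
    """np-archive of factor matrices plus a JSON manifest of shapes/ranks."""
    os.makedirs(directory, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    manifest: dict[str, dict] = {}
    for name, ad in adapters.items():
        arrays[f"{name}.W0"] = ad.W0
        arrays[f"{name}.B"] = ad.B_lr.data
        arrays[f"{name}.A"] = ad.A_lr.data
        manifest[name] = {"rank": ad.rank, "d_out": ad.W0.shape[0],
                          "d_in": ad.W0.shape[1]}
    np.savez(os.path.join(directory, "adapters.npz"), **arrays)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_adapters(directory: str) -> dict[str, LoRAAdapter]:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    data = np.load(os.path.join(directory, "adapters.npz"))
    out: dict[str, LoRAAdapter] = {}
    for name, meta in manifest.items():
        ad = LoRAAdapter(
            W0=data[f"{name}.W0"],
            B_lr=Tensor(data[f"{name}.B"], requires_grad=True),
            A_lr=Tensor(data[f"{name}.A"], requires_grad=True),
            rank=int(meta["rank"]),
        )
        out[name] = ad
    return out
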