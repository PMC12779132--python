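"""Seeded generator of synthetic multimodal case records.

The generator emulates the *shape* of small medical-imaging coding
datasets — C mutually exclusive classes, a few hundred cases, one image,
one short text and one structured vector per case — with a known and
controllable class signal in every modality:

* structured features are class-conditional Gaussians with unit
  covariance and pairwise mean distance ``delta``;
* images are class-specific stripe/quadrant templates plus pixel noise,
  clipped to [0, 1];
* text tokens are drawn from a class-skewed categorical distribution
  (each class up-weights its own vocabulary block);
* the label vector is the one-hot class; severity (mild / moderate /
  severe) is the tercile bin of the case's latent deviation from its
  class mean.

Two perturbation operations mirror common robustness protocols:
:func:`apply_input_noise` corrupts a fixed fraction of the pooled
continuous feature entries, and :func:`subsample` drops a fraction of
the *training* records only.  Both are pure (the input dataset is never
modified) and fully seeded.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .records import SEVERITY_LEVELS, CaseRecord, read_jsonl, write_jsonl

__all__ = [
    "GeneratorConfig", "SyntheticDataset", "generate_dataset",
    "apply_input_noise", "apply_label_noise", "subsample", "drop_modality",
    "write_fixtures", "read_fixtures",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Desk-scale defaults: trains in minutes on one CPU core."""

    n_samples: int = 600
    n_classes: int = 3
    image_size: int = 16
    vocab_size: int = 32
    text_length: int = 12
    structured_dim: int = 8
    class_separation: float = 4.0   # pairwise distance between class means
    pixel_noise: float = 0.1
    seed: int = 0
    train_frac: float = 0.70
    val_frac: float = 0.15

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.class_separation < 0:
            raise ValueError("class separation must be non-negative")
        if min(self.n_samples, self.image_size, self.vocab_size,
               self.text_length, self.structured_dim) < 1:
            raise ValueError("all sizes must be positive")
        if self.n_classes > self.structured_dim:
            raise ValueError("n_classes must not exceed structured_dim")
        if not 0 < self.train_frac + self.val_frac < 1:
            raise ValueError("train and validation fractions must leave a test split")


@dataclass
class SyntheticDataset:
    records: list[CaseRecord]
    class_means: np.ndarray          # C x d_s structured means
    templates: np.ndarray            # C x H x W image templates
    token_probs: np.ndarray          # C x vocab categorical distributions
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    config: GeneratorConfig = field(default=None)  # type: ignore[assignment]

    def split(self, name: str) -> list[CaseRecord]:
        idx = {"train": self.train_idx, "val": self.val_idx,
               "test": self.test_idx}[name]
        return [self.records[i] for i in idx]

    @property
    def classes(self) -> np.ndarray:
        return np.asarray([int(np.argmax(r.labels)) for r in self.records])


def _class_means(C: int, d: int, delta: float) -> np.ndarray:
    """C means in R^d with all pairwise distances exactly delta."""
    means = np.zeros((C, d))
    for c in range(C):
        means[c, c] = delta / np.sqrt(2.0)
    means -= means.mean(axis=0)
    return means


def _templates(C: int, size: int) -> np.ndarray:
    """Deterministic class-specific patterns: stripes of varying period
    and orientation, quadrant blocks for every third class."""
    t = np.zeros((C, size, size))
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    for c in range(C):
        kind = c % 3
        period = 2 + 2 * (c // 3)
        if kind == 0:     # horizontal stripes
            pat = (rows // period) % 2
        elif kind == 1:   # vertical stripes
            pat = (cols // period) % 2
        else:             # quadrant block
            pat = ((rows < size // 2) ^ (cols < size // 2)).astype(int)
        t[c] = 0.25 + 0.5 * pat
    return t


def _token_probs(C: int, vocab: int, skew: float = 0.7) -> np.ndarray:
    """Each class puts ``skew`` mass on its own vocabulary block."""
    probs = np.full((C, vocab), (1.0 - skew) / vocab)
    block = vocab // C
    for c in range(C):
        lo, hi = c * block, (c + 1) * block if c < C - 1 else vocab
        probs[c, lo:hi] += skew / (hi - lo)
    return probs / probs.sum(axis=1, keepdims=True)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a fully seeded dataset with disjoint train/val/test splits."""
    rng = np.random.default_rng(config.seed)
    C, n = config.n_classes, config.n_samples
    means = _class_means(C, config.structured_dim, config.class_separation)
    templates = _templates(C, config.image_size)
    token_probs = _token_probs(C, config.vocab_size)

    # near-balanced class assignment (round-robin, then shuffled)
    classes = np.arange(n) % C
    rng.shuffle(classes)

    structured = means[classes] + rng.standard_normal((n, config.structured_dim))
    images = np.clip(
        templates[classes] + rng.normal(0.0, config.pixel_noise,
                                        (n, config.image_size, config.image_size)),
        0.0, 1.0)
    texts = np.stack([
        rng.choice(config.vocab_size, size=config.text_length, p=token_probs[c])
        for c in classes])

    # severity = tercile of the latent deviation from the class mean
    deviation = np.linalg.norm(structured - means[classes], axis=1)
    terciles = np.quantile(deviation, [1 / 3, 2 / 3])
    severity_idx = np.searchsorted(terciles, deviation)

    records = []
    for i in range(n):
        labels = np.zeros(C, dtype=np.int64)
        labels[classes[i]] = 1
        records.append(CaseRecord(
            case_id=f"case-{i:05d}",
            image=images[i],
            text=texts[i],
            structured=structured[i],
            labels=labels,
            severity=SEVERITY_LEVELS[severity_idx[i]],
        ))

    perm = rng.permutation(n)
    n_train = int(round(config.train_frac * n))
    n_val = int(round(config.val_frac * n))
    return SyntheticDataset(
        records=records,
        class_means=means,
        templates=templates,
        token_probs=token_probs,
        train_idx=perm[:n_train],
        val_idx=perm[n_train:n_train + n_val],
        test_idx=perm[n_train + n_val:],
        config=config,
    )


def _feature_entry_count(records: list[CaseRecord]) -> int:
    total = 0
    for r in records:
        if r.structured is not None:
            total += r.structured.size
        if r.image is not None:
            total += r.image.size
    return total


def apply_input_noise(dataset: SyntheticDataset, fraction: float,
                      seed: int) -> SyntheticDataset:
    """Corrupt exactly ``floor(fraction * total feature entries)`` entries.

    Entries are pooled across all structured coordinates and image pixels
    of every record; chosen entries receive additive Gaussian noise at
    one empirical standard deviation of the pooled features, and images
    are re-clipped to [0, 1].  Labels, severity and text are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("noise fraction must lie in [0, 1]")
    out = copy.deepcopy(dataset)
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)

    slots: list[tuple[int, str]] = []  # (record index, field) per entry block
    pooled = []
    for i, r in enumerate(out.records):
        if r.structured is not None:
            pooled.append(r.structured.ravel())
        if r.image is not None:
            pooled.append(r.image.ravel())
    pooled_vals = np.concatenate(pooled)
    sigma = float(pooled_vals.std())
    total = pooled_vals.size
    n_corrupt = int(np.floor(fraction * total))
    chosen = rng.choice(total, size=n_corrupt, replace=False)
    noise = rng.normal(0.0, sigma, size=n_corrupt)

    # map flat pooled indices back onto (record, field, offset)
    offsets = []
    cursor = 0
    for i, r in enumerate(out.records):
        if r.structured is not None:
            offsets.append((cursor, cursor + r.structured.size, i, "structured"))
            cursor += r.structured.size
        if r.image is not None:
            offsets.append((cursor, cursor + r.image.size, i, "image"))
            cursor += r.image.size
    starts = np.asarray([o[0] for o in offsets])
    block = np.searchsorted(starts, chosen, side="right") - 1
    for b, flat_idx, dv in zip(block, chosen, noise):
        lo, _hi, i, fieldname = offsets[b]
        rec = out.records[i]
        arr = getattr(rec, fieldname)
        arr.ravel()[flat_idx - lo] += dv
    for r in out.records:
        if r.image is not None:
            np.clip(r.image, 0.0, 1.0, out=r.image)
    return out


def apply_label_noise(dataset: SyntheticDataset, fraction: float,
                      seed: int) -> SyntheticDataset:
    """Alternative noise model: reassign a fraction of training labels
    to a uniformly random other class."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("noise fraction must lie in [0, 1]")
    out = copy.deepcopy(dataset)
    rng = np.random.default_rng(seed)
    n_flip = int(np.floor(fraction * len(out.train_idx)))
    flip = rng.choice(out.train_idx, size=n_flip, replace=False)
    C = len(out.records[0].labels)
    for i in flip:
        rec = out.records[i]
        current = int(np.argmax(rec.labels))
        new = int(rng.choice([c for c in range(C) if c != current]))
        rec.labels[:] = 0
        rec.labels[new] = 1
    return out


def subsample(dataset: SyntheticDataset, keep_fraction: float,
              seed: int) -> SyntheticDataset:
    """Uniformly drop ``1 - keep_fraction`` of the TRAINING records only."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    out = copy.deepcopy(dataset)
    if keep_fraction == 1.0:
        return out
    rng = np.random.default_rng(seed)
    n_keep = int(round(keep_fraction * len(out.train_idx)))
    kept = rng.choice(out.train_idx, size=n_keep, replace=False)
    out.train_idx = np.sort(kept)
    return out


def drop_modality(dataset: SyntheticDataset, modality: str, fraction: float,
                  seed: int) -> SyntheticDataset:
    """Remove one modality from a fraction of records (incomplete-record
    scenario); the other modalities and all labels are untouched."""
    if modality not in ("structured", "text", "image"):
        raise ValueError(f"unknown modality {modality!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = copy.deepcopy(dataset)
    rng = np.random.default_rng(seed)
    n_drop = int(np.floor(fraction * len(out.records)))
    chosen = rng.choice(len(out.records), size=n_drop, replace=False)
    for i in chosen:
        rec = out.records[i]
        others = [m for m in ("structured", "text", "image") if m != modality]
        if all(getattr(rec, m) is None for m in others):
            continue  # never empty a record entirely
        setattr(rec, modality, None)
    return out


def write_fixtures(dataset: SyntheticDataset, path: str) -> None:
    """JSON Lines case records plus a JSON manifest of generative
    parameters and split indices."""
    os.makedirs(path, exist_ok=True)
    write_jsonl(dataset.records, os.path.join(path, "records.jsonl"))
    manifest = {
        "class_means": dataset.class_means.tolist(),
        "templates": dataset.templates.tolist(),
        "token_probs": dataset.token_probs.tolist(),
        "train_idx": dataset.train_idx.tolist(),
        "val_idx": dataset.val_idx.tolist(),
        "test_idx": dataset.test_idx.tolist(),
        "config": None if dataset.config is None else vars(dataset.config).copy()
        if not hasattr(dataset.config, "__dataclass_fields__")
        else {f: getattr(dataset.config, f)
              for f in dataset.config.__dataclass_fields__},
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh)


def read_fixtures(path: str) -> SyntheticDataset:
    records = read_jsonl(os.path.join(path, "records.jsonl"), image_root=path)
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    cfg = manifest.get("config")
    return SyntheticDataset(
        records=records,
        class_means=np.asarray(manifest["class_means"]),
        templates=np.asarray(manifest["templates"]),
        token_probs=np.asarray(manifest["token_probs"]),
        train_idx=np.asarray(manifest["train_idx"], dtype=np.int64),
        val_idx=np.asarray(manifest["val_idx"], dtype=np.int64),
        test_idx=np.asarray(manifest["test_idx"], dtype=np.int64),
        config=None if cfg is None else GeneratorConfig(**cfg),
    )
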