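"""Core data containers: multimodal case records and token feature sequences.

A *case record* bundles the three input channels of one medical case —
an image grid, a token-id text sequence and a numeric structured-feature
vector — together with its binary label vector and a three-level severity
grade.  A :class:`FeatureSequence` is the currency between network blocks:
an ordered ``n x d`` matrix of token embeddings where every token carries
a modality tag and a position index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor

MODALITIES = ("structured", "text", "image")
SEVERITY_LEVELS = ("mild", "moderate", "severe")


@dataclass
class CaseRecord:
    """One multimodal sample.

    Absent modalities are ``None``; at least one must be present.
    """

    case_id: str
    image: np.ndarray | None  # H x W grid, intensities in [0, 1]
    text: np.ndarray | None   # token ids
    structured: np.ndarray | None
    labels: np.ndarray        # binary vector of length L
    severity: str             # one of SEVERITY_LEVELS

    def __post_init__(self):
        if self.image is not None:
            self.image = np.asarray(self.image, dtype=np.float64)
            if self.image.ndim != 2:
                raise ValueError("image must be a 2-D grid")
            if self.image.min() < 0 or self.image.max() > 1:
                raise ValueError("image intensities must lie in [0, 1]")
        if self.text is not None:
            self.text = np.asarray(self.text, dtype=np.int64)
        if self.structured is not None:
            self.structured = np.asarray(self.structured, dtype=np.float64)
        if all(m is None for m in (self.image, self.text, self.structured)):
            raise ValueError("at least one modality must be present")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.severity not in SEVERITY_LEVELS:
            raise ValueError(f"severity must be one of {SEVERITY_LEVELS}")

    @property
    def modality_signature(self) -> tuple[bool, bool, bool]:
        """Presence flags in canonical (structured, text, image) order."""
        return (self.structured is not None,
                self.text is not None and len(self.text) > 0,
                self.image is not None)

    def to_json(self) -> str:
        return json.dumps({
            "id": self.case_id,
            "image": None if self.image is None else self.image.tolist(),
            "text": None if self.text is None else self.text.tolist(),
            "structured": None if self.structured is None else self.structured.tolist(),
            "labels": self.labels.tolist(),
            "severity": self.severity,
        })

    @classmethod
    def from_json(cls, line: str, image_root: str | None = None) -> "CaseRecord":
        d = json.loads(line)
        image = d.get("image")
        if isinstance(image, str):  # PNG file path
            from PIL import Image
            import os
            path = image if image_root is None else os.path.join(image_root, image)
            arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
            image = arr
        elif image is not None:
            image = np.asarray(image, dtype=np.float64)
        return cls(
            case_id=d["id"],
            image=image,
            text=None if d.get("text") is None else np.asarray(d["text"], dtype=np.int64),
            structured=None if d.get("structured") is None
            else np.asarray(d["structured"], dtype=np.float64),
            labels=np.asarray(d["labels"], dtype=np.int64),
            severity=d["severity"],
        )


def write_jsonl(records: Iterable[CaseRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_jsonl(path, image_root: str | None = None) -> list[CaseRecord]:
    with open(path) as fh:
        return [CaseRecord.from_json(line, image_root) for line in fh if line.strip()]


@dataclass
class FeatureSequence:
    """An ordered ``n x d`` (optionally batched ``... x n x d``) token matrix.

    ``tags`` assigns each of the ``n`` tokens to a modality; ``positions``
    are strictly increasing 0-based indices.  ``values`` may carry a
    gradient tape, so the same container flows through training.
    """

    values: Tensor
    tags: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = Tensor(self.values)
        n = self.values.shape[-2]
        if n < 1:
            raise ValueError("a feature sequence needs at least one token")
        if not np.isfinite(self.values.data).all():
            raise ValueError("feature values must be finite")
        self.tags = np.asarray(self.tags, dtype=object)
        if self.tags.shape != (n,):
            raise ValueError("one modality tag per token required")
        unknown = set(self.tags) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modality tags: {sorted(unknown)}")
        if self.positions is None:
            self.positions = np.arange(n)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (n,) or not (np.diff(self.positions) > 0).all() and n > 1:
            if n > 1 and not (np.diff(self.positions) > 0).all():
                raise ValueError("positions must be strictly increasing")

    @property
    def n_tokens(self) -> int:
        return self.values.shape[-2]

    @property
    def d(self) -> int:
        return self.values.shape[-1]

    def with_values(self, values: Tensor) -> "FeatureSequence":
        """Same tokens, new value matrix (used by every network block)."""
        return FeatureSequence(values, self.tags, self.positions)

    def modality_slice(self, modality: str) -> np.ndarray:
        """Boolean mask over tokens belonging to ``modality``."""
        return np.asarray([t == modality for t in self.tags], dtype=bool)


def severity_index(label: str) -> int:
    return SEVERITY_LEVELS.index(label)
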