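"""Modality encoders: raw case records to a unified token sequence.

Each modality is linearly projected into the shared ``d_model`` space:
the image as a grid of flattened non-overlapping patches, the text by
embedding-table lookup, and the structured vector as a single token.
Assembly concatenates the three parts in the canonical order
(structured, text, image), renumbers positions, and adds fixed
sinusoidal positional encodings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, embedding_take
from .layers import Linear
from .records import CaseRecord, FeatureSequence

__all__ = [
    "EmbeddingConfig", "ModalityEncoders", "embed_image", "embed_text",
    "embed_structured", "assemble_sequence", "sinusoidal_encoding",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    d_model: int = 64
    patch_size: int = 4
    vocab_size: int = 32
    structured_dim: int = 8
    max_positions: int = 512

    def __post_init__(self):
        if self.patch_size < 1 or self.d_model < 1:
            raise ValueError("sizes must be positive")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be at least 2")


class ModalityEncoders:
    """Trainable projection parameters for the three modalities."""

    def __init__(self, config: EmbeddingConfig, rng: np.random.Generator):
        self.config = config
        p = config.patch_size
        self.patch_proj = Linear(p * p, config.d_model, rng)
        self.token_table = Tensor(
            rng.normal(0.0, 0.5, size=(config.vocab_size, config.d_model)),
            requires_grad=True)
        self.structured_proj = Linear(config.structured_dim, config.d_model, rng)

    def parameters(self) -> list[Tensor]:
        return (self.patch_proj.parameters() + [self.token_table]
                + self.structured_proj.parameters())


def _patches(image: np.ndarray, p: int) -> np.ndarray:
    """Flattened p x p patches in raster order; shape (..., n_patches, p*p)."""
    *lead, H, W = image.shape
    if H % p or W % p:
        raise ValueError(f"image dims ({H}, {W}) not divisible by patch size {p}")
    x = image.reshape(*lead, H // p, p, W // p, p)
    x = np.moveaxis(x, -3, -2)  # (..., H/p, W/p, p, p)
    return x.reshape(*lead, (H // p) * (W // p), p * p)


def embed_image(image: np.ndarray, config: EmbeddingConfig,
                encoders: ModalityEncoders) -> FeatureSequence:
    """One token per p x p patch, raster order, linear projection."""
    image = np.asarray(image, dtype=np.float64)
    flat = _patches(image, config.patch_size)
    values = encoders.patch_proj(Tensor(flat))
    n = values.shape[-2]
    return FeatureSequence(values, np.asarray(["image"] * n, dtype=object))


def embed_text(tokens: np.ndarray, config: EmbeddingConfig,
               encoders: ModalityEncoders) -> FeatureSequence | None:
    """Embedding-table lookup, one row per token id.

    Returns ``None`` for an empty sequence (absent modality).
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.size == 0:
        return None
    if tokens.min() < 0 or tokens.max() >= config.vocab_size:
        raise ValueError("token id outside vocabulary")
    values = embedding_take(encoders.token_table, tokens)
    n = tokens.shape[-1]
    return FeatureSequence(values, np.asarray(["text"] * n, dtype=object))


def embed_structured(vector: np.ndarray,
                     encoders: ModalityEncoders) -> FeatureSequence:
    """A single token: one linear projection of the whole vector."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape[-1] != encoders.structured_proj.d_in:
        raise ValueError("structured vector length does not match projection")
    values = encoders.structured_proj(Tensor(vector[..., None, :]))
    return FeatureSequence(values, np.asarray(["structured"], dtype=object))


def sinusoidal_encoding(n: int, d: int) -> np.ndarray:
    """Fixed transformer positional encodings; position 0 is (0, 1, 0, 1, ...)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / (10000.0 ** (2 * i / d))
    enc = np.zeros((n, d))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle)
    return enc


_CANONICAL = {"structured": 0, "text": 1, "image": 2}


def assemble_sequence(parts: list[FeatureSequence | None],
                      config: EmbeddingConfig) -> FeatureSequence:
    """Concatenate modality parts in canonical order and add positions.

    Absent modalities (``None`` entries) contribute zero tokens; if every
    part is absent an empty-case error is raised.
    """
    parts = [p for p in parts if p is not None]
    if not parts:
        raise ValueError("empty case: all modalities absent")
    order = sorted(range(len(parts)), key=lambda i: _CANONICAL[str(parts[i].tags[0])])
    parts = [parts[i] for i in order]
    values = concat([p.values for p in parts], axis=-2)
    tags = np.concatenate([p.tags for p in parts])
    n = values.shape[-2]
    if n > config.max_positions:
        raise ValueError("sequence exceeds max_positions")
    values = values + Tensor(sinusoidal_encoding(n, config.d_model))
    return FeatureSequence(values, tags, np.arange(n))


def encode_case(record: CaseRecord, config: EmbeddingConfig,
                encoders: ModalityEncoders) -> FeatureSequence:
    """Full encoder path for one record (or a batch stacked upstream)."""
    parts: list[FeatureSequence | None] = []
    if record.structured is not None:
        parts.append(embed_structured(record.structured, encoders))
    if record.text is not None and len(record.text) > 0:
        parts.append(embed_text(record.text, config, encoders))
    if record.image is not None:
        parts.append(embed_image(record.image, config, encoders))
    return assemble_sequence(parts, config)
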