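"""Causal masked self-attention.

Standard scaled dot-product attention lets every token attend to every
other token.  The causal variant adds an additive mask ``M`` with
``M[i, j] = 0`` for ``j <= i`` and ``-inf`` for ``j > i`` to the logits
``Q K^T / sqrt(d_k)``, so each token interacts only with itself and
earlier tokens.  Masked positions receive *exactly* zero attention
weight, which makes the causality contract testable to machine
precision: perturbing a future token can never change an earlier output.

The multi-head block wraps this attention in a pre-norm residual
transformer layer (LayerNorm -> attention -> residual, LayerNorm ->
feed-forward -> residual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, masked_softmax
from .layers import FeedForward, LayerNorm, Linear
from .records import FeatureSequence

__all__ = [
    "CausalMask", "AttentionConfig", "build_causal_mask", "masked_attention",
    "MultiHeadCausalBlock", "DegenerateMaskError",
]


class DegenerateMaskError(ValueError):
    """Raised when an attention mask leaves a query row with no visible key."""


@dataclass(frozen=True)
class CausalMask:
    """Additive lower-triangular-visible mask over ``{0, -inf}``."""

    entries: np.ndarray

    def __post_init__(self):
        e = self.entries
        n = e.shape[0]
        if e.shape != (n, n):
            raise ValueError("mask must be square")
        lower = np.tril(np.ones((n, n), dtype=bool))
        if not (np.where(lower, e == 0.0, np.isneginf(e))).all():
            raise ValueError("entries must be 0 on/below the diagonal and -inf above")

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class AttentionConfig:
    """Head geometry: ``d_model = n_heads * d_k``."""

    d_model: int = 64
    n_heads: int = 4

    def __post_init__(self):
        if self.d_model < 1 or self.n_heads < 1:
            raise ValueError("d_model and n_heads must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def build_causal_mask(n: int) -> CausalMask:
    """The additive causal mask: 0 where ``i >= j``, ``-inf`` where ``i < j``."""
    if n < 1:
        raise ValueError("mask size must be at least 1")
    entries = np.where(np.tril(np.ones((n, n), dtype=bool)), 0.0, -np.inf)
    return CausalMask(entries)


def _mask_entries(mask) -> np.ndarray:
    m = mask.entries if isinstance(mask, CausalMask) else np.asarray(mask, dtype=np.float64)
    ok = (m == 0.0) | np.isneginf(m)
    if not ok.all():
        raise ValueError("additive mask entries must be 0 or -inf")
    return m


def masked_attention(Q, K, V, mask, return_weights: bool = False):
    """Scaled dot-product attention with an additive ``{0, -inf}`` mask.

    Output row ``i`` is a convex combination of the rows of ``V`` visible
    to query ``i``; weight on masked positions is exactly zero.  A query
    row with no visible key raises :class:`DegenerateMaskError`.
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("Q/K feature dims and K/V row counts must agree")
    m = _mask_entries(mask)
    if m.shape != (Q.shape[-2], K.shape[-2]):
        raise ValueError("mask shape must be (n_query, n_key)")
    visible = m == 0.0
    if not visible.any(axis=-1).all():
        raise DegenerateMaskError("a query row is fully masked")
    d_k = Q.shape[-1]
    logits = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    weights = masked_softmax(logits, visible)
    out = weights @ V
    return (out, weights) if return_weights else out


class MultiHeadCausalBlock:
    """Pre-norm residual transformer layer with multi-head masked attention.

    The mask is supplied per call (the causal mask in normal operation;
    an all-zero mask reduces the block to a standard bidirectional layer,
    which is how the causal-mask ablation is realized).
    """

    def __init__(self, config: AttentionConfig, rng: np.random.Generator,
                 ffn_hidden: int | None = None):
        d = config.d_model
        self.config = config
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.o_proj = Linear(d, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ffn = FeedForward(d, ffn_hidden or 4 * d, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        *lead, n, d = x.shape
        h = self.config.n_heads
        return x.reshape(*lead, n, h, self.config.d_k).swapaxes(-2, -3)

    def _merge_heads(self, x: Tensor) -> Tensor:
        y = x.swapaxes(-2, -3)
        *lead, n, h, dk = y.shape
        return y.reshape(*lead, n, h * dk)

    def attend(self, x: Tensor, mask, return_weights: bool = False):
        """Multi-head masked attention on pre-normalized inputs."""
        xn = self.ln1(x)
        q = self._split_heads(self.q_proj(xn))
        k = self._split_heads(self.k_proj(xn))
        v = self._split_heads(self.v_proj(xn))
        res = masked_attention(q, k, v, mask, return_weights=return_weights)
        heads, weights = res if return_weights else (res, None)
        out = self.o_proj(self._merge_heads(heads))
        return (out, weights) if return_weights else out

    def __call__(self, seq: FeatureSequence, mask=None) -> FeatureSequence:
        x = seq.values
        if x.shape[-1] != self.config.d_model:
            raise ValueError(
                f"input feature dim {x.shape[-1]} != d_model {self.config.d_model}")
        if mask is None:
            mask = build_causal_mask(seq.n_tokens)
        x = x + self.attend(x, mask)
        x = x + self.ffn(self.ln2(x))
        return seq.with_values(x)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for part in (self.q_proj, self.k_proj, self.v_proj, self.o_proj,
                     self.ln1, self.ln2, self.ffn):
            params += part.parameters()
        return params

    def attention_projections(self) -> dict[str, Linear]:
        """Named projections eligible for low-rank adaptation."""
        return {"q": self.q_proj, "v": self.v_proj}
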