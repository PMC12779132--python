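"""Constrained cross-modal attention fusion.

Unlike unconstrained cross-attention, information is exchanged only
between modality pairs on an explicit whitelist ``P`` of ordered
(query-modality, key-modality) pairs.  The allowed-pair mask sets logits
of every other pair to ``-inf``, so attention mass on disallowed pairs
is exactly zero.  The block follows the post-norm form

    out = LayerNorm(X_t + Concat(head_1, ..., head_h) @ W_O)

followed by a position-wise feed-forward network
``W2·ReLU(W1·x + b1) + b2``.

A query token whose row is fully masked (its modality may pair with
nothing on the key side) contributes a zero attention term, so the block
degrades gracefully to ``LayerNorm(X_t)`` instead of producing NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, masked_softmax
from .layers import FeedForward, LayerNorm, Linear
from .records import MODALITIES, FeatureSequence

__all__ = [
    "ModalityPairPolicy", "PCMABlockConfig", "build_allowed_mask",
    "ConstrainedCrossModalBlock", "pcma_multihead", "feed_forward",
    "DEFAULT_POLICY_PAIRS",
]

#: Default whitelist: text and image exchange symmetrically; the
#: structured token reads from both but is not read from.
DEFAULT_POLICY_PAIRS = (
    ("text", "image"), ("image", "text"),
    ("structured", "text"), ("structured", "image"),
)


@dataclass(frozen=True)
class ModalityPairPolicy:
    """Whitelist of ordered (query, key) modality pairs."""

    pairs: frozenset = field(default_factory=lambda: frozenset(DEFAULT_POLICY_PAIRS))

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        for q, k in self.pairs:
            if q not in MODALITIES or k not in MODALITIES:
                raise ValueError(f"unknown modality in pair ({q}, {k})")

    @property
    def query_modalities(self) -> frozenset:
        return frozenset(q for q, _ in self.pairs)

    @property
    def key_modalities(self) -> frozenset:
        return frozenset(k for _, k in self.pairs)

    @classmethod
    def complete(cls) -> "ModalityPairPolicy":
        return cls(frozenset((a, b) for a in MODALITIES for b in MODALITIES))

    @classmethod
    def empty(cls) -> "ModalityPairPolicy":
        return cls(frozenset())


@dataclass(frozen=True)
class PCMABlockConfig:
    d_model: int = 64
    n_heads: int = 4
    ffn_hidden: int = 128
    ln_epsilon: float = 1e-5

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")
        if self.ffn_hidden < 1:
            raise ValueError("ffn_hidden must be positive")


def build_allowed_mask(policy: ModalityPairPolicy, query_tags, key_tags) -> np.ndarray:
    """Additive mask: entry (i, j) is 0 iff (modality(i), modality(j)) in P."""
    query_tags = [str(t) for t in query_tags]
    key_tags = [str(t) for t in key_tags]
    for t in set(query_tags) | set(key_tags):
        if t not in MODALITIES:
            raise ValueError(f"tag {t!r} maps to no modality")
    allowed = np.asarray(
        [[(q, k) in policy.pairs for k in key_tags] for q in query_tags], dtype=bool)
    return np.where(allowed, 0.0, -np.inf)


class ConstrainedCrossModalBlock:
    """Multi-head cross-attention from X_t to X_s under an allowed-pair policy."""

    def __init__(self, config: PCMABlockConfig, rng: np.random.Generator):
        d = config.d_model
        self.config = config
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.o_proj = Linear(d, d, rng)  # W_O
        self.ln = LayerNorm(d, eps=config.ln_epsilon)
        self.ffn = FeedForward(d, config.ffn_hidden, rng)
        self.ffn_ln = LayerNorm(d, eps=config.ln_epsilon)

    def _split(self, x: Tensor) -> Tensor:
        *lead, n, d = x.shape
        h = self.config.n_heads
        return x.reshape(*lead, n, h, d // h).swapaxes(-2, -3)

    def _merge(self, x: Tensor) -> Tensor:
        y = x.swapaxes(-2, -3)
        *lead, n, h, dk = y.shape
        return y.reshape(*lead, n, h * dk)

    def attend(self, x_t: FeatureSequence, x_s: FeatureSequence,
               policy: ModalityPairPolicy, return_weights: bool = False):
        """LayerNorm(X_t + Concat(heads) W_O); exact zeros off-whitelist."""
        if x_t.d != self.config.d_model or x_s.d != self.config.d_model:
            raise ValueError("both sequences must have d_model columns")
        mask = build_allowed_mask(policy, x_t.tags, x_s.tags)
        visible = mask == 0.0
        q = self._split(self.q_proj(x_t.values))
        k = self._split(self.k_proj(x_s.values))
        v = self._split(self.v_proj(x_s.values))
        d_k = self.config.d_model // self.config.n_heads
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
        # fully-masked query rows yield an all-zero weight row -> zero term
        weights = masked_softmax(logits, visible)
        fused = self.o_proj(self._merge(weights @ v))
        out = self.ln(x_t.values + fused)
        seq = x_t.with_values(out)
        return (seq, weights) if return_weights else seq

    def __call__(self, x_t: FeatureSequence, x_s: FeatureSequence,
                 policy: ModalityPairPolicy) -> FeatureSequence:
        seq = self.attend(x_t, x_s, policy)
        out = self.ffn_ln(seq.values + self.ffn(seq.values))
        return seq.with_values(out)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for part in (self.q_proj, self.k_proj, self.v_proj, self.o_proj,
                     self.ln, self.ffn, self.ffn_ln):
            params += part.parameters()
        return params

    def attention_projections(self) -> dict[str, Linear]:
        return {"q": self.q_proj, "v": self.v_proj}


def pcma_multihead(x_t: FeatureSequence, x_s: FeatureSequence,
                   policy: ModalityPairPolicy, config: PCMABlockConfig,
                   block: ConstrainedCrossModalBlock | None = None,
                   rng: np.random.Generator | None = None) -> FeatureSequence:
    """Functional form of the constrained cross-modal attention sub-layer."""
    if block is None:
        block = ConstrainedCrossModalBlock(config, rng or np.random.default_rng(0))
    return block.attend(x_t, x_s, policy)


def feed_forward(x: FeatureSequence | Tensor, w1, b1, w2, b2):
    """Position-wise ``W2·ReLU(W1·x + b1) + b2`` (weights as matrices)."""
    values = x.values if isinstance(x, FeatureSequence) else x
    values = values if isinstance(values, Tensor) else Tensor(values)
    w1t, w2t = Tensor(np.asarray(w1, float)), Tensor(np.asarray(w2, float))
    b1t, b2t = Tensor(np.asarray(b1, float)), Tensor(np.asarray(b2, float))
    hidden = (values @ w1t.swapaxes(-1, -2) + b1t).relu()
    out = hidden @ w2t.swapaxes(-1, -2) + b2t
    if isinstance(x, FeatureSequence):
        return x.with_values(out)
    return out
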