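"""The full multimodal coding network.

Wiring: modality encoders -> assembled token sequence -> stacked causal
attention blocks -> constrained cross-modal fusion -> mean pooling ->
coding head + severity head.  Per-modality mean-pooled token
representations are exposed *before* fusion as the contrastive views.

Every architectural ablation is a strict configuration change, not a
code fork: with the causal mask off, attention uses the all-zero mask;
with fusion off, the fused sequence is the plain causal-stack output
(concatenation + mean pooling); with multi-task learning off, the
auxiliary loss weights are zero.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionConfig, MultiHeadCausalBlock, build_causal_mask
from .autodiff import Tensor
from .encoding import EmbeddingConfig, ModalityEncoders, encode_case
from .fusion import (DEFAULT_POLICY_PAIRS, ConstrainedCrossModalBlock,
                     ModalityPairPolicy, PCMABlockConfig)
from .lora import LoRALinear
from .records import MODALITIES, CaseRecord, FeatureSequence

__all__ = ["ModelConfig", "CodingNetwork", "stack_records"]


@dataclass(frozen=True)
class ModelConfig:
    n_labels: int = 3
    d_model: int = 64
    n_heads: int = 4
    n_causal_blocks: int = 2
    ffn_hidden: int = 128
    patch_size: int = 4
    vocab_size: int = 32
    structured_dim: int = 8
    policy_pairs: tuple = DEFAULT_POLICY_PAIRS
    use_causal_mask: bool = True
    use_pcma: bool = True
    use_mtl: bool = True
    lora_enabled: bool = False
    lora_rank: int = 4

    def __post_init__(self):
        AttentionConfig(self.d_model, self.n_heads)  # validates divisibility
        if self.n_labels < 1 or self.n_causal_blocks < 1:
            raise ValueError("n_labels and n_causal_blocks must be positive")


def stack_records(records: list[CaseRecord]) -> CaseRecord:
    """Stack same-signature records into one batched pseudo-record."""
    sig = records[0].modality_signature
    if any(r.modality_signature != sig for r in records):
        raise ValueError("records in a batch must share a modality signature")
    has_s, has_t, has_i = sig
    batched = CaseRecord.__new__(CaseRecord)
    batched.case_id = "batch"
    batched.structured = (np.stack([r.structured for r in records])
                          if has_s else None)
    batched.text = np.stack([r.text for r in records]) if has_t else None
    batched.image = np.stack([r.image for r in records]) if has_i else None
    batched.labels = np.stack([r.labels for r in records])
    batched.severity = records[0].severity
    return batched


def _token_select(values: Tensor, token_idx: np.ndarray) -> Tensor:
    """Select tokens along the second-to-last axis."""
    index = (slice(None),) * (values.ndim - 2) + (token_idx, slice(None))
    return values[index]


class CodingNetwork:
    """Trainable parameters and forward pass of the whole architecture."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.embed_config = EmbeddingConfig(
            d_model=config.d_model, patch_size=config.patch_size,
            vocab_size=config.vocab_size, structured_dim=config.structured_dim)
        self.encoders = ModalityEncoders(self.embed_config, rng)
        attn_cfg = AttentionConfig(config.d_model, config.n_heads)
        self.causal_blocks = [
            MultiHeadCausalBlock(attn_cfg, rng, ffn_hidden=config.ffn_hidden)
            for _ in range(config.n_causal_blocks)]
        self.pcma_config = PCMABlockConfig(
            d_model=config.d_model, n_heads=config.n_heads,
            ffn_hidden=config.ffn_hidden)
        self.pcma_block = ConstrainedCrossModalBlock(self.pcma_config, rng)
        self.policy = ModalityPairPolicy(frozenset(config.policy_pairs))
        from .layers import Linear
        self.coding_head = Linear(config.d_model, config.n_labels, rng)
        self.severity_head = Linear(config.d_model, 3, rng)
        self._lora_rng = rng
        if config.lora_enabled:
            self.enable_lora(config.lora_rank)

    # -- LoRA -----------------------------------------------------------------
    def enable_lora(self, rank: int) -> None:
        """Freeze the attention q/v projections under low-rank adapters."""
        for block in [*self.causal_blocks, self.pcma_block]:
            for name, proj in block.attention_projections().items():
                wrapped = LoRALinear(proj, rank, self._lora_rng)
                setattr(block, f"{name}_proj", wrapped)

    def adapters(self) -> dict[str, "LoRALinear"]:
        out = {}
        blocks = {f"causal{i}": b for i, b in enumerate(self.causal_blocks)}
        blocks["pcma"] = self.pcma_block
        for bname, block in blocks.items():
            for pname in ("q_proj", "v_proj"):
                proj = getattr(block, pname)
                if isinstance(proj, LoRALinear):
                    out[f"{bname}.{pname}"] = proj
        return out

    # -- forward --------------------------------------------------------------
    def encode(self, batched: CaseRecord) -> FeatureSequence:
        return encode_case(batched, self.embed_config, self.encoders)

    def causal_stack(self, seq: FeatureSequence) -> FeatureSequence:
        n = seq.n_tokens
        if self.config.use_causal_mask:
            mask = build_causal_mask(n)
        else:
            mask = np.zeros((n, n))
        for block in self.causal_blocks:
            seq = block(seq, mask)
        return seq

    def modality_embeddings(self, seq: FeatureSequence) -> dict[str, Tensor]:
        """Mean-pooled per-modality token representations (pre-fusion)."""
        out: dict[str, Tensor] = {}
        for m in MODALITIES:
            idx = np.flatnonzero(seq.modality_slice(m))
            if idx.size:
                out[m] = _token_select(seq.values, idx).mean(axis=-2)
        return out

    def forward(self, records: list[CaseRecord]):
        """Label logits (B x L), severity logits (B x 3), contrastive views."""
        batched = stack_records(records)
        seq = self.causal_stack(self.encode(batched))
        views = self.modality_embeddings(seq)
        if self.config.use_pcma:
            fused = self.pcma_block(seq, seq, self.policy)
        else:
            fused = seq  # plain concatenation of modality tokens
        pooled = fused.values.mean(axis=-2)
        return self.coding_head(pooled), self.severity_head(pooled), views

    def predict_scores(self, records: list[CaseRecord],
                       batch_size: int = 64) -> np.ndarray:
        """Per-label scores (softmax over classes), grouping records by
        modality signature so incomplete records are handled."""
        scores = np.zeros((len(records), self.config.n_labels))
        groups: dict[tuple, list[int]] = {}
        for i, r in enumerate(records):
            groups.setdefault(r.modality_signature, []).append(i)
        for idx_list in groups.values():
            for lo in range(0, len(idx_list), batch_size):
                chunk = idx_list[lo:lo + batch_size]
                logits, _, _ = self.forward([records[i] for i in chunk])
                z = logits.data - logits.data.max(axis=-1, keepdims=True)
                p = np.exp(z)
                scores[chunk] = p / p.sum(axis=-1, keepdims=True)
        return scores

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        """All trainable tensors (LoRA bases, being plain arrays, excluded)."""
        params = self.encoders.parameters()
        for block in self.causal_blocks:
            params += block.parameters()
        params += self.pcma_block.parameters()
        params += self.coding_head.parameters()
        params += self.severity_head.parameters()
        # deduplicate while preserving order
        seen: set[int] = set()
        unique = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                unique.append(p)
        return unique

    def n_parameters(self) -> int:
        total = sum(p.data.size for p in self.parameters())
        if not self.config.use_pcma:
            total -= sum(p.data.size for p in self.pcma_block.parameters())
        return total

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s

    def clone(self) -> "CodingNetwork":
        return copy.deepcopy(self)
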