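"""Basic trainable layers shared by the attention and fusion blocks."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Linear:
    """Affine map ``y = x @ W.T + b`` with ``W`` of shape (d_out, d_in)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        if scale is None:
            scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(d_out, d_in)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight.swapaxes(-1, -2)
        if self.bias is not None:
            y = y + self.bias
        return y

    def parameters(self) -> list[Tensor]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class LayerNorm:
    """Per-token normalization over the feature axis with learned affine."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class FeedForward:
    """Position-wise two-layer network ``W2·ReLU(W1·x + b1) + b2``."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        if hidden < 1:
            raise ValueError("hidden width must be positive")
        self.w1 = Linear(d, hidden, rng)
        self.w2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(self.w1(x).relu())

    def parameters(self) -> list[Tensor]:
        return self.w1.parameters() + self.w2.parameters()
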