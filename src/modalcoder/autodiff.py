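"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network layers in this package (causal attention, cross-modal fusion,
LoRA adapters, task heads) are small enough that a compact tape-based
engine is sufficient: a :class:`Tensor` wraps an ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` accumulates
gradients by reverse topological traversal.  Broadcasting follows NumPy
semantics; gradients of broadcast operands are summed back to the
operand's shape.

Only the primitives the model needs are implemented.  Each primitive's
backward rule is exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "masked_softmax", "log_softmax", "embedding_take", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g, out):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bwd(g, out):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g, out: (g.reshape(old),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,), lambda g, out: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, idx):
        def bwd(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- reductions & nonlinearities ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g, out: (g * mask,))

    def exp(self):
        def bwd(g, out):
            return (g * out.data,)

        return Tensor._make(np.exp(self.data), (self,), bwd)

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def sqrt(self):
        return self**0.5

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad, node)):
                if not parent.requires_grad or g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None


# -- free functions -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def masked_softmax(logits: Tensor, visible: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to ``visible`` entries.

    Entries where ``visible`` is False receive *exactly* zero probability;
    rows with no visible entry yield the zero vector (no NaN).  The maximum
    over visible entries is subtracted before exponentiation for stability.
    """
    visible = np.broadcast_to(np.asarray(visible, dtype=bool), logits.shape)
    x = np.where(visible, logits.data, -np.inf)
    rowmax = np.max(x, axis=-1, keepdims=True)
    rowmax = np.where(np.isfinite(rowmax), rowmax, 0.0)  # fully-masked rows
    e = np.where(visible, np.exp(x - rowmax), 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    p = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)

    def bwd(g, out):
        gp = g * p
        return (_unbroadcast(p * (g - gp.sum(axis=-1, keepdims=True)), logits.shape),)

    return Tensor._make(p, (logits,), bwd)


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    x = logits.data
    m = x.max(axis=axis, keepdims=True)
    lse = m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))
    out_data = x - lse

    def bwd(g, out):
        p = np.exp(out.data)
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor._make(out_data, (logits,), bwd)


def embedding_take(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids, dtype=np.intp)

    def bwd(g, out):
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        return (full,)

    return Tensor._make(table.data[ids], (table,), bwd)


class Adam:
    """Adaptive-moment gradient descent over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
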