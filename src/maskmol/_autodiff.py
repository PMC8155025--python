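"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the primitives the masked-graph network needs are provided: broadcast
add/multiply, matrix multiply against 2-D weights, sigmoid/tanh/relu,
integer gather, reshape, axis sums, layer normalization and a masked
categorical negative log-likelihood.  Everything runs in float64; gradients
are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter", "add", "mul", "matmul", "sigmoid",
    "tanh", "relu", "take", "reshape", "sum_axis", "layer_norm", "masked_nll",
    "backward",
]


class Tensor:
    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.bwd = bwd  # callable(out_grad) -> tuple of parent grads (or None)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))
    out.bwd = lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))
    out.bwd = lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape),
    )
    return out


def matmul(a: Tensor, w: Tensor) -> Tensor:
    """``a @ w`` with ``w`` strictly 2-D (a may carry leading batch axes)."""
    if w.data.ndim != 2:
        raise ValueError("matmul expects a 2-D right operand")
    out = Tensor(a.data @ w.data, (a, w))

    def bwd(g):
        ga = g @ w.data.T
        a2 = a.data.reshape(-1, a.data.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        return ga, a2.T @ g2

    out.bwd = bwd
    return out


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = Tensor(s, (a,))
    out.bwd = lambda g: (g * s * (1.0 - s),)
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))
    out.bwd = lambda g: (g * (1.0 - t * t),)
    return out


def relu(a: Tensor) -> Tensor:
    m = a.data > 0
    out = Tensor(np.where(m, a.data, 0.0), (a,))
    out.bwd = lambda g: (g * m,)
    return out


def take(a: Tensor, idx: np.ndarray, axis: int = 0) -> Tensor:
    """Integer gather along axis 0 or 1; backward scatter-adds."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(np.take(a.data, idx, axis=axis), (a,))

    def bwd(g):
        ga = np.zeros_like(a.data)
        if axis == 0:
            np.add.at(ga, idx, g)
        elif axis == 1:
            np.add.at(ga, (slice(None), idx), g)
        else:
            raise ValueError("take supports axis 0 or 1")
        return (ga,)

    out.bwd = bwd
    return out


def reshape(a: Tensor, shape: tuple) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))
    out.bwd = lambda g: (g.reshape(a.data.shape),)
    return out


def sum_axis(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    out.bwd = bwd
    return out


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data, (a, gain, bias))

    def bwd(g):
        axes = tuple(range(g.ndim - 1))
        dgain = (g * xhat).sum(axis=axes)
        dbias = g.sum(axis=axes)
        gx = g * gain.data
        da = inv * (
            gx
            - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        )
        return da, dgain, dbias

    out.bwd = bwd
    return out


def masked_nll(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Sum of -log softmax(logits)[target] over slots where ``mask`` is true.

    ``logits``: (..., C); ``targets``/``mask``: (...).  Returns a scalar.
    """
    targets = np.asarray(targets, dtype=np.intp)
    mask = np.asarray(mask, dtype=bool)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - zmax)
    lse = np.log(ez.sum(axis=-1)) + zmax[..., 0]
    picked = np.take_along_axis(z, targets[..., None], axis=-1)[..., 0]
    val = float(((lse - picked) * mask).sum())
    out = Tensor(val, (logits,))

    def bwd(g):
        soft = ez / ez.sum(axis=-1, keepdims=True)
        onehot = np.zeros_like(soft)
        np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
        return (float(g) * (soft - onehot) * mask[..., None],)

    out.bwd = bwd
    return out


def backward(root: Tensor) -> None:
    """Reverse-accumulate gradients from a scalar ``root``."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node.bwd is None or node.grad is None:
            continue
        grads = node.bwd(node.grad)
        for p, g in zip(node.parents, grads):
            if g is None or not p.requires_grad:
                continue
            if p.grad is None:
                p.grad = np.zeros_like(p.data)
            p.grad += g
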