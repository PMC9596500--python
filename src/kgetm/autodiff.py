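"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

This is the numerical core that powers the graph-attention encoder, the
variational encoder and end-to-end ELBO optimisation.  It implements only
the operations those models need (broadcast arithmetic, matmul, gather /
scatter-add for per-node graph aggregation, stable softmax pieces), each
with an explicit backward rule, plus an Adam optimiser.

Gradients are accumulated into ``Tensor.grad`` by ``Tensor.backward()``,
which performs a topological sweep over the recorded computation graph.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather_rows", "scatter_add_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were expanded
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the graph reachable from self
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * scale)

        return self._make(self.data * scale, (self,), backward)

    def maximum(self, other: "Tensor"):
        """Elementwise maximum; ties send the gradient to ``self``."""
        other = self._lift(other)
        take_self = self.data >= other.data
        out_data = np.where(take_self, self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * take_self, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~take_self, other.shape))

        return self._make(out_data, (self, other), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------- softmax utilities
    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logZ = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - logZ
        soft = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        old_shape = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return self._make(out_data, (self,), backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return self._make(self.data.T, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(out_data, (self,), backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ----------------------------------------------------------------- functions
def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]`` (first axis), differentiable in ``t``."""
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, index, g)
            t._accumulate(full)

    return t._make(out_data, (t,), backward)


def scatter_add_rows(t: Tensor, index: np.ndarray, num_rows: int) -> Tensor:
    """Segment sum: ``out[i] = sum over rows j with index[j] == i of t[j]``."""
    index = np.asarray(index, dtype=np.intp)
    out_data = np.zeros((num_rows,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, index, t.data)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g[index])

    return t._make(out_data, (t,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adam with optional decoupled L2 weight decay per parameter group."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.groups: list[dict] = []
        self.add_group(params, lr=lr, weight_decay=weight_decay)
        self.betas = betas
        self.eps = eps
        self.t = 0

    def add_group(self, params: Iterable[Tensor], lr: float,
                  weight_decay: float = 0.0) -> None:
        params = [p for p in params]
        self.groups.append({
            "params": params,
            "lr": lr,
            "weight_decay": weight_decay,
            "m": [np.zeros_like(p.data) for p in params],
            "v": [np.zeros_like(p.data) for p in params],
        })

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for group in self.groups:
            lr, wd = group["lr"], group["weight_decay"]
            for p, m, v in zip(group["params"], group["m"], group["v"]):
                if p.grad is None:
                    continue
                g = p.grad
                if wd:
                    g = g + wd * p.data
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
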