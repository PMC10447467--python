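"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the multi-task imaging network in
:mod:`tmesurv.network`: dense and 2-D convolution layers, the gated-attention
activations (tanh / sigmoid / softmax), pooling, and the reductions needed by
the cross-entropy and Cox partial-likelihood losses. Everything is float64,
which keeps finite-difference gradient checks meaningful.

Usage mirrors the obvious pattern::

    x = Tensor(np.random.randn(4, 3))
    w = Tensor(np.zeros((3, 2)), requires_grad=True)
    loss = (x @ w).sum()
    loss.backward()
    w.grad  # -> dloss/dw
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self._parents = tuple((p, fn) for p, fn in parents if p.requires_grad)

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p, _ in node._parents if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(self.data + other.data, parents=[
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(g, other.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(self.data * other.data, parents=[
            (self, lambda g: _unbroadcast(g * other.data, self.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(self.data / other.data, parents=[
            (self, lambda g: _unbroadcast(g / other.data, self.shape)),
            (other, lambda g: _unbroadcast(-g * self.data / other.data ** 2, other.shape)),
        ])

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        if other.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")

        def grad_a(g):
            return g @ other.data.T

        def grad_b(g):
            a2 = self.data.reshape(-1, self.data.shape[-1])
            g2 = g.reshape(-1, g.shape[-1])
            return a2.T @ g2

        return Tensor(self.data @ other.data, parents=[(self, grad_a), (other, grad_b)])

    # -- elementwise -------------------------------------------------------
    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=[(self, lambda g: g * (1.0 - out ** 2))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(out, parents=[(self, lambda g: g * out * (1.0 - out))])

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=[(self, lambda g: g * out)])

    def log(self):
        return Tensor(np.log(self.data), parents=[(self, lambda g: g / self.data)])

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor(self.data * mask, parents=[(self, lambda g: g * mask)])

    def clip_min(self, low: float):
        """max(x, low); gradient flows only where x > low."""
        mask = (self.data > low).astype(np.float64)
        return Tensor(np.maximum(self.data, low), parents=[(self, lambda g: g * mask)])

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), parents=[(self, lambda g: g.reshape(old))])

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes),
                      parents=[(self, lambda g: g.transpose(inv))])

    def __getitem__(self, idx):
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis))) for p in parts)

        def vjp(g):
            out = np.zeros_like(self.data)
            if basic:
                out[idx] += g        # basic indexing selects disjoint elements
            else:
                np.add.at(out, idx, g)
            return out
        return Tensor(self.data[idx], parents=[(self, vjp)])

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.shape).copy()
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=[(self, vjp)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_last(self):
        """Maximum over the trailing axis (backward routes to the argmax)."""
        arg = np.argmax(self.data, axis=-1)
        out = np.take_along_axis(self.data, arg[..., None], axis=-1)[..., 0]

        def vjp(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
            return gx

        return Tensor(out, parents=[(self, vjp)])

    def softmax(self, axis: int = -1):
        z = self - Tensor(np.max(self.data, axis=axis, keepdims=True))
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=None, keepdims: bool = False):
        m = Tensor(np.max(self.data, axis=axis, keepdims=True))
        shifted = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        if keepdims:
            return shifted
        if axis is None:
            return shifted.reshape(())
        return shifted.reshape(tuple(np.delete(shifted.shape, axis)))

    # -- image ops ---------------------------------------------------------
    def pad2d(self, pad: int):
        if pad == 0:
            return self
        widths = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return Tensor(np.pad(self.data, widths), parents=[(self, lambda g: g[sl])])

    def im2col(self, kernel: int, stride: int):
        """(B, C, H, W) -> patch tensor (B, C, OH, OW, k, k)."""
        b, c, h, w = self.shape
        oh = (h - kernel) // stride + 1
        ow = (w - kernel) // stride + 1
        out = np.empty((b, c, oh, ow, kernel, kernel))
        for di in range(kernel):
            for dj in range(kernel):
                out[..., di, dj] = self.data[:, :, di:di + stride * oh:stride,
                                             dj:dj + stride * ow:stride]

        def vjp(g):
            gx = np.zeros_like(self.data)
            for di in range(kernel):
                for dj in range(kernel):
                    gx[:, :, di:di + stride * oh:stride,
                       dj:dj + stride * ow:stride] += g[..., di, dj]
            return gx

        return Tensor(out, parents=[(self, vjp)])

    def item(self) -> float:
        return float(self.data)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return vjp

    return Tensor(np.concatenate(datas, axis=axis),
                  parents=[(t, make_vjp(i)) for i, t in enumerate(tensors)])


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    def make_vjp(i):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  parents=[(t, make_vjp(i)) for i, t in enumerate(tensors)])


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Standard Adam (Kingma & Ba) on a list of :class:`Parameter`."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
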