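"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoders and loss functions need:
broadcast arithmetic, matmul, elementwise nonlinearities, reductions
(sum/mean/max), row gather, concatenation and clipping. Gradients are
accumulated by topological traversal of the op graph; every op is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather_rows", "gather_axis1",
           "logsumexp", "slice_last", "softmax"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x if x.dtype == np.float64 else x.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return self._make(a * b, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g / b, a.shape), _unbroadcast(-g * a / (b * b), b.shape))

        return self._make(a / b, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self.data

        def backward(g):
            return (g * exponent * np.power(a, exponent - 1),)

        return self._make(np.power(a, exponent), (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(a @ b, (self, other), backward)

    def swapaxes(self, ax1: int, ax2: int):
        return self._make(
            np.swapaxes(self.data, ax1, ax2),
            (self,),
            lambda g: (np.swapaxes(g, ax1, ax2),),
        )

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),))

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        a = self.data
        return self._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (straight-through inside)."""
        a = self.data
        mask = (a >= lo) & (a <= hi)
        return self._make(np.clip(a, lo, hi), (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a_shape = self.data.shape
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a_shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along an axis; ties route gradient to the first argmax."""
        a = self.data
        out_data = a.max(axis=axis, keepdims=keepdims)
        idx = a.argmax(axis=axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            grad = np.zeros_like(a)
            np.put_along_axis(grad, np.expand_dims(idx, axis), g, axis)
            return (grad,)

        return self._make(out_data, (self,), backward)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64, copy=True)
                else:
                    parent.grad += g


def gather_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    """x[indices] for a 2-D source; `indices` may be any shape (output gains its dims).

    Gradient scatter-adds into the source rows.
    """
    indices = np.asarray(indices, dtype=np.intp)
    src_shape = x.data.shape

    def backward(g):
        grad = np.zeros(src_shape)
        np.add.at(grad, indices, g)
        return (grad,)

    return x._make(x.data[indices], (x,), backward)


def gather_axis1(x: Tensor, indices: np.ndarray) -> Tensor:
    """out[b, t, :] = x[b, indices[b, t], :] for a 3-D tensor.

    Gradient scatter-adds back along axis 1.
    """
    indices = np.asarray(indices, dtype=np.intp)
    B = x.data.shape[0]
    bb = np.arange(B)[:, None].repeat(indices.shape[1], axis=1)
    src_shape = x.data.shape

    def backward(g):
        grad = np.zeros(src_shape)
        np.add.at(grad, (bb, indices), g)
        return (grad,)

    return x._make(x.data[bb, indices], (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def slice_last(x: Tensor, start: int, stop: int) -> Tensor:
    """x[..., start:stop]; gradient zero-pads back into the source."""
    src_shape = x.data.shape

    def backward(g):
        grad = np.zeros(src_shape)
        grad[..., start:stop] = g
        return (grad,)

    return x._make(x.data[..., start:stop], (x,), backward)


def logsumexp(x: Tensor, axis: int) -> Tensor:
    """Numerically stable log-sum-exp along `axis` (keeps the axis dropped)."""
    shift = x.data.max(axis=axis, keepdims=True)  # constant w.r.t. grad
    shifted = x - Tensor(shift)
    s = shifted.exp().sum(axis=axis)
    return s.log() + Tensor(np.squeeze(shift, axis=axis))


def softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def clip_grad_norm(self, max_norm: float):
        total = np.sqrt(sum(
            float((p.grad * p.grad).sum()) for p in self.params.values()
            if p.grad is not None
        ))
        if total > max_norm > 0:
            scale = max_norm / total
            for p in self.params.values():
                if p.grad is not None:
                    p.grad *= scale
        return total

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
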