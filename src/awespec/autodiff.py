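"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small dense networks (a few thousand to a few
hundred thousand parameters), trained on CPU in double precision.  A compact
tape-based engine over :class:`numpy.ndarray` is sufficient and keeps the whole
computational graph inspectable: every operation below records its parents and
a closure that maps the output gradient to parent gradients.  Broadcasting
follows numpy semantics; gradients of broadcast operands are sum-reduced back
to the operand shape.

Only the primitives the spectral models need are provided: arithmetic,
(batched) matmul, exp/log/erf, power, reductions (sum/mean/max/min), clipping,
concatenation, reshape, transpose and basic slicing.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "as_tensor", "concat", "maximum_const"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` so it has ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate gradients of a scalar (or given seed) into the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep for long loss pipelines
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other),
                     _backward=lambda g: ((self, _unbroadcast(g, self.shape)),
                                          (other, _unbroadcast(g, other.shape))))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other),
                     _backward=lambda g: ((self, _unbroadcast(g * other.data, self.shape)),
                                          (other, _unbroadcast(g * self.data, other.shape))))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * out_data / other.data, other.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        p = float(exponent)
        out = Tensor(self.data ** p, _parents=(self,),
                     _backward=lambda g: ((self, g * p * self.data ** (p - 1.0)),))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bw(g):
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)
            return ((self, ga), (other, gb))

        return Tensor(a @ b, _parents=(self, other), _backward=bw)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, _parents=(self,),
                      _backward=lambda g: ((self, g * out_data),))

    def log(self):
        return Tensor(np.log(self.data), _parents=(self,),
                      _backward=lambda g: ((self, g / self.data),))

    def erf(self):
        return Tensor(_sp.erf(self.data), _parents=(self,),
                      _backward=lambda g: ((self, g * 2.0 / np.sqrt(np.pi)
                                            * np.exp(-self.data ** 2)),))

    def sqrt(self):
        return self ** 0.5

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return ((self, np.broadcast_to(gg, self.shape).copy()),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def _minmax(self, np_fn, axis, keepdims):
        out_data = np_fn(self.data, axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            od = out_data
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
                od = np.expand_dims(od, axis)
            mask = (self.data == od).astype(float)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            return ((self, mask * gg),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def max(self, axis=None, keepdims: bool = False):
        return self._minmax(np.max, axis, keepdims)

    def min(self, axis=None, keepdims: bool = False):
        return self._minmax(np.min, axis, keepdims)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), _parents=(self,),
                      _backward=lambda g: ((self, g.reshape(old)),))

    def swapaxes(self, a: int, b: int):
        return Tensor(np.swapaxes(self.data, a, b), _parents=(self,),
                      _backward=lambda g: ((self, np.swapaxes(g, a, b)),))

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing by slicing."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return Tensor(data, _parents=tuple(tensors), _backward=bw)


def maximum_const(x: Tensor, c: float) -> Tensor:
    """Elementwise max(x, c) against a constant; gradient flows where x > c."""
    x = as_tensor(x)
    mask = (x.data > c).astype(float)
    return Tensor(np.maximum(x.data, c), _parents=(x,),
                  _backward=lambda g: ((x, g * mask),))
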