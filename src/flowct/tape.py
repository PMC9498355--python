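"""Minimal reverse-mode automatic differentiation over numpy arrays.

The flow layers, the training loss and the latent-space reconstruction
objective are all expressed with :class:`Tensor` operations, so a single
backward pass yields gradients with respect to model parameters (training)
or latent codes (reconstruction).  Only the operations the flow actually
needs are implemented: elementwise arithmetic, sigmoid/relu/exp/log,
axis reductions, reshape/moveaxis/concat/slice, channel-mixing matmul and
stride-1 "same" 3D convolution.

All arithmetic is float64.  Gradients of every op are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Tensor", "as_tensor", "concat", "conv3d", "matmul_last"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operator
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        """Accumulate gradients of `self` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves with no incoming grad keep grad=None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(out_data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g, self.shape),
                                          _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g * other.data, self.shape),
                                          _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: (
                          _unbroadcast(g / other.data, self.shape),
                          _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor(self.data ** p, parents=(self,),
                      backward=lambda g: (g * p * self.data ** (p - 1),))

    # -- nonlinearities --------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      backward=lambda g: (g / self.data,))

    def sigmoid(self):
        out = expit(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return Tensor(np.where(mask, self.data, 0.0), parents=(self,),
                      backward=lambda g: (g * mask,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(out, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), parents=(self,),
                      backward=lambda g: (g.reshape(old),))

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), parents=(self,),
                      backward=lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


def matmul_last(x: Tensor, w: Tensor) -> Tensor:
    """Contract the trailing axis of `x` (..., C) with `w` (C, K) -> (..., K)."""
    x, w = as_tensor(x), as_tensor(w)
    out = x.data @ w.data

    def bwd(g):
        gx = g @ w.data.T
        lead = tuple(range(g.ndim - 1))
        gw = np.tensordot(x.data, g, axes=(lead, lead))
        return gx, gw

    return Tensor(out, parents=(x, w), backward=bwd)


def _conv3d_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 correlation of x (B,D,H,W,Cin) with w (kd,kh,kw,Cin,Cout)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    kd, kh, kw = w.shape[:3]
    win = sliding_window_view(x, (kd, kh, kw), axis=(1, 2, 3))
    # win: (B, D', H', W', Cin, kd, kh, kw)
    return np.tensordot(win, w, axes=([5, 6, 7, 4], [0, 1, 2, 3]))


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' stride-1 3D convolution, channels-last, odd cubic kernels."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    k = w.shape[0]
    pad = (k - 1) // 2
    out = _conv3d_raw(x.data, w.data, pad) + b.data

    def bwd(g):
        # grad wrt input: full correlation with spatially flipped, C-transposed kernel
        w_flip = w.data[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        gx = _conv3d_raw(g, w_flip, k - 1 - pad)
        # grad wrt weights: correlate input windows with output grad
        xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0))) \
            if pad else x.data
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # (B,D,H,W,Cin,kd,kh,kw) x (B,D,H,W,Cout) -> (Cin,kd,kh,kw,Cout)
        gw = np.tensordot(win, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        gw = gw.transpose(1, 2, 3, 0, 4)
        gb = g.sum(axis=(0, 1, 2, 3))
        return gx, gw, gb

    return Tensor(out, parents=(x, w, b), backward=bwd)
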