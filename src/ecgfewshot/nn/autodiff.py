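"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set the package's 1-D signal models need:
broadcasted arithmetic, (batched) matmul, strided 1-D convolution, ReLU,
exp/log/sqrt, reductions, reshapes/transposes and indexing.  Gradients are
kept on every node of the graph, so intermediate activations (e.g. a
convolutional feature map) can be inspected after ``backward`` — which is
what 1-D Grad-CAM relies on.

Arrays keep their floating dtype (models train in float32; float64 inputs
stay float64, which the oracle-equivalence tests rely on).  Gradient
accumulation is ownership-aware: a freshly allocated gradient is adopted
in place, while a shared buffer is only ever read, never mutated.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv1d", "log_softmax", "softmax", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> tuple[np.ndarray, bool]:
    """Sum ``grad`` down to ``shape``; the flag says the result is a fresh array."""
    if grad.shape == shape:
        return grad, False
    extra = grad.ndim - len(shape)
    fresh = False
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
        fresh = True
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
        fresh = True
    return grad.reshape(shape), fresh


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_own_grad")

    def __init__(self, data, requires_grad: bool = False, _prev: Iterable["Tensor"] = ()):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = tuple(_prev)
        self._own_grad = False

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray, own: bool) -> None:
        """Add ``g`` to this node's gradient; ``own`` means ``g`` may be adopted."""
        if self.grad is None:
            self.grad = g
            self._own_grad = own
        elif self._own_grad:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._own_grad = True

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._own_grad = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        if isinstance(other, (int, float, np.floating)):
            # python scalars stay "weak" so float32 graphs are not upcast
            other = float(other)
            out = Tensor(self.data + other, _prev=(self,))

            def _bw():
                self._accum(out.grad, False)

            out._backward = _bw
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            self._accum(*_unbroadcast(out.grad, self.shape))
            other._accum(*_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float, np.floating)):
            other = float(other)
            out = Tensor(self.data * other, _prev=(self,))

            def _bw():
                self._accum(out.grad * other, True)

            out._backward = _bw
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            g, _ = _unbroadcast(out.grad * other.data, self.shape)
            self._accum(g, True)
            g, _ = _unbroadcast(out.grad * self.data, other.shape)
            other._accum(g, True)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        if isinstance(other, (int, float, np.floating)):
            return self + (-float(other))
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, (int, float, np.floating)):
            return self * (1.0 / float(other))
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, _prev=(self,))

        def _bw():
            self._accum(out.grad * (p * self.data ** (p - 1)), True)

        out._backward = _bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw():
            g = out.grad
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(*_true_fresh(_unbroadcast(ga, self.shape)))
            other._accum(*_true_fresh(_unbroadcast(gb, other.shape)))

        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))
        advanced = _is_advanced(idx)

        def _bw():
            g = np.zeros_like(self.data)
            if advanced:
                np.add.at(g, idx, out.grad)
            else:
                g[idx] = out.grad
            self._accum(g, True)

        out._backward = _bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _prev=(self,))

        def _bw():
            self._accum(out.grad * mask, True)

        out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw():
            self._accum(out.grad * out.data, True)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            self._accum(out.grad / self.data, True)

        out._backward = _bw
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions and shape ops ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape), False)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw():
            self._accum(out.grad.reshape(self.shape), False)

        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def _bw():
            self._accum(out.grad.transpose(inv), False)

        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'None'})"


def _true_fresh(pair: tuple[np.ndarray, bool]) -> tuple[np.ndarray, bool]:
    # matmul gradients are always freshly allocated by np.matmul
    g, _ = pair
    return g, True


def _is_advanced(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, (np.ndarray, list)) for i in items)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Strided valid 1-D convolution (cross-correlation).

    ``x``: (B, C_in, T); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    Output: (B, C_out, (T - K)//stride + 1).
    """
    xd, wd = x.data, w.data
    B, Cin, T = xd.shape
    Cout, _, K = wd.shape
    if wd.shape[1] != Cin:
        raise ValueError(f"channel mismatch: x has {Cin}, w expects {wd.shape[1]}")
    Tout = (T - K) // stride + 1
    cols = sliding_window_view(xd, K, axis=2)[:, :, : (Tout - 1) * stride + 1 : stride, :]
    out_data = np.einsum("bctk,ock->bot", cols, wd, optimize=True) + b.data[None, :, None]
    out = Tensor(out_data, _prev=(x, w, b))

    def _bw():
        g = out.grad  # (B, Cout, Tout)
        w._accum(np.einsum("bot,bctk->ock", g, cols, optimize=True), True)
        b._accum(g.sum(axis=(0, 2)), True)
        gx = np.zeros_like(xd)
        for k in range(K):
            # each kernel tap scatters into x at offset k with the conv stride
            gx[:, :, k : k + stride * Tout : stride] += np.einsum(
                "bot,oc->bct", g, wd[:, :, k], optimize=True
            )
        x._accum(gx, True)

    out._backward = _bw
    return out


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along one axis (max-shifted)."""
    shift = np.max(t.data, axis=axis, keepdims=True)
    shifted = t - Tensor(shift)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != (axis % out.ndim)))
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    return t - logsumexp(t, axis=axis, keepdims=True)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(t, axis=axis).exp()
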