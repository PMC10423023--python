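"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float64 numpy
array and records, for every operation, a closure that accumulates the
gradient into its parents. ``backward()`` runs the closures in reverse
topological order. Only the operations needed by the encoders and losses in
this package are provided. Everything is deterministic: no op consults any
global random state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

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
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 60))),
            np.exp(np.clip(self.data, -60, None)) / (1.0 + np.exp(np.clip(self.data, -60, None))),
        )
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        sig = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 60))),
            np.exp(np.clip(self.data, -60, None)) / (1.0 + np.exp(np.clip(self.data, -60, None))),
        )
        return self._make(out_data, (self,), lambda g: (g * sig,))

    # -- reductions and shape ops ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.argmax(self.data, axis=axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(argmax, axis), g, axis=axis)
            return (grad,)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def diagonal(self):
        n = self.data.shape[0]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.fill_diagonal(grad, g)
            return (grad,)

        return self._make(np.diagonal(self.data).copy(), (self,), backward)

    def take_rows(self, idx: np.ndarray):
        """Gather rows (embedding lookup); ``idx`` may be any integer shape."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx.ravel(), g.reshape(-1, self.data.shape[-1]))
            return (grad,)

        return self._make(out_data, (self,), backward)

    def sliding_windows(self, kernel: int):
        """im2col for 'same'-padded 1D convolution.

        Input shape (B, L, E) -> output (B, L, kernel * E), where window t
        covers positions t - k//2 .. t + (k - 1 - k//2), zero-padded.
        """
        B, L, E = self.data.shape
        pad = kernel // 2
        padded = np.zeros((B, L + kernel - 1, E))
        padded[:, pad : pad + L] = self.data
        win = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=1)
        out_data = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, kernel * E)

        def backward(g):
            g = g.reshape(B, L, kernel, E)
            gpad = np.zeros((B, L + kernel - 1, E))
            for t in range(kernel):
                gpad[:, t : t + L] += g[:, :, t]
            return (gpad[:, pad : pad + L],)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1D tensors into a matrix (axis 0)."""
    out_data = np.stack([t.data for t in tensors], axis=0)

    def backward(g):
        return tuple(g[i] for i in range(len(tensors)))

    return Tensor._make(out_data, tuple(tensors), backward)
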