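"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the network needs: broadcasting
arithmetic, 2-D weight matmul with arbitrary leading batch axes,
ReLU/sigmoid/exp/log nonlinearities, axis reductions, reshapes, slicing
along the time axis, a sliding-window unfold for temporal convolution,
and a node-mixing product against a fixed propagation matrix.

Gradients are accumulated into ``Tensor.grad`` by :func:`backward`,
which runs a topological sort of the recorded tape.  Every backward
rule is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "backward"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient tape entry.

    ``requires_grad`` marks leaves (parameters); interior nodes record
    their parents and a closure that maps the output gradient to parent
    gradients.
    """

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
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        data = self.data + other.data

        def bw(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        data = self.data * other.data

        def bw(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), bw)

    __rmul__ = __mul__

    def matmul(self, w: "Tensor") -> "Tensor":
        """``self @ w`` where ``w`` is 2-D and self has any leading axes."""
        w = Tensor._wrap(w)
        data = self.data @ w.data

        def bw(g):
            gx = g @ w.data.T
            x2 = self.data.reshape(-1, self.data.shape[-1])
            g2 = g.reshape(-1, g.shape[-1])
            gw = x2.T @ g2
            return gx, gw

        return Tensor._make(data, (self, w), bw)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g_ = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % len(shape) for a in axes):
                    g_ = np.expand_dims(g_, ax)
            return (np.broadcast_to(g_, shape).copy(),)

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    def slice_axis(self, axis: int, start: int, stop: int) -> "Tensor":
        """Basic slice along one axis; backward pads with zeros."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, stop)
        idx = tuple(idx)
        shape = self.data.shape

        def bw(g):
            gx = np.zeros(shape)
            gx[idx] = g
            return (gx,)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- network-specific ops -------------------------------------------------

    def unfold_time(self, w: int) -> "Tensor":
        """Sliding windows of width ``w`` along axis -2 (time).

        Input ``(..., T, c)`` -> output ``(..., T-w+1, w, c)``.
        """
        T = self.data.shape[-2]
        if T < w:
            raise ValueError(f"time length {T} shorter than kernel width {w}")
        Tp = T - w + 1
        view = np.stack([self.data[..., k:k + Tp, :] for k in range(w)],
                        axis=-2)  # (..., Tp, w, c)
        shape = self.data.shape

        def bw(g):
            gx = np.zeros(shape)
            for k in range(w):
                gx[..., k:k + Tp, :] += g[..., :, k, :]
            return (gx,)

        return Tensor._make(view, (self,), bw)

    def node_mix(self, S: np.ndarray) -> "Tensor":
        """Left-multiply the node axis by a fixed matrix ``S``.

        Input ``(B, n, T, c)`` -> ``S @ f_t`` applied at every timepoint
        and channel.  ``S`` is either one shared ``(n, n)`` operator or a
        per-subject stack ``(B, n, n)``; it carries no gradient (it is
        the normalized adjacency, fixed during training).
        """
        if S.ndim == 2:
            data = np.einsum("ij,bjtc->bitc", S, self.data)

            def bw(g):
                return (np.einsum("ji,bjtc->bitc", S, g),)
        else:
            data = np.einsum("bij,bjtc->bitc", S, self.data)

            def bw(g):
                return (np.einsum("bji,bjtc->bitc", S, g),)

        return Tensor._make(data, (self,), bw)

    def detached(self) -> np.ndarray:
        return self.data


def backward(root: Tensor) -> None:
    """Accumulate gradients of scalar ``root`` into every reachable leaf."""
    if root.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
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
            stack.append((p, False))

    grads: dict[int, np.ndarray] = {id(root): np.ones_like(root.data)}
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.requires_grad:
            node.grad = g if node.grad is None else node.grad + g
        if node._backward is None:
            continue
        for parent, pg in zip(node._parents, node._backward(g)):
            if id(parent) in grads:
                grads[id(parent)] = grads[id(parent)] + pg
            else:
                grads[id(parent)] = pg
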