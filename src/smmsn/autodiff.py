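"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: broadcasting arithmetic,
matrix products, elementwise exp/log/power, axis reductions, transpose,
column-wise concatenation, LeakyReLU and a numerically stable row softmax.
Gradients are accumulated by a topological backward sweep; broadcasting is
undone by summing the upstream gradient over the broadcast axes.

Every tensor holds a dense float array; float32 data stays float32 (the
training loop uses single precision, the unit tests double).  Gradients for
constant operands of a product are never materialized.  There is no graph
reuse between backward calls: build the graph, call ``backward`` once, step
the optimizer, rebuild.  That matches full-batch training, where each epoch
recomputes the whole forward pass anyway.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "leaky_relu", "row_softmax", "log_row_softmax",
           "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        data = np.asarray(data)
        if data.dtype != np.float32:  # default to double except explicit f32
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _lift_like(self, x) -> "Tensor":
        """Lift ``x``, casting constant scalars to this tensor's dtype so a
        python-float coefficient never upcasts a float32 graph."""
        if isinstance(x, Tensor):
            if (x.data.ndim == 0 and not x.requires_grad
                    and x.data.dtype != self.data.dtype):
                return Tensor(x.data.astype(self.data.dtype))
            return x
        arr = np.asarray(x)
        if arr.ndim == 0:
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift_like(other)
        out = Tensor._node(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._node(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift_like(other)
        out = Tensor._node(self.data * other.data, (self, other), None)
        na, nb = self.requires_grad, other.requires_grad

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape) if na else None,
                _unbroadcast(g * self.data, other.shape) if nb else None,
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift_like(other)
        out = Tensor._node(self.data / other.data, (self, other), None)
        na, nb = self.requires_grad, other.requires_grad

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape) if na else None,
                _unbroadcast(-g * self.data / other.data**2, other.shape) if nb else None,
            )

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor._node(self.data**exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(self.data @ other.data, (self, other), None)
        na, nb = self.requires_grad, other.requires_grad

        def backward(g):
            return (g @ other.data.T if na else None,
                    self.data.T @ g if nb else None)

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor._node(val, (self,), None)
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor._node(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    # -- reductions / reshaping -----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor._node(self.data.T, (self,), None)
        out._backward = lambda g: (g.T,)
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = np.asarray(pg)
        # leaves with no interior op (e.g. loss == parameter) are handled above


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` with gradient routing by slice."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor._node(data, tuple(tensors), None)
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    x = Tensor._lift(x)
    dt = x.data.dtype.type
    mask = np.where(x.data > 0, dt(1.0), dt(slope))
    out = Tensor._node(x.data * mask, (x,), None)
    out._backward = lambda g: (g * mask,)
    return out


def row_softmax(logits: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis.

    The row max is subtracted as a constant (softmax is shift invariant, so
    the extra term contributes zero gradient and can be dropped).
    """
    logits = Tensor._lift(logits)
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def log_row_softmax(logits: Tensor) -> Tensor:
    """log softmax over the last axis, stable even where softmax underflows.

    KL-type losses should take log probabilities from here rather than
    ``row_softmax(...).log()``: in single precision a softmax entry can
    underflow to exactly 0, whose log is -inf, while the log-sum-exp form
    stays finite.
    """
    logits = Tensor._lift(logits)
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = shifted.exp().sum(axis=-1, keepdims=True).log()
    return shifted - lse


class Adam:
    """Adam with decoupled L2 weight decay applied through the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
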