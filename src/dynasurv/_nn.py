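"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the two small networks in this package (an Elman
recurrent encoder and a two-layer discrete-time survival head): broadcasting
arithmetic, matmul, tanh/relu, softmax building blocks, masked sums, Adam
with L2 weight decay, and torch-style uniform fan-in initialization so the
architectures behave like their usual deep-learning-library counterparts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "Linear", "concat", "relu", "tanh", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, value, parents=(), backward_fn=None, requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def back(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor(self.value + other.value, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g, out):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        return Tensor(self.value * other.value, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g, out):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        return Tensor(self.value / other.value, (self, other), back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g, out):
            return (g @ other.value.T, self.value.T @ g)

        return Tensor(self.value @ other.value, (self, other), back)

    def sum(self, axis=None, keepdims=False):
        def back(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        def back(g, out):
            return (g * out.value,)

        return Tensor(np.exp(self.value), (self,), back)

    def log(self):
        return Tensor(np.log(self.value), (self,), lambda g, out: (g / self.value,))

    def take(self, rows, cols):
        """Gather self[rows, cols] (used for event-interval log-probabilities)."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)

        def back(g, out):
            full = np.zeros_like(self.value)
            np.add.at(full, (rows, cols), g)
            return (full,)

        return Tensor(self.value[rows, cols], (self,), back)

    # -- reverse pass ----------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.value)
        self.grad = np.ones_like(self.value)
        for t in reversed(order):
            if t.backward_fn is None:
                continue
            grads = t.backward_fn(t.grad, t)
            for p, g in zip(t.parents, grads):
                if p.requires_grad:
                    p.grad = p.grad + g if p.grad is not None else np.asarray(g, dtype=float)


class Parameter(Tensor):
    def __init__(self, value):
        super().__init__(value, requires_grad=True)


def tanh(t: Tensor) -> Tensor:
    out = Tensor(np.tanh(t.value), (t,), None)
    out.backward_fn = lambda g, o: (g * (1.0 - o.value**2),)
    return out


def relu(t: Tensor) -> Tensor:
    return Tensor(np.maximum(t.value, 0.0), (t,), lambda g, o: (g * (t.value > 0),))


def log_softmax(t: Tensor) -> Tensor:
    """Row-wise log-softmax over the last axis (numerically stable)."""
    x = t.value
    m = x.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))
    out_val = x - lse

    def back(g, out):
        p = np.exp(out.value)
        return (g - p * g.sum(axis=-1, keepdims=True),)

    return Tensor(out_val, (t,), back)


def concat(tensors, axis=1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), back)


class Linear:
    """Dense layer with torch-style U(-1/sqrt(fan_in), 1/sqrt(fan_in)) init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(n_in)
        self.W = Parameter(rng.uniform(-k, k, size=(n_in, n_out)))
        self.b = Parameter(rng.uniform(-k, k, size=n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self):
        return [self.W, self.b]


class Adam:
    """Adam with L2 weight decay folded into the gradient (torch semantics)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
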