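"""Minimal reverse-mode automatic differentiation over numpy arrays.

All differentiable math in this package (autoencoders, cross-view
generators, entropy weighting, fuzzy membership, the information-theoretic
fusion loss) is expressed through this module so that a single source of
truth serves both training (gradients) and plain numpy evaluation.

Every helper accepts either a :class:`Tensor` or a plain array-like and
returns the matching kind, so the scientific modules are written once and
run in both worlds. Gradients are accumulated in float64; no broadcasting
rule beyond numpy's is introduced.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "asdata", "is_tensor", "constant", "detach",
    "exp", "log", "tanh", "clip_min", "clip", "asum", "amean",
    "take_rows", "embed_rows", "softmax_rows", "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` fall through to our reflected methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))

        def bw(g):
            self._accumulate(g.T)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # ---- autograd driver -----------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def item(self):
        return float(self.data)

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        od = asdata(other)
        out = Tensor(self.data + od, _parents=_parents(self, other))

        def bw(g):
            self._accumulate(g)
            if isinstance(other, Tensor):
                other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        od = asdata(other)
        out = Tensor(self.data - od, _parents=_parents(self, other))

        def bw(g):
            self._accumulate(g)
            if isinstance(other, Tensor):
                other._accumulate(-g)

        out._backward = bw
        return out

    def __rsub__(self, other):
        od = asdata(other)
        out = Tensor(od - self.data, _parents=(self,))

        def bw(g):
            self._accumulate(-g)

        out._backward = bw
        return out

    def __mul__(self, other):
        od = asdata(other)
        out = Tensor(self.data * od, _parents=_parents(self, other))
        sd = self.data

        def bw(g):
            self._accumulate(g * od)
            if isinstance(other, Tensor):
                other._accumulate(g * sd)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        od = asdata(other)
        out = Tensor(self.data / od, _parents=_parents(self, other))
        sd = self.data

        def bw(g):
            self._accumulate(g / od)
            if isinstance(other, Tensor):
                other._accumulate(-g * sd / (od * od))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        od = asdata(other)
        out = Tensor(od / self.data, _parents=(self,))
        sd = self.data

        def bw(g):
            self._accumulate(-g * od / (sd * sd))

        out._backward = bw
        return out

    def __pow__(self, exponent):
        c = float(exponent)
        out = Tensor(self.data ** c, _parents=(self,))
        sd = self.data

        def bw(g):
            self._accumulate(g * c * sd ** (c - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        od = asdata(other)
        out = Tensor(self.data @ od, _parents=_parents(self, other))
        sd = self.data

        def bw(g):
            self._accumulate(g @ od.T)
            if isinstance(other, Tensor):
                other._accumulate(sd.T @ g)

        out._backward = bw
        return out

    def __rmatmul__(self, other):
        od = asdata(other)
        out = Tensor(od @ self.data, _parents=(self,))

        def bw(g):
            self._accumulate(od.T @ g)

        out._backward = bw
        return out

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def _parents(a, b):
    return (a, b) if isinstance(b, Tensor) else (a,)


# ---- generic helpers (Tensor or ndarray in, same kind out) -------------

def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def asdata(x) -> np.ndarray:
    """Plain float64 view of a Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def constant(x) -> np.ndarray:
    return asdata(x)


def detach(x):
    """Value of ``x`` with the gradient path severed."""
    return asdata(x).copy()


def exp(x):
    if isinstance(x, Tensor):
        out = Tensor(np.exp(x.data), _parents=(x,))
        od = out.data

        def bw(g):
            x._accumulate(g * od)

        out._backward = bw
        return out
    return np.exp(asdata(x))


def log(x):
    if isinstance(x, Tensor):
        out = Tensor(np.log(x.data), _parents=(x,))

        def bw(g):
            x._accumulate(g / x.data)

        out._backward = bw
        return out
    return np.log(asdata(x))


def tanh(x):
    if isinstance(x, Tensor):
        out = Tensor(np.tanh(x.data), _parents=(x,))
        od = out.data

        def bw(g):
            x._accumulate(g * (1.0 - od * od))

        out._backward = bw
        return out
    return np.tanh(asdata(x))


def clip_min(x, lo):
    """Elementwise max(x, lo); subgradient 0 on the clipped set."""
    lo = np.asarray(lo, dtype=np.float64)
    if isinstance(x, Tensor):
        out = Tensor(np.maximum(x.data, lo), _parents=(x,))
        keep = x.data > lo

        def bw(g):
            x._accumulate(g * keep)

        out._backward = bw
        return out
    return np.maximum(asdata(x), lo)


def clip(x, lo, hi):
    return -clip_min(-clip_min(x, lo), -hi)


def asum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(asdata(x), axis=axis, keepdims=keepdims)


def amean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(asdata(x), axis=axis, keepdims=keepdims)


def take_rows(x, idx):
    """Row gather; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)
    if isinstance(x, Tensor):
        out = Tensor(x.data[idx], _parents=(x,))
        shape = x.data.shape

        def bw(g):
            full = np.zeros(shape)
            np.add.at(full, idx, g)
            x._accumulate(full)

        out._backward = bw
        return out
    return asdata(x)[idx]


def embed_rows(x, idx, n_rows):
    """Place the rows of ``x`` at positions ``idx`` of an otherwise-zero
    ``(n_rows, x.shape[1])`` matrix."""
    idx = np.asarray(idx, dtype=np.intp)
    if isinstance(x, Tensor):
        data = np.zeros((n_rows,) + x.data.shape[1:])
        data[idx] = x.data
        out = Tensor(data, _parents=(x,))

        def bw(g):
            x._accumulate(g[idx])

        out._backward = bw
        return out
    xd = asdata(x)
    data = np.zeros((n_rows,) + xd.shape[1:])
    data[idx] = xd
    return data


def softmax_rows(x):
    """Row-wise softmax; the row max is detached for stability."""
    shift = asdata(x).max(axis=-1, keepdims=True)
    e = exp(x - shift)
    return e / asum(e, axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
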