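"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the evidential multiomics network needs:
broadcasting arithmetic, (batched) matmul, the sigmoid/tanh/softplus/relu
nonlinearities, reductions, log/exp, |x|, and the digamma/log-gamma pair
required by the Dirichlet KL penalty.  Gradients are accumulated by a
topological sweep over the recorded computation graph.

Arrays are float64 throughout: the package trades speed for the exactness
its analytic unit tests assert.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._grad_owned = False
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        ub = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            # keep a reference; copy lazily only if a second consumer arrives
            self.grad = ub
            self._grad_owned = ub is not g
        elif self._grad_owned:
            self.grad += ub
        else:
            self.grad = self.grad + ub
            self._grad_owned = True

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- properties --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(g)
            b._accumulate(g)

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(g * b.data)
            b._accumulate(g * a.data)

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            a._accumulate(g / b.data)
            b._accumulate(-g * a.data / (b.data ** 2))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._result(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            ad, bd = a.data, b.data
            a2 = ad.reshape(1, -1) if ad.ndim == 1 else ad
            b2 = bd.reshape(-1, 1) if bd.ndim == 1 else bd
            g2 = np.asarray(g)
            if ad.ndim == 1 and bd.ndim == 1:
                g2 = g2.reshape(1, 1)
            elif ad.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            elif bd.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            if ad.ndim == 1:
                ga = np.squeeze(ga, -2)   # drop the synthetic row axis
            if bd.ndim == 1:
                gb = np.squeeze(gb, -1)   # drop the synthetic column axis
            a._accumulate(ga)
            b._accumulate(gb)

        return Tensor._result(a.data @ b.data, (a, b), backward)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._result(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._result(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._result(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = special.expit(a.data)

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), backward)

    def softplus(self):
        a = self

        def backward(g):
            a._accumulate(g * special.expit(a.data))

        # log1p(exp(x)) computed stably
        return Tensor._result(np.logaddexp(0.0, a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._result(a.data * mask, (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            a._accumulate(g * sign)

        return Tensor._result(np.abs(a.data), (a,), backward)

    def digamma(self):
        a = self

        def backward(g):
            a._accumulate(g * special.polygamma(1, a.data))

        return Tensor._result(special.digamma(a.data), (a,), backward)

    def gammaln(self):
        a = self

        def backward(g):
            a._accumulate(g * special.digamma(a.data))

        return Tensor._result(special.gammaln(a.data), (a,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._result(a.data.reshape(*shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._result(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def expand_dims(self, axis: int):
        a = self

        def backward(g):
            a._accumulate(np.squeeze(g, axis=axis))

        return Tensor._result(np.expand_dims(a.data, axis), (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def stack(tensors: list, axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    parents = [Tensor._lift(t) for t in tensors]

    def backward(g):
        for i, p in enumerate(parents):
            p._accumulate(np.take(g, i, axis=axis))

    data = np.stack([p.data for p in parents], axis=axis)
    return Tensor._result(data, parents, backward)


# -- composites --------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax, fused as one graph node.

    Backward uses the Jacobian-vector identity
    dx = (g - sum(g * y, axis)) * y.
    """
    x = Tensor._lift(x)
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        x._accumulate((g - (g * y).sum(axis=axis, keepdims=True)) * y)

    return Tensor._result(y, (x,), backward)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm


# -- layers ------------------------------------------------------------------

class Linear:
    """Affine map with Glorot-uniform weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            bound = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Adam:
    """Adam with bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1 ** self.t)
            v_hat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
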