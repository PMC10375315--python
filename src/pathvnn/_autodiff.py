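"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the pathway-structured network needs:
broadcast-aware arithmetic, matrix product, tanh/sigmoid/log/power,
axis reductions and concatenation, plus ``Linear`` / ``BatchNorm1d``
layers and an Adam optimizer. Graphs are built define-by-run and freed
after each backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Linear", "BatchNorm1d", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # release graph references eagerly
            node._backward = None
            node._parents = ()

    # -- construction helper -----------------------------------------------
    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._op(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._op(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._op(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._op(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._op(self.data**e, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._op(self.data @ other.data, (self, other), bwd)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y**2))

        return Tensor._op(y, (self,), bwd)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        return Tensor._op(y, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._op(np.log(self.data), (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._op(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


# -- layers --------------------------------------------------------------------


class Linear:
    """Dense layer y = x @ W + b with Kaiming-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(max(n_in, 1))
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(1, n_out)),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization over axis 0 with running statistics for inference."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, n_features)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_features)), requires_grad=True)
        self.running_mean = np.zeros((1, n_features))
        self.running_var = np.ones((1, n_features))
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            n = x.data.shape[0]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            # unbiased variance for the running estimate, as is conventional
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data * n / max(n - 1, 1))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / (
                (Tensor(self.running_var) + self.eps) ** 0.5
            )
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
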