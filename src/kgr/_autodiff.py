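"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine sized for the needs of this package: dense array ops,
broadcasting, flat-index gathers (embedding lookup and im2col convolution),
and the elementwise nonlinearities the link-prediction models use.  Training
runs full batches of a few hundred thousand scalar scores, for which numpy
vectorization is entirely adequate on one CPU.

Gradient correctness is validated against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "spmm", "SGD", "Adagrad", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """A node of the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------

    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, -g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * self.data / (other.data**2), other.data.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g: np.ndarray) -> None:
            a, b = self.data, other.data
            ga = g @ b.swapaxes(-1, -2)
            gb = a.swapaxes(-1, -2) @ g
            _accum(self, _unbroadcast(ga, a.shape))
            _accum(other, _unbroadcast(gb, b.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    def pow(self, exponent: float) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bw)

    def abs(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, g * np.sign(self.data))

        return Tensor(np.abs(self.data), parents=(self,), backward=bw)

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)

        def bw(g: np.ndarray) -> None:
            _accum(self, g * 0.5 / np.maximum(out, 1e-300))

        return Tensor(out, parents=(self,), backward=bw)

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accum(self, np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bw(g: np.ndarray) -> None:
            _accum(self, g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def concat(self, other: "Tensor", axis: int = 0) -> "Tensor":
        other = Tensor._lift(other)
        n = self.data.shape[axis]

        def bw(g: np.ndarray) -> None:
            ga, gb = np.split(g, [n], axis=axis)
            _accum(self, ga)
            _accum(other, gb)

        return Tensor(np.concatenate([self.data, other.data], axis=axis), parents=(self, other), backward=bw)

    def take_flat(self, idx: np.ndarray) -> "Tensor":
        """Gather from the flattened array; backward scatter-adds."""
        idx = np.asarray(idx)

        def bw(g: np.ndarray) -> None:
            full = np.zeros(self.data.size)
            np.add.at(full, idx.ravel(), g.ravel())
            _accum(self, full.reshape(self.data.shape))

        return Tensor(self.data.ravel()[idx], parents=(self,), backward=bw)

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Gather rows of a 2-D array (embedding lookup)."""
        idx = np.asarray(idx)

        def bw(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx.ravel(), g.reshape(-1, self.data.shape[1]))
            _accum(self, full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g: np.ndarray) -> None:
            _accum(self, g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def bw(g: np.ndarray) -> None:
            _accum(self, g * (1.0 - out**2))

        return Tensor(out, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g: np.ndarray) -> None:
            _accum(self, g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bw(g: np.ndarray) -> None:
            _accum(self, g * out)

        return Tensor(out, parents=(self,), backward=bw)

    def cos(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, -g * np.sin(self.data))

        return Tensor(np.cos(self.data), parents=(self,), backward=bw)

    def sin(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            _accum(self, g * np.cos(self.data))

        return Tensor(np.sin(self.data), parents=(self,), backward=bw)

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), numerically stable; derivative is the sigmoid."""
        out = np.logaddexp(0.0, self.data)

        def bw(g: np.ndarray) -> None:
            _accum(self, g / (1.0 + np.exp(-np.clip(self.data, -500, 500))))

        return Tensor(out, parents=(self,), backward=bw)

    def dropout(self, rate: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)

        def bw(g: np.ndarray) -> None:
            _accum(self, g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    # -- backward pass -----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad = t.grad + g


def spmm(A, x: Tensor) -> Tensor:
    """Sparse(constant) @ dense(Tensor) product; backward uses Aᵀ."""

    def bw(g: np.ndarray) -> None:
        _accum(x, A.T @ g)

    return Tensor(A @ x.data, parents=(x,), backward=bw)


class SGD:
    """Plain stochastic gradient descent over a parameter list."""

    def __init__(self, params: Iterable[Tensor], lr: float) -> None:
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adagrad:
    """Adagrad: per-coordinate learning rates from accumulated squared grads."""

    def __init__(self, params: Iterable[Tensor], lr: float, eps: float = 1e-10) -> None:
        self.params = list(params)
        self.lr = lr
        self.eps = eps
        self.acc = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.acc[i] += p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(self.acc[i]) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
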