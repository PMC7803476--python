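"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the sequence labeler needs: broadcasting
add/mul, matmul, tanh/sigmoid/exp/log, reductions, concatenation, advanced
indexing (with scatter-add backward, so embedding lookups and CRF path
scores differentiate correctly), a numerically stable log-sum-exp, and a
stable binary cross-entropy-with-logits primitive.  Everything is float64:
the networks here are small and the CRF tests check partition functions to
1e-9.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, list]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum out broadcast axes so grad matches the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _children: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(c.requires_grad for c in _children)
        self.grad: Optional[np.ndarray] = None
        self._children = _children
        self._backward = _backward

    # -- graph machinery ---------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._children:
                stack.append((child, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(value: Union["Tensor", ArrayLike]) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _children=(self, other))

        def backward(grad):
            self._accumulate(_unbroadcast(grad, self.data.shape))
            other._accumulate(_unbroadcast(grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _children=(self,))
        out._backward = lambda grad: self._accumulate(-grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _children=(self, other))

        def backward(grad):
            self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _children=(self,))
        out._backward = lambda grad: self._accumulate(
            grad * exponent * self.data ** (exponent - 1.0)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _children=(self, other))

        def backward(grad):
            self._accumulate(grad @ other.data.T)
            other._accumulate(self.data.T @ grad)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, _children=(self,))
        out._backward = lambda grad: self._accumulate(grad * (1.0 - value**2))
        return out

    def sigmoid(self):
        value = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(value, _children=(self,))
        out._backward = lambda grad: self._accumulate(grad * value * (1.0 - value))
        return out

    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, _children=(self,))
        out._backward = lambda grad: self._accumulate(grad * value)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _children=(self,))
        out._backward = lambda grad: self._accumulate(grad / self.data)
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int):
        out = Tensor(self.data.reshape(shape), _children=(self,))
        out._backward = lambda grad: self._accumulate(grad.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _children=(self,))
        out._backward = lambda grad: self._accumulate(grad.T)
        return out

    def __getitem__(self, index):
        out = Tensor(self.data[index], _children=(self,))

        def backward(grad):
            full = np.zeros_like(self.data)
            np.add.at(full, index, grad)
            self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis: Optional[int] = None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _children=(self,))

        def backward(grad):
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis: Optional[int] = None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def logsumexp(self, axis: int, keepdims: bool = False):
        peak = self.data.max(axis=axis, keepdims=True)
        value = peak + np.log(np.exp(self.data - peak).sum(axis=axis, keepdims=True))
        softmax = np.exp(self.data - value)
        squeezed = value if keepdims else np.squeeze(value, axis=axis)
        out = Tensor(squeezed, _children=(self,))

        def backward(grad):
            if not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(grad * softmax)

        out._backward = backward
        return out

    def softmax(self, axis: int):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _children=tuple(tensors),
    )

    def backward(grad):
        offset = 0
        for t in tensors:
            width = t.data.shape[axis]
            index = [slice(None)] * grad.ndim
            index[axis] = slice(offset, offset + width)
            t._accumulate(grad[tuple(index)])
            offset += width

    out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, numerically stable."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), _children=(logits,))
    sig = 0.5 * (1.0 + np.tanh(0.5 * z))

    def backward(grad):
        logits._accumulate(grad * (sig - y) / y.size)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 0.001,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, frozen: Sequence[Tensor] = ()) -> None:
        frozen_ids = {id(p) for p in frozen}
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None or id(p) in frozen_ids:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
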