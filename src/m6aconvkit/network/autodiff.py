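"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the classifiers need: broadcasting
arithmetic, 2-D matmul, valid-padding 1-D convolution, the usual
activations, reductions, reshape/concat/indexing and a numerically
stable softmax. Gradients are accumulated by topological traversal.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

GradFn = Callable[[np.ndarray], np.ndarray]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(
        self,
        data: np.ndarray | float,
        parents: tuple[tuple["Tensor", GradFn], ...] = (),
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this node (seeded with ones)."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs from the LSTM loop are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                contribution = grad_fn(node.grad)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += contribution

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):  # noqa: D105
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):  # noqa: D105
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):  # noqa: D105
        return mul(self, -1.0)

    def __sub__(self, other):  # noqa: D105
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):  # noqa: D105
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):  # noqa: D105
        return matmul(self, other)

    def __getitem__(self, index):  # noqa: D105
        return getitem(self, index)

    def __repr__(self) -> str:  # noqa: D105
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data + b.data,
        parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data * b.data,
        parents=(
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor(
        a.data @ b.data,
        parents=(
            (a, lambda g: g @ b.data.T),
            (b, lambda g: a.data.T @ g),
        ),
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-padding 1-D convolution.

    ``x``: (batch, T, in_channels); ``w``: (kernel, in_channels,
    out_channels); ``b``: (out_channels,). Output: (batch, T-kernel+1,
    out_channels).
    """
    kernel = w.data.shape[0]
    t_out = x.data.shape[1] - kernel + 1
    if t_out < 1:
        raise ValueError(
            f"kernel size {kernel} too large for input length {x.data.shape[1]}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x.data, kernel, axis=1)
    # windows: (batch, t_out, in_channels, kernel)
    out = np.einsum("btck,kco->bto", windows, w.data, optimize=True) + b.data

    def grad_x(g: np.ndarray) -> np.ndarray:
        gw = np.einsum("bto,kco->btkc", g, w.data, optimize=True)
        gx = np.zeros_like(x.data)
        for k in range(kernel):
            gx[:, k : k + t_out, :] += gw[:, :, k, :]
        return gx

    return Tensor(
        out,
        parents=(
            (x, grad_x),
            (w, lambda g: np.einsum("btck,bto->kco", windows, g, optimize=True)),
            (b, lambda g: g.sum(axis=(0, 1))),
        ),
    )


def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    return Tensor(np.maximum(x.data, 0.0), parents=((x, lambda g: g * (x.data > 0)),))


def sigmoid(x: Tensor) -> Tensor:
    x = _wrap(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    return Tensor(s, parents=((x, lambda g: g * s * (1.0 - s)),))


def tanh(x: Tensor) -> Tensor:
    x = _wrap(x)
    t = np.tanh(x.data)
    return Tensor(t, parents=((x, lambda g: g * (1.0 - t * t)),))


def log(x: Tensor) -> Tensor:
    x = _wrap(x)
    return Tensor(np.log(x.data), parents=((x, lambda g: g / x.data),))


def tsum(x: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)

    def grad(g: np.ndarray) -> np.ndarray:
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, x.data.shape).copy()

    return Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=((x, grad),))


def tmean(x: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    count = x.data.size if axis is None else x.data.shape[axis]
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = _wrap(x)
    return Tensor(x.data.reshape(shape), parents=((x, lambda g: g.reshape(x.data.shape)),))


def getitem(x: Tensor, index) -> Tensor:
    x = _wrap(x)

    def grad(g: np.ndarray) -> np.ndarray:
        gx = np.zeros_like(x.data)
        np.add.at(gx, index, g)
        return gx

    return Tensor(x.data[index], parents=((x, grad),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i: int) -> GradFn:
        def grad(g: np.ndarray) -> np.ndarray:
            slicer = [slice(None)] * g.ndim
            slicer[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(slicer)]

        return grad

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple((t, make_grad(i)) for i, t in enumerate(tensors)),
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _wrap(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def grad(g: np.ndarray) -> np.ndarray:
        return s * (g - (g * s).sum(axis=axis, keepdims=True))

    return Tensor(s, parents=((x, grad),))


def binary_cross_entropy(prob: Tensor, targets: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean BCE; probabilities are squeezed into [eps, 1-eps] for stability."""
    y = np.asarray(targets, dtype=np.float64)
    p = add(mul(prob, 1.0 - 2.0 * eps), eps)
    losses = add(mul(Tensor(y), log(p)), mul(Tensor(1.0 - y), log(add(mul(p, -1.0), 1.0))))
    return mul(tmean(losses), -1.0)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
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
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * p.grad
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * p.grad**2
            m_hat = self._m[i] / (1 - self.beta1**self.t)
            v_hat = self._v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
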