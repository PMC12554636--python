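"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small and dense (a few hundred nodes, feature
widths in the tens to low hundreds), so a compact tape-based engine over
``numpy.ndarray`` is sufficient: every differentiable operation the encoders,
fusion gate and decoder need is provided here, together with an AdamW
optimizer. Gradients are exact (validated against central finite differences
in the test suite).

Functions in this module dispatch on their argument type: given a
:class:`Tensor` they build the tape, given a plain ``ndarray`` they compute
the same value eagerly in numpy. This lets every model operation double as
its own inference-mode implementation.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "softmax",
    "concat",
    "dropout",
    "sum_",
    "mean",
    "take_rows",
    "bce_with_logits",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape.

    Parameters
    ----------
    data:
        The value, coerced to a float64 array.
    requires_grad:
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order by depth-first traversal
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = _bw
        return out

    def reshape(self, *shape) -> "Tensor":
        out = _make(self.data.reshape(*shape), (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        out._backward = _bw
        return out

    @property
    def T(self) -> "Tensor":
        out = _make(self.data.T, (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad.T)

        out._backward = _bw
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    grads_needed = any(p.requires_grad for p in parents)
    out.requires_grad = grads_needed
    if grads_needed:
        out._parents = tuple(parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Create a trainable tensor; with ``rng`` draws Glorot-style init."""
    if rng is not None:
        shape = tuple(data) if isinstance(data, (tuple, list)) else data
        if scale is None:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            fan_out = shape[-1]
            scale = float(np.sqrt(2.0 / (fan_in + fan_out)))
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops (Tensor/ndarray dual dispatch)
# ---------------------------------------------------------------------------


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def matmul(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data @ b.data, (a, b))

    def _bw():
        if a.requires_grad:
            a._accumulate(out.grad @ b.data.T if b.data.ndim > 1 else np.outer(out.grad, b.data))
        if b.requires_grad:
            b._accumulate(a.data.T @ out.grad if a.data.ndim > 1 else np.outer(a.data, out.grad))

    out._backward = _bw
    return out


def relu(x):
    if not _is_tensor(x):
        return np.maximum(np.asarray(x, dtype=np.float64), 0.0)
    x = as_tensor(x)
    out = _make(np.maximum(x.data, 0.0), (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0.0))

    out._backward = _bw
    return out


def identity(x):
    return x


def tanh(x):
    if not _is_tensor(x):
        return np.tanh(np.asarray(x, dtype=np.float64))
    x = as_tensor(x)
    val = np.tanh(x.data)
    out = _make(val, (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * (1.0 - val**2))

    out._backward = _bw
    return out


def sigmoid(x):
    if not _is_tensor(x):
        from scipy.special import expit

        return expit(np.asarray(x, dtype=np.float64))
    x = as_tensor(x)
    from scipy.special import expit

    val = expit(x.data)
    out = _make(val, (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * val * (1.0 - val))

    out._backward = _bw
    return out


def exp(x):
    if not _is_tensor(x):
        return np.exp(np.asarray(x, dtype=np.float64))
    x = as_tensor(x)
    val = np.exp(x.data)
    out = _make(val, (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * val)

    out._backward = _bw
    return out


def log(x):
    if not _is_tensor(x):
        return np.log(np.asarray(x, dtype=np.float64))
    x = as_tensor(x)
    out = _make(np.log(x.data), (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad / x.data)

    out._backward = _bw
    return out


def softmax(x, axis: int = -1):
    """Numerically stable softmax along ``axis``."""
    if not _is_tensor(x):
        from scipy.special import softmax as sp_softmax

        return sp_softmax(np.asarray(x, dtype=np.float64), axis=axis)
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)
    out = _make(val, (x,))

    def _bw():
        if x.requires_grad:
            g = out.grad
            dot = (g * val).sum(axis=axis, keepdims=True)
            x._accumulate(val * (g - dot))

    out._backward = _bw
    return out


def concat(xs: Iterable, axis: int = -1):
    xs = list(xs)
    if not _is_tensor(*xs):
        return np.concatenate([np.asarray(x) for x in xs], axis=axis)
    ts = [as_tensor(x) for x in xs]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = _bw
    return out


def sum_(x, axis=None):
    if not _is_tensor(x):
        return np.asarray(x).sum(axis=axis)
    x = as_tensor(x)
    out = _make(x.data.sum(axis=axis), (x,))

    def _bw():
        if x.requires_grad:
            g = out.grad
            if axis is not None:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.shape).copy())

    out._backward = _bw
    return out


def mean(x, axis=None):
    if not _is_tensor(x):
        return np.asarray(x).mean(axis=axis)
    x = as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return sum_(x, axis=axis) * (1.0 / n)


def take_rows(x, idx):
    """Row gather; gradient scatter-adds (duplicate indices supported)."""
    idx = np.asarray(idx)
    if not _is_tensor(x):
        return np.asarray(x)[idx]
    return as_tensor(x)[idx]


def dropout(x, rate: float, rng: np.random.Generator | None, training: bool):
    """Inverted dropout: scales kept units by 1/(1-rate) during training."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    shape = x.shape if isinstance(x, Tensor) else np.asarray(x).shape
    mask = (rng.random(shape) >= rate) / (1.0 - rate)
    if isinstance(x, Tensor):
        return x * Tensor(mask)
    return np.asarray(x) * mask


def bce_with_logits(logits, labels):
    """Mean binary cross-entropy computed stably in logit space.

    Uses ``max(z, 0) - z*y + log1p(exp(-|z|))`` so no finite logit can
    overflow or produce log(0).
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("bce_with_logits requires a non-empty batch")
    if not _is_tensor(logits):
        z = np.asarray(logits, dtype=np.float64)
        return float(np.mean(np.maximum(z, 0) - z * labels + np.log1p(np.exp(-np.abs(z)))))
    logits = as_tensor(logits)
    z = logits.data
    val = np.mean(np.maximum(z, 0) - z * labels + np.log1p(np.exp(-np.abs(z))))
    out = _make(np.asarray(val), (logits,))

    def _bw():
        if logits.requires_grad:
            from scipy.special import expit

            logits._accumulate(out.grad * (expit(z) - labels) / labels.size)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class AdamW:
    """Adam with decoupled weight decay.

    Defaults follow the common (0.9, 0.999) moment schedule; ``lr`` and
    ``weight_decay`` are the two knobs the training protocol specifies.
    """

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 2e-3,
        weight_decay: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
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
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g**2
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)
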