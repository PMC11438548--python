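"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Exactly the operations the pair-classification network needs: dense linear
algebra, elementwise nonlinearities, row gathering and segment reduction
(for attention softmax over neighborhoods and deep-set pooling), and a
numerically stable binary cross-entropy on logits.  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


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
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        # each parent is (Tensor, fn(upstream_grad) -> grad contribution)
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return Tensor(
            self.data / other.data,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ),
        )

    def __matmul__(self, other):
        other = Tensor._lift(other)
        return Tensor(
            self.data @ other.data,
            parents=(
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ),
        )

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, parents=((self, back),))

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    # -- backward pass ---------------------------------------------------

    def backward(self):
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
            for p, _ in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(node.grad)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += contrib


# -- elementwise nonlinearities ------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    factor = np.where(mask, 1.0, slope)
    return Tensor(x.data * factor, parents=((x, lambda g: g * factor),))


def elu(x: Tensor) -> Tensor:
    ex = np.exp(np.minimum(x.data, 0.0))
    out = np.where(x.data > 0, x.data, ex - 1.0)
    deriv = np.where(x.data > 0, 1.0, ex)
    return Tensor(out, parents=((x, lambda g: g * deriv),))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    return Tensor(s, parents=((x, lambda g: g * s * (1 - s)),))


def exp(x: Tensor) -> Tensor:
    ex = np.exp(x.data)
    return Tensor(ex, parents=((x, lambda g: g * ex),))


# -- structural ops -------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def make_back(i):
        def back(g):
            return np.split(g, splits, axis=axis)[i]

        return back

    return Tensor(
        np.concatenate(datas, axis=axis),
        parents=tuple((t, make_back(i)) for i, t in enumerate(tensors)),
    )


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)

    def back(g):
        out = np.zeros_like(x.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(x.data[idx], parents=((x, back),))


def segment_sum(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=int)
    out = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out, segments, x.data)
    return Tensor(out, parents=((x, lambda g: g[segments]),))


def segment_softmax(scores: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of per-row scores within each segment (attention coefficients).

    The per-segment max is treated as a constant shift, which leaves the
    softmax value and its gradient unchanged while keeping the exponentials
    bounded.
    """
    segments = np.asarray(segments, dtype=int)
    seg_max = np.full((n_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segments, scores.data)
    shifted = scores + Tensor(-seg_max[segments])
    ex = exp(shifted)
    denom = segment_sum(ex, segments, n_segments)
    return ex / gather_rows(denom, segments)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    loss_i = max(z,0) - z*y + log(1 + exp(-|z|)); the gradient wrt the
    logit is sigmoid(z) - y, applied analytically.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    s = 1.0 / (1.0 + np.exp(-z))
    n = z.size
    return Tensor(per.mean(), parents=((logits, lambda g: g * (s - y) / n),))


# -- parameters and optimization ------------------------------------------


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class Adam:
    """Adam with decoupled weight decay (the AdamW formulation)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )
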