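"""A compact reverse-mode automatic-differentiation core over numpy arrays.

The segmentation network needs gradients through dense linear maps, pointwise
nonlinearities, gathers along ragged neighborhoods, and segment reductions
(weighted sums, softmax, max). This module provides exactly those primitives
on a :class:`Tensor` wrapper plus an AdamW optimizer; everything runs in
float64 on a single CPU core, which is the scale the toolkit targets.

Only operations the network uses are implemented — this is not a general
deep-learning framework.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An ndarray with a gradient tape entry.

    ``parents`` is a list of ``(tensor, grad_fn)`` pairs, where ``grad_fn``
    maps the upstream gradient to this parent's gradient contribution.
    """

    __slots__ = ("value", "grad", "requires_grad", "parents")

    def __init__(self, value, requires_grad: bool = False, parents=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self.parents = parents or []

    @property
    def shape(self):
        return self.value.shape

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` tensor."""
        if seed is None:
            seed = np.ones_like(self.value)
        # topological order via iterative DFS
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
            for parent, _ in node.parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, grad_fn in node.parents:
                pg = grad_fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def parameter(value, rng: np.random.Generator | None = None,
              scale: float | None = None) -> Tensor:
    """A trainable tensor. With ``rng`` given, ``value`` is a shape tuple and
    the tensor is He-initialized (``scale`` overrides the variance)."""
    if rng is not None:
        shape = tuple(value)
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        sd = scale if scale is not None else np.sqrt(2.0 / fan_in)
        value = rng.normal(0.0, sd, size=shape)
    return Tensor(value, requires_grad=True)


def _track(x: Tensor) -> bool:
    return x.requires_grad or bool(x.parents)


def _make(value, parents):
    parents = [(p, fn) for p, fn in parents if _track(p)]
    return Tensor(value, parents=parents)


def constant(value) -> Tensor:
    return Tensor(value)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    av, bv = a.value, b.value
    return _make(av @ bv, [(a, lambda g: g @ bv.T), (b, lambda g: av.T @ g)])


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.value + b.value,
                 [(a, lambda g: _unbroadcast(g, a.value.shape)),
                  (b, lambda g: _unbroadcast(g, b.value.shape))])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.value - b.value,
                 [(a, lambda g: _unbroadcast(g, a.value.shape)),
                  (b, lambda g: _unbroadcast(-g, b.value.shape))])


def mul(a: Tensor, b: Tensor) -> Tensor:
    av, bv = a.value, b.value
    return _make(av * bv,
                 [(a, lambda g: _unbroadcast(g * bv, av.shape)),
                  (b, lambda g: _unbroadcast(g * av, bv.shape))])


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0
    return _make(a.value * mask, [(a, lambda g: g * mask)])


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    values = [t.value for t in tensors]
    out = np.concatenate(values, axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        width = t.value.shape[axis]
        lo, hi = offset, offset + width
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(lo, hi)
        parents.append((t, lambda g, sl=tuple(sl): g[sl]))
        offset += width
    return _make(out, parents)


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)

    def grad_fn(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return out

    return _make(a.value[idx], [(a, grad_fn)])


def segment_sum(a: Tensor, seg: np.ndarray, n_segments: int,
                weights: np.ndarray | None = None) -> Tensor:
    """``out[s] = sum_{e: seg[e]=s} w[e] * a[e]`` with constant weights."""
    seg = np.asarray(seg, dtype=np.int64)
    av = a.value
    wa = av if weights is None else av * weights[:, None]
    out = np.zeros((n_segments,) + av.shape[1:])
    np.add.at(out, seg, wa)

    def grad_fn(g):
        ge = g[seg]
        return ge if weights is None else ge * weights[:, None]

    return _make(out, [(a, grad_fn)])


def segment_max(a: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Channel-wise max over segments; gradient split equally among ties."""
    seg = np.asarray(seg, dtype=np.int64)
    av = a.value
    out = np.full((n_segments,) + av.shape[1:], -np.inf)
    np.maximum.at(out, seg, av)
    winners = av == out[seg]
    counts = np.zeros_like(out)
    np.add.at(counts, seg, winners.astype(np.float64))

    def grad_fn(g):
        return (g / np.maximum(counts, 1.0))[seg] * winners

    return _make(out, [(a, grad_fn)])


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of per-edge scores within each segment. ``scores`` is (E,)."""
    seg = np.asarray(seg, dtype=np.int64)
    sv = scores.value
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, seg, sv)
    e = np.exp(sv - seg_max[seg])
    denom = np.zeros(n_segments)
    np.add.at(denom, seg, e)
    w = e / denom[seg]

    def grad_fn(g):
        dot = np.zeros(n_segments)
        np.add.at(dot, seg, w * g)
        return w * (g - dot[seg])

    return _make(w, [(scores, grad_fn)])


def rowsum(a: Tensor, keepdims: bool = False) -> Tensor:
    out = a.value.sum(axis=1, keepdims=keepdims)

    def grad_fn(g):
        if not keepdims:
            g = g[:, None]
        return np.broadcast_to(g, a.value.shape).copy()

    return _make(out, [(a, grad_fn)])


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits.

    Returned separately from the tape: callers pass the gradient to
    ``logits.backward``.
    """
    z = logits.value
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, c = z.shape
    w = np.ones(n) if class_weights is None else class_weights[labels]
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = float(-(w * logp[np.arange(n), labels]).sum() / w.sum())
    grad = p * w[:, None]
    grad[np.arange(n), labels] -= w
    grad /= w.sum()
    return loss, grad


class AdamW:
    """Decoupled-weight-decay Adam over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.value -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                             + self.weight_decay * p.value)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
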