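"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the quasi-DenseNet: stride-1 "same" convolutions
(im2col + BLAS matmul), batch normalization, ReLU, ceil-mode average pooling,
channel concatenation, global average pooling, dense layers, dropout and a
weighted sigmoid binary cross-entropy. Float32 throughout.

A :class:`Var` wraps an array plus a backward closure; calling
:func:`backward` on the scalar loss topologically propagates gradients into
every reachable :class:`Var`. Parameters are ordinary ``Var`` objects marked
``trainable`` and reused across forward passes.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Var", "backward", "conv2d", "batchnorm", "relu", "avg_pool_ceil",
           "concat", "global_avg_pool", "dense", "dropout", "sigmoid",
           "sigmoid_bce", "Adam"]


class Var:
    """A node in the computation graph: value, gradient slot, backward closure."""

    __slots__ = ("value", "grad", "_parents", "_bw", "trainable", "name")

    def __init__(self, value, parents=(), bw=None, trainable=False, name=""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._bw = bw  # fn(grad_out) -> iterable of grads aligned with parents
        self.trainable = trainable
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    @property
    def size(self):
        return self.value.size


def backward(loss: Var) -> None:
    """Backpropagate from a scalar loss, accumulating ``.grad`` on all nodes."""
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:  # iterative topo sort; graphs are deep for dense nets
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    for node in order:
        node.grad = None
    loss.grad = np.ones_like(loss.value)
    for node in reversed(order):
        if node._bw is None or node.grad is None:
            continue
        for parent, g in zip(node._parents, node._bw(node.grad)):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = g.astype(np.float32, copy=False)
            else:
                parent.grad = parent.grad + g


def conv2d(x: Var, w: Var, b: Var | None, padding: str = "same") -> Var:
    """Stride-1 2-D convolution (cross-correlation); ``w`` is (F, C, kh, kw).

    Computed as a sum of per-tap matrix products in channels-last layout —
    no im2col column matrix is materialized, keeping the backward cache to
    the (padded) input itself. The gradient w.r.t. the input is skipped when
    the input is a graph leaf (saves the largest backward product on the
    first layer).
    """
    f, c, kh, kw = w.shape
    ph, pw = ((kh - 1) // 2, (kw - 1) // 2) if padding == "same" else (0, 0)
    xv = x.value
    if ph or pw:
        xv = np.pad(xv, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # channels-last, contiguous: per-tap slices feed BLAS without 9x expansion
    xp = np.ascontiguousarray(xv.transpose(0, 2, 3, 1))  # (n, hp, wp, c)
    n, hp, wp, _ = xp.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    out = np.zeros((n, ho, wo, f), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i : i + ho, j : j + wo, :] @ w.value[:, :, i, j].T
    if b is not None:
        out += b.value
    need_dx = x.trainable or x._bw is not None or len(x._parents) > 0

    def bw(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (n, ho, wo, f)
        gm = gl.reshape(-1, f)
        dw = np.empty_like(w.value)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, i : i + ho, j : j + wo, :].reshape(-1, c)
                dw[:, :, i, j] = gm.T @ xs
        db = gm.sum(axis=0) if b is not None else None
        dx = None
        if need_dx:
            dxp = np.zeros((n, hp, wp, c), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + ho, j : j + wo, :] += gl @ w.value[:, :, i, j]
            dxp = dxp.transpose(0, 3, 1, 2)
            dx = dxp[:, :, ph : ph + ho, pw : pw + wo] if (ph or pw) else dxp
            dx = np.ascontiguousarray(dx)
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Var(out.transpose(0, 3, 1, 2), parents, bw)


def batchnorm(x: Var, gamma: Var, beta: Var, running_mean: np.ndarray,
              running_var: np.ndarray, training: bool, momentum: float = 0.9,
              eps: float = 1e-3) -> Var:
    """Batch normalization over all axes except the channel axis.

    Channel axis is 1 for 4-D inputs (N,C,H,W) and the last axis for 2-D
    inputs (N,F). ``running_mean``/``running_var`` are updated in place
    during training and used verbatim at inference.
    """
    axes = (0, 2, 3) if x.value.ndim == 4 else (0,)
    cshape = (1, -1, 1, 1) if x.value.ndim == 4 else (1, -1)
    if training:
        mean = x.value.mean(axis=axes)
        var = x.value.var(axis=axes)
        running_mean *= momentum
        running_mean += (1 - momentum) * mean
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.value - mean.reshape(cshape)) * inv_std.reshape(cshape)
    out = gamma.value.reshape(cshape) * xhat + beta.value.reshape(cshape)

    m = x.value.size / mean.size  # samples per channel

    def bw(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        gs = g * gamma.value.reshape(cshape)
        if training:
            dx = (inv_std.reshape(cshape) / m) * (
                m * gs
                - gs.sum(axis=axes).reshape(cshape)
                - xhat * (gs * xhat).sum(axis=axes).reshape(cshape)
            )
        else:
            dx = gs * inv_std.reshape(cshape)
        return dx, dgamma, dbeta

    return Var(out, (x, gamma, beta), bw)


def relu(x: Var) -> Var:
    mask = x.value > 0
    return Var(x.value * mask, (x,), lambda g: (g * mask,))


def avg_pool_ceil(x: Var, k: int | tuple[int, int] = 3, stride: int | tuple[int, int] = 3) -> Var:
    """Average pooling with ceil-mode output size; edge windows average only
    the cells that exist (padding is never counted). ``k``/``stride`` may be
    per-axis (height, width) tuples."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    n, c, h, w = x.shape
    ho = -(-h // sh)
    wo = -(-w // sw)
    hp, wp = ho * sh, wo * sw
    xp = np.pad(x.value, ((0, 0), (0, 0), (0, hp - h), (0, wp - w)))
    sums = xp.reshape(n, c, ho, sh, wo, sw).sum(axis=(3, 5))
    rows = np.minimum(sh, h - sh * np.arange(ho))
    cols = np.minimum(sw, w - sw * np.arange(wo))
    counts = (rows[:, None] * cols[None, :]).astype(np.float32)
    out = sums / counts

    def bw(g):
        gsc = (g / counts)[:, :, :, None, :, None]
        dxp = np.broadcast_to(gsc, (n, c, ho, sh, wo, sw)).reshape(n, c, hp, wp)
        return (dxp[:, :, :h, :w].copy(),)

    return Var(out, (x,), bw)


def concat(vars_: list[Var], axis: int = 1) -> Var:
    vars_ = list(vars_)  # snapshot: callers may mutate their list afterwards
    out = np.concatenate([v.value for v in vars_], axis=axis)
    sizes = [v.shape[axis] for v in vars_]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(vars_))
        )

    return Var(out, tuple(vars_), bw)


def global_avg_pool(x: Var) -> Var:
    n, c, h, w = x.shape
    out = x.value.mean(axis=(2, 3))

    def bw(g):
        return (np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).copy(),)

    return Var(out, (x,), bw)


def dense(x: Var, w: Var, b: Var) -> Var:
    out = x.value @ w.value + b.value

    def bw(g):
        return g @ w.value.T, x.value.T @ g, g.sum(axis=0)

    return Var(out, (x, w, b), bw)


def dropout(x: Var, rate: float, rng: np.random.Generator, training: bool) -> Var:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
    return Var(x.value * keep, (x,), lambda g: (g * keep,))


def sigmoid(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-x.value))
    return Var(s, (x,), lambda g: (g * s * (1.0 - s),))


def sigmoid_bce(logits: Var, targets: np.ndarray, class_weights: np.ndarray | None = None) -> Var:
    """Mean class-weighted binary cross-entropy on logits (numerically stable).

    ``loss = mean_c w_c * mean_n [ max(z,0) - z*y + log(1+exp(-|z|)) ]``.
    """
    z = logits.value
    y = targets.astype(np.float32)
    w = np.ones(z.shape[1], dtype=np.float32) if class_weights is None else class_weights.astype(np.float32)
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float((per * w).mean())

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        return (g * (s - y) * w / z.size,)

    return Var(np.float32(loss), (logits,), bw)


class Adam:
    """Adam optimizer over a list of trainable :class:`Var` parameters."""

    def __init__(self, params: list[Var], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
                 clip_norm: float | None = None):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.clip_norm is not None:
            total = math.sqrt(sum(
                float((p.grad * p.grad).sum()) for p in self.params if p.grad is not None
            ))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale if scale != 1.0 else p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
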