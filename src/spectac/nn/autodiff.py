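"""Reverse-mode automatic differentiation on numpy arrays.

Each op returns a :class:`Tensor` holding a ``_backward`` closure that
accumulates gradients into its parents; :meth:`Tensor.backward` runs the
closures in reverse topological order.  Volumes are laid out
``(N, C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to a broadcasted operand's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * DTYPE(c), parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accumulate(g * DTYPE(c))
    return out


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    pos = a.data > 0
    out = Tensor(np.where(pos, a.data, alpha * a.data), parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accumulate(
        g * np.where(pos, DTYPE(1.0), DTYPE(alpha))
    )
    return out


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accumulate(g * s * (1 - s))
    return out


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=axis), parents=(a, b))
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        if a.requires_grad:
            a._accumulate(ga)
        if b.requires_grad:
            b._accumulate(gb)

    out._backward = backward
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0.0:
        return a
    mask = (rng.random(a.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accumulate(g * mask)
    return out


# ------------------------------------------------------------ convolution

def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """3D convolution: x (N,C,D,H,W), w (F,C,k,k,k), b (F,).

    Implemented as k^3 shifted GEMMs (one per kernel tap), which avoids
    materializing the k^3-fold im2col matrix.
    """
    n, c, d, h, wd = x.shape
    f, _, k, _, _ = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    dp, hp, wp = xp.shape[2:]
    do = (dp - k) // stride + 1
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    m = do * ho * wo
    taps = [(a, b_, c_) for a in range(k) for b_ in range(k) for c_ in range(k)]

    def shifted(src, a, b_, c_):
        return src[:, :, a : a + stride * do : stride,
                   b_ : b_ + stride * ho : stride,
                   c_ : c_ + stride * wo : stride]

    # per sample, pack the k^3 shifted tap views into one (k^3*C, M)
    # matrix; forward and both backward passes are then plain GEMMs with
    # no axis reordering anywhere
    def sample_cols(xi):
        cols = np.empty((k**3 * c, m), dtype=DTYPE)
        for i, t in enumerate(taps):
            cols[i * c : (i + 1) * c] = shifted(xi[None], *t).reshape(c, m)
        return cols

    cols_all = [sample_cols(xp[i]) for i in range(n)]
    w2 = w.data.transpose(2, 3, 4, 1, 0).reshape(k**3 * c, f)
    out_data = np.empty((n, f, do, ho, wo), dtype=DTYPE)
    for i in range(n):
        out_data[i] = (w2.T @ cols_all[i]).reshape(f, do, ho, wo)
    out_data += b.data.reshape(1, f, 1, 1, 1)
    out = Tensor(out_data, parents=(x, w, b))

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw2 = np.zeros((k**3 * c, f), dtype=DTYPE)
            for i in range(n):
                gw2 += cols_all[i] @ g[i].reshape(f, m).T
            w._accumulate(
                gw2.reshape(k, k, k, c, f).transpose(4, 3, 0, 1, 2).copy()
            )
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(n):
                gcols = w2 @ g[i].reshape(f, m)  # (k^3*C, M)
                for j, t in enumerate(taps):
                    shifted(gxp[i : i + 1], *t)[...] += (
                        gcols[j * c : (j + 1) * c].reshape(1, c, do, ho, wo)
                    )
            x._accumulate(gxp[:, :, pad : pad + d, pad : pad + h, pad : pad + wd])

    out._backward = backward
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fully connected: x (N,C) @ w (C,K) + b (K,)."""
    out = Tensor(x.data @ w.data + b.data, parents=(x, w, b))

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    out._backward = backward
    return out


# ------------------------------------------------------- pooling / resize

def max_pool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {(d, h, w)}")
    xr = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=DTYPE)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        x._accumulate(gr)

    out._backward = backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the three spatial dims."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    out = Tensor(data, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        n, c, d, h, w = x.shape
        gr = g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
        x._accumulate(gr)

    out._backward = backward
    return out


def global_mean(x: Tensor) -> Tensor:
    """Mean over the spatial dims: (N,C,D,H,W) -> (N,C)."""
    n, c, d, h, w = x.shape
    m = d * h * w
    out = Tensor(x.data.mean(axis=(2, 3, 4)), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(
        np.broadcast_to(g[:, :, None, None, None] / DTYPE(m), x.shape).astype(DTYPE)
    )
    return out


# ------------------------------------------------------------------ losses

def mean_abs_diff(a: Tensor, b: Tensor) -> Tensor:
    """L1 loss mean(|a - b|); subgradient 0 at ties."""
    diff = a.data - b.data
    out = Tensor(np.abs(diff).mean(), parents=(a, b))
    sgn = np.sign(diff) / DTYPE(diff.size)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * sgn)
        if b.requires_grad:
            b._accumulate(-g * sgn)

    out._backward = backward
    return out


def bce_with_logits(logits: Tensor, target) -> Tensor:
    """Mean binary cross-entropy against constant 0/1 targets (scalar or
    per-row array), computed from logits for numerical stability."""
    z = logits.data
    t = np.broadcast_to(np.asarray(target, dtype=DTYPE), z.shape)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))
    s = 1.0 / (1.0 + np.exp(-z))
    out._backward = lambda g: logits.requires_grad and logits._accumulate(
        g * (s - t) / DTYPE(z.size)
    )
    return out
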