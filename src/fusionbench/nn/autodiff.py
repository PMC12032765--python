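"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine provides exactly the operations needed by the segmentation
networks in :mod:`fusionbench.fusion`: N-dimensional convolution with odd
kernels and "same" padding, ReLU, 2x max-pooling, 2x nearest-neighbour
upsampling, channel concatenation/slicing, channel softmax and the scalar
arithmetic required by the soft-Dice loss.  Gradients are checked against
central finite differences in the test suite.

Tensors are dense float64/float32 numpy arrays laid out as
``(batch, channels, *spatial)``; spatial rank may be 2 or 3.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "conv",
    "relu",
    "leaky_relu",
    "instance_norm",
    "maxpool2",
    "upsample2",
    "concat",
    "channel_softmax",
    "take_channel",
    "scale",
    "sum_all",
    "backward",
]


class Tensor:
    """A node in the computation graph.

    ``value`` is a numpy array (possibly 0-d for scalars).  ``grad`` is
    populated by :func:`backward`.  Leaf tensors (parameters, inputs) are
    created directly; intermediate tensors carry a ``_grad_fn`` closure that
    routes the upstream gradient to their parents.
    """

    __slots__ = ("value", "grad", "_parents", "_grad_fn")

    def __init__(
        self,
        value: np.ndarray,
        parents: Sequence["Tensor"] = (),
        grad_fn: Callable[[np.ndarray], Sequence[np.ndarray]] | None = None,
    ):
        self.value = np.asarray(value)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._grad_fn = grad_fn

    @property
    def shape(self):
        return self.value.shape

    # -- scalar / elementwise arithmetic (same-shape or python-float operands)

    def _binary(self, other, fwd, bwd_self, bwd_other):
        if isinstance(other, Tensor):
            out = fwd(self.value, other.value)
            return Tensor(
                out,
                (self, other),
                lambda g: (bwd_self(g, self.value, other.value),
                           bwd_other(g, self.value, other.value)),
            )
        c = float(other)
        out = fwd(self.value, c)
        return Tensor(out, (self,), lambda g: (bwd_self(g, self.value, c),))

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):  # float - tensor
        c = float(other)
        return Tensor(c - self.value, (self,), lambda g: (-g,))

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other, lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def item(self) -> float:
        return float(self.value)


def constant(value) -> Tensor:
    """A leaf tensor that does not require a gradient (still receives one)."""
    arr = np.asarray(value)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(float)
    return Tensor(arr)


# ---------------------------------------------------------------------------
# convolution


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    nd = x.ndim - 2
    return np.pad(x, [(0, 0), (0, 0)] + [(p, p)] * nd)


def conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded, stride-1 convolution (cross-correlation).

    ``x``: (N, C, *S); ``w``: (O, C, *k) with odd isotropic kernel size;
    ``b``: (O,).  Spatial rank 2 or 3.
    """
    xv, wv = x.value, w.value
    nd = xv.ndim - 2
    k = wv.shape[2]
    p = k // 2
    spatial = xv.shape[2:]
    xp = _pad_spatial(xv, p) if p else xv
    out = np.zeros((xv.shape[0], wv.shape[0]) + spatial, dtype=xv.dtype)
    offsets = list(itertools.product(range(k), repeat=nd))
    slices = {
        off: tuple(slice(o, o + s) for o, s in zip(off, spatial))
        for off in offsets
    }
    for off in offsets:
        sl = (slice(None), slice(None)) + slices[off]
        out += np.einsum("oc,nc...->no...", wv[(slice(None), slice(None)) + off], xp[sl])
    out += b.value.reshape((1, -1) + (1,) * nd)

    def grad_fn(g):
        gx_p = np.zeros_like(xp)
        gw = np.zeros_like(wv)
        for off in offsets:
            sl = (slice(None), slice(None)) + slices[off]
            wk = wv[(slice(None), slice(None)) + off]
            gx_p[sl] += np.einsum("oc,no...->nc...", wk, g)
            red = (0,) + tuple(range(2, g.ndim))
            gw[(slice(None), slice(None)) + off] = np.tensordot(
                g, xp[sl], axes=(red, red)
            )
        if p:
            crop = (slice(None), slice(None)) + tuple(slice(p, p + s) for s in spatial)
            gx = gx_p[crop]
        else:
            gx = gx_p
        gb = g.sum(axis=(0,) + tuple(range(2, g.ndim)))
        return gx, gw, gb

    return Tensor(out, (x, w, b), grad_fn)


# ---------------------------------------------------------------------------
# pointwise / pooling / resampling


def relu(x: Tensor) -> Tensor:
    mask = x.value > 0
    return Tensor(x.value * mask, (x,), lambda g: (g * mask,))


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    slope = np.where(x.value > 0, 1.0, alpha)
    return Tensor(x.value * slope, (x,), lambda g: (g * slope,))


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes with a
    learned affine (``gamma``, ``beta`` of shape (C,))."""
    v = x.value
    nd = v.ndim - 2
    axes = tuple(range(2, v.ndim))
    mu = v.mean(axis=axes, keepdims=True)
    var = v.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = (v - mu) * inv
    gshape = (1, -1) + (1,) * nd
    out = gamma.value.reshape(gshape) * xn + beta.value.reshape(gshape)

    def grad_fn(g):
        dxn = g * gamma.value.reshape(gshape)
        mean_dxn = dxn.mean(axis=axes, keepdims=True)
        mean_dxn_xn = (dxn * xn).mean(axis=axes, keepdims=True)
        dx = inv * (dxn - mean_dxn - xn * mean_dxn_xn)
        dgamma = (g * xn).sum(axis=(0,) + axes)
        dbeta = g.sum(axis=(0,) + axes)
        return dx, dgamma, dbeta

    return Tensor(out, (x, gamma, beta), grad_fn)


def _pool_reshape(v: np.ndarray):
    nd = v.ndim - 2
    shape = list(v.shape[:2])
    for s in v.shape[2:]:
        if s % 2:
            raise ValueError("maxpool2/upsample2 require even spatial dims")
        shape += [s // 2, 2]
    r = v.reshape(shape)
    # move the window axes to the tail: (N, C, *S/2, 2**nd)
    win_axes = tuple(3 + 2 * i for i in range(nd))
    keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(nd))
    r = r.transpose(keep_axes + win_axes)
    return r.reshape(r.shape[: 2 + nd] + (2 ** nd,)), keep_axes, win_axes


def maxpool2(x: Tensor) -> Tensor:
    v = x.value
    nd = v.ndim - 2
    r, keep_axes, win_axes = _pool_reshape(v)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        # undo reshape/transpose
        half = v.shape[:2] + tuple(s // 2 for s in v.shape[2:])
        gr = gr.reshape(half + (2,) * nd)
        inv = np.argsort(keep_axes + win_axes)
        gr = gr.transpose(inv)
        return (gr.reshape(v.shape),)

    return Tensor(out, (x,), grad_fn)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of every spatial axis."""
    v = x.value
    nd = v.ndim - 2
    out = v
    for ax in range(2, 2 + nd):
        out = np.repeat(out, 2, axis=ax)

    def grad_fn(g):
        gr = g
        for ax in range(2, 2 + nd):
            s = gr.shape
            gr = gr.reshape(s[:ax] + (s[ax] // 2, 2) + s[ax + 1:]).sum(axis=ax + 1)
        return (gr,)

    return Tensor(out, (x,), grad_fn)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    vals = [t.value for t in xs]
    sizes = [v.shape[axis] for v in vals]
    out = np.concatenate(vals, axis=axis)
    bounds = np.cumsum([0] + sizes)

    def grad_fn(g):
        return tuple(
            g[(slice(None),) * axis + (slice(bounds[i], bounds[i + 1]),)]
            for i in range(len(vals))
        )

    return Tensor(out, tuple(xs), grad_fn)


def take_channel(x: Tensor, i: int) -> Tensor:
    out = x.value[:, i]

    def grad_fn(g):
        gx = np.zeros_like(x.value)
        gx[:, i] = g
        return (gx,)

    return Tensor(out, (x,), grad_fn)


def channel_softmax(x: Tensor) -> Tensor:
    v = x.value
    m = v.max(axis=1, keepdims=True)
    e = np.exp(v - m)
    p = e / e.sum(axis=1, keepdims=True)

    def grad_fn(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    return Tensor(p, (x,), grad_fn)


def scale(x: Tensor, arr: np.ndarray) -> Tensor:
    """Elementwise multiply by a constant array (no gradient to ``arr``)."""
    arr = np.asarray(arr)
    return Tensor(x.value * arr, (x,), lambda g: (g * arr,))


def sum_all(x: Tensor) -> Tensor:
    return Tensor(np.asarray(x.value.sum()), (x,),
                  lambda g: (np.broadcast_to(g, x.value.shape).copy(),))


# ---------------------------------------------------------------------------


def backward(loss: Tensor) -> None:
    """Reverse-mode sweep from a scalar ``loss``; fills ``.grad`` on leaves."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    for n in topo:
        n.grad = None
    loss.grad = np.ones_like(loss.value)
    for node in reversed(topo):
        if node._grad_fn is None or node.grad is None:
            continue
        for parent, g in zip(node._parents, node._grad_fn(node.grad)):
            if parent.grad is None:
                parent.grad = np.array(g, dtype=parent.value.dtype, copy=True)
            else:
                parent.grad += g
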