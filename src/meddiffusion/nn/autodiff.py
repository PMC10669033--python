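"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the reference U-Net needs: dense and
convolutional affine maps, group normalization, SiLU, 2x average pooling,
2x nearest-neighbour upsampling, channel concatenation, and a mean-squared
loss.  Feature maps are laid out (B, C, H, W); everything is float64.

Each primitive builds a :class:`Var` node recording its parents and a
backward closure.  :func:`backward` runs a topological sweep accumulating
gradients into ``Var.grad``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Var",
    "backward",
    "add",
    "add_channel_bias",
    "concat_channels",
    "conv2d",
    "linear",
    "group_norm",
    "silu",
    "avg_pool2",
    "upsample_nearest2",
    "mse_loss",
]


class Var:
    """A node in the computation graph: a value, its gradient, and the
    closure propagating the gradient to its parents."""

    __slots__ = ("value", "grad", "parents", "bw")

    def __init__(
        self,
        value: np.ndarray,
        parents: Sequence["Var"] = (),
        bw: Callable[[np.ndarray], tuple] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self.bw = bw

    @property
    def shape(self):
        return self.value.shape


def backward(root: Var) -> None:
    """Accumulate d(root)/d(node) into every reachable node's ``grad``."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.value)
    for node in reversed(topo):
        if node.bw is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.bw(node.grad)):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
            else:
                parent.grad = parent.grad + g


def add(a: Var, b: Var) -> Var:
    """Elementwise sum of same-shape tensors (residual connections)."""
    assert a.value.shape == b.value.shape
    return Var(a.value + b.value, (a, b), lambda g: (g, g))


def add_channel_bias(x: Var, v: Var) -> Var:
    """x: (B, C, H, W) plus a per-(batch, channel) bias v: (B, C)."""
    out = x.value + v.value[:, :, None, None]
    return Var(out, (x, v), lambda g: (g, g.sum(axis=(2, 3))))


def concat_channels(a: Var, b: Var) -> Var:
    ca = a.value.shape[1]
    out = np.concatenate([a.value, b.value], axis=1)
    return Var(out, (a, b), lambda g: (g[:, :ca], g[:, ca:]))


def silu(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-x.value))
    out = x.value * s

    def bw(g):
        return (g * s * (1.0 + x.value * (1.0 - s)),)

    return Var(out, (x,), bw)


def linear(x: Var, w: Var, b: Var) -> Var:
    """x: (B, Din) @ w: (Din, Dout) + b: (Dout,)."""
    out = x.value @ w.value + b.value

    def bw(g):
        return (g @ w.value.T, x.value.T @ g, g.sum(axis=0))

    return Var(out, (x, w, b), bw)


def conv2d(x: Var, w: Var, b: Var) -> Var:
    """Same-padding stride-1 convolution via im2col.

    x: (B, Cin, H, W), w: (Cout, Cin, k, k) with odd k, b: (Cout,).
    """
    B, Cin, H, W = x.value.shape
    Cout, Cin_w, k, _ = w.value.shape
    assert Cin == Cin_w, f"channel mismatch {Cin} vs {Cin_w}"
    p = k // 2
    xp = np.pad(x.value, ((0, 0), (0, 0), (p, p), (p, p)))
    # (B, Cin, H, W, k, k) -> (B, H*W, Cin*k*k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, Cin * k * k)
    wmat = w.value.reshape(Cout, Cin * k * k).T  # (Cin*k*k, Cout)
    out = (cols @ wmat + b.value).transpose(0, 2, 1).reshape(B, Cout, H, W)

    def bw(g):
        gm = g.reshape(B, Cout, H * W).transpose(0, 2, 1)  # (B, H*W, Cout)
        gw = np.tensordot(cols, gm, axes=([0, 1], [0, 1])).T.reshape(w.value.shape)
        gb = gm.sum(axis=(0, 1))
        gcols = (gm @ wmat.T).reshape(B, H, W, Cin, k, k)
        gxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki : ki + H, kj : kj + W] += gcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        gx = gxp[:, :, p : p + H, p : p + W]
        return (gx, gw, gb)

    return Var(out, (x, w, b), bw)


def group_norm(x: Var, gamma: Var, beta: Var, groups: int, eps: float = 1e-5) -> Var:
    """Normalize over (channels-per-group, H, W) within each (batch, group)."""
    B, C, H, W = x.value.shape
    assert C % groups == 0, f"channels {C} not divisible by groups {groups}"
    xg = x.value.reshape(B, groups, -1)
    mean = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv_std).reshape(B, C, H, W)
    out = gamma.value[None, :, None, None] * xhat + beta.value[None, :, None, None]

    def bw(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = (g * gamma.value[None, :, None, None]).reshape(B, groups, -1)
        xh = xhat.reshape(B, groups, -1)
        m1 = gxhat.mean(axis=2, keepdims=True)
        m2 = (gxhat * xh).mean(axis=2, keepdims=True)
        gx = (inv_std * (gxhat - m1 - xh * m2)).reshape(B, C, H, W)
        return (gx, ggamma, gbeta)

    return Var(out, (x, gamma, beta), bw)


def avg_pool2(x: Var) -> Var:
    """2x2 average pooling, stride 2 (H, W must be even)."""
    B, C, H, W = x.value.shape
    assert H % 2 == 0 and W % 2 == 0
    out = x.value.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def bw(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        return (gx,)

    return Var(out, (x,), bw)


def upsample_nearest2(x: Var) -> Var:
    """2x nearest-neighbour upsampling."""
    out = np.repeat(np.repeat(x.value, 2, axis=2), 2, axis=3)

    def bw(g):
        B, C, H2, W2 = g.shape
        gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        return (gx,)

    return Var(out, (x,), bw)


def mse_loss(pred: Var, target: np.ndarray) -> Var:
    """Mean over all elements of (pred - target)^2; returns a scalar Var."""
    diff = pred.value - np.asarray(target, dtype=np.float64)
    n = diff.size
    out = np.asarray((diff**2).mean())

    def bw(g):
        return (g * 2.0 * diff / n,)

    return Var(out, (pred,), bw)
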