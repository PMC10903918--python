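"""Minimal reverse-mode autodiff engine on numpy arrays.

Implements exactly the operations the dual-decoder segmentation network
needs: 3×3 'same' convolution (im2col), 2×2 max pooling, nearest-neighbor
2× upsampling, channel concatenation, batch normalization, swish/logistic
activations, and Dice / mean-squared-error losses, plus an Adam optimizer.

Tensors are ``(N, C, H, W)`` float64 throughout; gradients are accumulated
by a topological backward sweep over the define-by-run graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Node:
    """One value in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_bwd")

    def __init__(self, data, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape


class Param(Node):
    """A trainable leaf."""

    def __init__(self, data):
        super().__init__(data)


def _topo(root: Node) -> list[Node]:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def backward(root: Node) -> None:
    """Accumulate d(root)/d(node) into every ``.grad`` in the graph."""
    for n in _topo(root):
        n.grad = None
    root.grad = np.ones_like(root.data)
    for node in reversed(_topo(root)):
        if node._bwd is None or node.grad is None:
            continue
        grads = node._bwd(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = g
            else:
                parent.grad = parent.grad + g


# --------------------------------------------------------------------------
# ops
# --------------------------------------------------------------------------

def conv2d(x: Node, w: Param, b: Param) -> Node:
    """3×3 (or k×k) stride-1 'same' convolution with zero padding."""
    N, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    assert Cin == C, f"channel mismatch {Cin} vs {C}"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * kh * kw)
    wmat = w.data.reshape(Cout, C * kh * kw)
    out = cols @ wmat.T + b.data[None, :]
    out = out.reshape(N, H, W, Cout).transpose(0, 3, 1, 2)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * H * W, Cout)
        dw = (gmat.T @ cols).reshape(w.data.shape)
        db = gmat.sum(axis=0)
        dcols = (gmat @ wmat).reshape(N, H, W, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for a in range(kh):
            for c in range(kw):
                dxp[:, :, a:a + H, c:c + W] += dcols[:, :, :, :, a, c]
        dx = dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp
        return dx, dw, db

    return Node(out, (x, w, b), bwd)


def maxpool2(x: Node) -> Node:
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, "pooling needs even spatial dims"
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(N, C, H, W),)

    return Node(out, (x,), bwd)


def upsample2(x: Node) -> Node:
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        N, C, H2, W2 = g.shape
        dx = g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        return (dx,)

    return Node(out, (x,), bwd)


def concat(a: Node, b: Node) -> Node:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def bwd(g):
        return g[:, :ca], g[:, ca:]

    return Node(out, (a, b), bwd)


def add(a: Node, b: Node) -> Node:
    return Node(a.data + b.data, (a, b), lambda g: (g, g))


class BatchNormState:
    """Running statistics and mode for one batch-norm layer."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.mean = np.zeros(channels)
        self.var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps


def batchnorm(x: Node, gamma: Param, beta: Param, state: BatchNormState,
              training: bool) -> Node:
    eps = state.eps
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        state.mean = state.momentum * state.mean + (1 - state.momentum) * mu
        state.var = state.momentum * state.var + (1 - state.momentum) * var
    else:
        mu, var = state.mean, state.var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gm = gamma.data[None, :, None, None]
        if training:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            gx = g * gm
            dx = (inv[None, :, None, None] / m) * (
                m * gx
                - gx.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        else:
            dx = g * gm * inv[None, :, None, None]
        return dx, dgamma, dbeta

    return Node(out, (x, gamma, beta), bwd)


def sigmoid(x: Node) -> Node:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Node(s, (x,), lambda g: (g * s * (1 - s),))


def swish_op(x: Node) -> Node:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = x.data * s
    return Node(out, (x,), lambda g: (g * (s + x.data * s * (1 - s)),))


# --------------------------------------------------------------------------
# losses (scalar nodes)
# --------------------------------------------------------------------------

def dice_loss_node(pred: Node, target: np.ndarray, eps: float = 1e-7) -> Node:
    """Soft Dice loss ``1 − (2·Σŷy + ε) / (Σŷ² + Σy² + ε)`` over the batch."""
    y = np.asarray(target, dtype=np.float64)
    p = pred.data
    num = 2.0 * (p * y).sum() + eps
    den = (p * p).sum() + (y * y).sum() + eps
    out = 1.0 - num / den

    def bwd(g):
        dp = g * (-(2.0 * y * den - num * 2.0 * p) / (den * den))
        return (dp,)

    return Node(out, (pred,), bwd)


def mse_loss_node(pred: Node, target: np.ndarray) -> Node:
    """Mean squared error over all pixels."""
    y = np.asarray(target, dtype=np.float64)
    diff = pred.data - y
    out = np.mean(diff * diff)

    def bwd(g):
        return (g * 2.0 * diff / diff.size,)

    return Node(out, (pred,), bwd)


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
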