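"""Minimal CNN building blocks on numpy.

Implements exactly the pieces the backbone zoo needs: 2-D convolution
(im2col), depthwise convolution, residual and depthwise-separable blocks,
global average pooling, a dense head, softmax cross-entropy and Adam.
Every layer carries its own analytic backward pass, so the same machinery
serves both training and Grad-CAM feature-layer gradients.

All tensors are float32 in NCHW layout. Everything is deterministic given
the numpy Generator used at construction and the data order at train time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d:
    """k x k convolution, stride s, 'same' padding (pad = k // 2)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = ksize, stride
        self.pad = ksize // 2
        fan_in = in_ch * ksize * ksize
        self.W = _he_init(rng, (out_ch, fan_in), fan_in)
        self.b = np.zeros(out_ch, F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_shape(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]        # n,c,oh,ow,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, -1)
        cols = np.ascontiguousarray(cols)
        out = cols @ self.W.T + self.b                        # n,oh*ow,out
        self._cache = (cols, (n, c, h, w), (oh, ow))
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, oh, ow)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (oh, ow) = self._cache
        gmat = g.transpose(0, 2, 3, 1).reshape(n, oh * ow, self.out_ch)
        flat_g = gmat.reshape(-1, self.out_ch)
        flat_c = cols.reshape(-1, cols.shape[-1])
        self.gW = flat_g.T @ flat_c
        self.gb = flat_g.sum(axis=0)
        gcols = (gmat @ self.W).reshape(n, oh, ow, c, self.k, self.k)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        gxp = np.zeros((n, c, hp, wp), gcols.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            gxp = gxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return gxp

    def params(self):
        return [("W", self), ("b", self)]


class DepthwiseConv2d:
    """Per-channel k x k convolution ('same' padding)."""

    def __init__(self, ch: int, ksize: int, stride: int, rng: np.random.Generator):
        self.ch, self.k, self.stride = ch, ksize, stride
        self.pad = ksize // 2
        self.W = _he_init(rng, (ch, ksize, ksize), ksize * ksize)
        self.b = np.zeros(ch, F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        out = np.einsum("nchwij,cij->nchw", win, self.W, optimize=True)
        out += self.b[None, :, None, None]
        self._cache = (win, (n, c, h, w))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        win, (n, c, h, w) = self._cache
        oh, ow = g.shape[2], g.shape[3]
        self.gW = np.einsum("nchw,nchwij->cij", g, win, optimize=True)
        self.gb = g.sum(axis=(0, 2, 3))
        gwin = np.einsum("nchw,cij->nchwij", g, self.W, optimize=True)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        gxp = np.zeros((n, c, hp, wp), gwin.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                gxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += gwin[:, :, :, :, i, j]
        if self.pad:
            gxp = gxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return gxp

    def params(self):
        return [("W", self), ("b", self)]


def _relu(x):
    return np.maximum(x, 0.0)


class ConvStage:
    """Conv -> ReLU."""

    def __init__(self, in_ch, out_ch, ksize, stride, rng):
        self.conv = Conv2d(in_ch, out_ch, ksize, stride, rng)
        self.out_ch = out_ch
        self._mask = None

    def forward(self, x):
        y = _relu(self.conv.forward(x))
        self._mask = y > 0
        return y

    def backward(self, g):
        return self.conv.backward(g * self._mask)

    def params(self):
        return self.conv.params()


class ResBlock:
    """conv3x3 -> ReLU -> conv3x3, plus identity/1x1-projection skip, ReLU."""

    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng)
        self.proj = (Conv2d(in_ch, out_ch, 1, stride, rng)
                     if stride != 1 or in_ch != out_ch else None)
        self.out_ch = out_ch
        self._m1 = self._mout = None

    def forward(self, x):
        a = _relu(self.conv1.forward(x))
        self._m1 = a > 0
        y = self.conv2.forward(a)
        s = self.proj.forward(x) if self.proj is not None else x
        out = _relu(y + s)
        self._mout = out > 0
        return out

    def backward(self, g):
        g = g * self._mout
        ga = self.conv2.backward(g) * self._m1
        gx = self.conv1.backward(ga)
        gx += self.proj.backward(g) if self.proj is not None else g
        return gx

    def params(self):
        p = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            p += self.proj.params()
        return p


class SepBlock:
    """Depthwise 3x3 -> ReLU -> pointwise 1x1 -> ReLU (Xception-style)."""

    def __init__(self, in_ch, out_ch, stride, rng):
        self.dw = DepthwiseConv2d(in_ch, 3, stride, rng)
        self.pw = Conv2d(in_ch, out_ch, 1, 1, rng)
        self.out_ch = out_ch
        self._m1 = self._m2 = None

    def forward(self, x):
        a = _relu(self.dw.forward(x))
        self._m1 = a > 0
        y = _relu(self.pw.forward(a))
        self._m2 = y > 0
        return y

    def backward(self, g):
        ga = self.pw.backward(g * self._m2) * self._m1
        return self.dw.backward(ga)

    def params(self):
        return self.dw.params() + self.pw.params()


class Head:
    """Global average pool over space, then a dense layer to n_classes logits."""

    def __init__(self, in_ch, n_classes, rng):
        self.W = _he_init(rng, (n_classes, in_ch), in_ch)
        self.b = np.zeros(n_classes, F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        pooled = x.mean(axis=(2, 3))
        self._cache = (pooled, (n, c, h, w))
        return pooled @ self.W.T + self.b

    def backward(self, g):
        pooled, (n, c, h, w) = self._cache
        self.gW = g.T @ pooled
        self.gb = g.sum(axis=0)
        gp = g @ self.W
        return np.ascontiguousarray(np.broadcast_to(
            gp[:, :, None, None] / (h * w), (n, c, h, w)))

    def params(self):
        return [("W", self), ("b", self)]


class Network:
    """An ordered list of named stages followed by a pooled dense head."""

    def __init__(self, stages: list[tuple[str, object]], head: Head):
        self.stages = stages
        self.head = head
        self.stage_names = [name for name, _ in stages]

    def forward(self, x: np.ndarray, capture: str | None = None):
        """Run forward; optionally return the activation of a named stage."""
        captured = None
        for name, stage in self.stages:
            x = stage.forward(x)
            if name == capture:
                captured = x
        logits = self.head.forward(x)
        return (logits, captured) if capture is not None else logits

    def backward(self, glogits: np.ndarray, stop_at: str | None = None):
        """Backpropagate from the logits.

        With ``stop_at``, returns the gradient w.r.t. that stage's OUTPUT
        (parameter grads above it are still filled; below it, untouched).
        Without it, propagates through all stages and returns the input grad.
        """
        g = self.head.backward(glogits)
        for name, stage in reversed(self.stages):
            if name == stop_at:
                return g
            g = stage.backward(g)
        if stop_at is not None:
            raise KeyError(f"unknown stage {stop_at!r}")
        return g

    def params(self):
        out = []
        for _, stage in self.stages:
            out += stage.params()
        out += self.head.params()
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, (attr, layer) in enumerate(self.params()):
            state[f"p{i}_{attr}"] = getattr(layer, attr)
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, (attr, layer) in enumerate(self.params()):
            setattr(layer, attr, state[f"p{i}_{attr}"].astype(F32).copy())


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, net: Network, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, a)) for a, l in net.params()]
        self.v = [np.zeros_like(getattr(l, a)) for a, l in net.params()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (attr, layer) in enumerate(self.net.params()):
            g = getattr(layer, "g" + attr)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p = getattr(layer, attr)
            setattr(layer, attr,
                    (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-12, None)))
    g = p
    g[np.arange(n), labels] -= 1.0
    return float(loss), (g / n).astype(F32)
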