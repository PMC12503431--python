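"""Minimal CPU neural-network layers with explicit backpropagation.

All layers operate on float32 arrays in NCHW layout. Every layer implements
``forward``/``backward`` plus an analytic ``flop_walk`` used by the profiler:
one multiply-accumulate (MAC) is counted as one FLOP, normalisation,
activation and pooling as zero, matching the convention under which a
ResNet50 inference pass at 224x224 costs about 3.8 GFLOPs.

Shapes passed to ``flop_walk`` are per-sample ``(C, H, W)`` tuples.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    """Base layer: identity with no parameters and no cost."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def out_shape(self, in_shape):
        return in_shape

    def flop_walk(self, in_shape, prefix: str = ""):
        """Return (entries, out_shape); entries are (name, macs) per sample."""
        return [], self.out_shape(in_shape)


def _pair(k):
    return (k, k) if np.isscalar(k) else tuple(k)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col and batched matmul.

    Supports grouped and depthwise convolution (``groups == in_channels``
    with any integer channel multiplier).
    """

    def __init__(self, cin, cout, kernel, stride=1, padding=None, groups=1,
                 bias=True, rng=None, name="conv"):
        kh, kw = _pair(kernel)
        if cin % groups or cout % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.stride = stride
        self.padding = (kh - 1) // 2 if padding is None else padding
        self.groups = groups
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = (cin // groups) * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin // groups, kh, kw))
        self.W = Param(w, name + ".W")
        self.b = Param(np.zeros(cout), name + ".b") if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.kh) // self.stride + 1
        wo = (w + 2 * self.padding - self.kw) // self.stride + 1
        return (self.cout, ho, wo)

    def macs_per_sample(self, in_shape):
        _, ho, wo = self.out_shape(in_shape)
        return (self.cin // self.groups) * self.cout * self.kh * self.kw * ho * wo

    def flop_walk(self, in_shape, prefix=""):
        out = self.out_shape(in_shape)
        return [(prefix or self.name, self.macs_per_sample(in_shape))], out

    def _im2col(self, x):
        n, c, h, w = x.shape
        p, s = self.padding, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (N,C,Ho,Wo,kh,kw)
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(
            n, self.groups, (c // self.groups) * self.kh * self.kw, ho * wo)
        return np.ascontiguousarray(cols), (ho, wo)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        cols, (ho, wo) = self._im2col(x)
        g = self.groups
        wg = self.W.data.reshape(g, self.cout // g, -1)
        y = np.matmul(wg, cols)                        # (N,g,cout/g,L)
        y = y.reshape(x.shape[0], self.cout, ho, wo)
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        return y

    def backward(self, dy):
        cols, x_shape, (ho, wo) = self._cache
        n = x_shape[0]
        g = self.groups
        dyg = dy.reshape(n, g, self.cout // g, ho * wo)
        wg = self.W.data.reshape(g, self.cout // g, -1)
        dW = np.matmul(dyg, cols.transpose(0, 1, 3, 2)).sum(axis=0)
        self.W.grad = dW.reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad = dy.sum(axis=(0, 2, 3))
        dcols = np.matmul(wg.transpose(0, 2, 1), dyg)  # (N,g,K,L)
        dcols = dcols.reshape(n, self.cin, self.kh, self.kw, ho, wo)
        p, s = self.padding, self.stride
        hp, wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        dxp = np.zeros((n, self.cin, hp, wp), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, name="bn"):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c), name + ".gamma")
        self.beta = Param(np.zeros(c), name + ".beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._cache = (xhat, ivar)
        else:
            self._cache = ("eval", ivar)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        cache = self._cache
        self._cache = None
        if cache[0] is None or (isinstance(cache[0], str) and cache[0] == "eval"):
            ivar = cache[1]
            return dy * (self.gamma.data * ivar)[None, :, None, None]
        xhat, ivar = cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * self.gamma.data[None, :, None, None]
        self.gamma.grad = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dy.sum(axis=(0, 2, 3))
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (ivar[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class ReLU6(Layer):
    def forward(self, x, train=False):
        y = np.clip(x, 0, 6)
        if train:
            self._mask = (x > 0) & (x < 6)
        return y

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y.astype(np.float32)

    def backward(self, dy):
        return dy * self._y * (1 - self._y)


class HardSigmoid(Layer):
    """relu6(x + 3) / 6, the gating activation of squeeze-excite blocks."""

    def forward(self, x, train=False):
        y = np.clip((x + 3.0) / 6.0, 0.0, 1.0)
        if train:
            self._mask = (x > -3) & (x < 3)
        return y.astype(np.float32)

    def backward(self, dy):
        return dy * self._mask / 6.0


class MaxPool2d(Layer):
    def __init__(self, kernel=2, stride=None, padding=0):
        self.k = kernel
        self.stride = stride or kernel
        self.padding = padding

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return (c, ho, wo)

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        if train:
            self._arg = flat.argmax(axis=-1)
            self._x_shape = x.shape  # padded shape
        return flat.max(axis=-1)

    def backward(self, dy):
        k, s, p = self.k, self.stride, self.padding
        n, c, hp, wp = self._x_shape
        ho, wo = dy.shape[2], dy.shape[3]
        dflat = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        dwin = dflat.reshape(n, c, ho, wo, k, k).transpose(0, 1, 4, 5, 2, 3)
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dwin[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C)."""

    def out_shape(self, in_shape):
        return (in_shape[0],)

    def forward(self, x, train=False):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               dy.shape + (h, w)).astype(np.float32).copy()


class Linear(Layer):
    def __init__(self, i, o, bias=True, rng=None, name="fc"):
        rng = rng or np.random.default_rng(0)
        self.i, self.o = i, o
        self.W = Param(rng.normal(0, np.sqrt(2.0 / i), size=(o, i)), name + ".W")
        self.b = Param(np.zeros(o), name + ".b") if bias else None
        self.name = name

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_shape(self, in_shape):
        return (self.o,)

    def flop_walk(self, in_shape, prefix=""):
        return [(prefix or self.name, self.i * self.o)], (self.o,)

    def forward(self, x, train=False):
        if train:
            self._x = x
        y = x @ self.W.data.T
        if self.b is not None:
            y = y + self.b.data
        return y.astype(np.float32)

    def backward(self, dy):
        self.W.grad = dy.T @ self._x
        if self.b is not None:
            self.b.grad = dy.sum(axis=0)
        return (dy @ self.W.data).astype(np.float32)


class Dropout(Layer):
    def __init__(self, p=0.5):
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, 2 * h, 2 * w)

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers, name="seq"):
        self.layers = list(layers)
        self.name = name

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def out_shape(self, in_shape):
        for l in self.layers:
            in_shape = l.out_shape(in_shape)
        return in_shape

    def flop_walk(self, in_shape, prefix=""):
        entries = []
        for i, l in enumerate(self.layers):
            sub, in_shape = l.flop_walk(in_shape, f"{prefix}.{i}" if prefix else str(i))
            entries.extend(sub)
        return entries, in_shape

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Residual(Layer):
    """y = act(main(x) + shortcut(x)); shortcut=None means identity."""

    def __init__(self, main, shortcut=None, activation=None, name="res"):
        self.main = main
        self.shortcut = shortcut
        self.activation = activation
        self.name = name

    def params(self):
        ps = list(self.main.params())
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def out_shape(self, in_shape):
        return self.main.out_shape(in_shape)

    def flop_walk(self, in_shape, prefix=""):
        entries, out = self.main.flop_walk(in_shape, (prefix + ".main") if prefix else "main")
        if self.shortcut is not None:
            sub, _ = self.shortcut.flop_walk(in_shape, (prefix + ".short") if prefix else "short")
            entries.extend(sub)
        return entries, out

    def forward(self, x, train=False):
        y = self.main.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        y = y + s
        if self.activation is not None:
            y = self.activation.forward(y, train=train)
        return y

    def backward(self, dy):
        if self.activation is not None:
            dy = self.activation.backward(dy)
        dx = self.main.backward(dy)
        if self.shortcut is None:
            dx = dx + dy
        else:
            dx = dx + self.shortcut.backward(dy)
        return dx


class SEBlock(Layer):
    """Squeeze-and-excitation channel gating with hard-sigmoid activation."""

    def __init__(self, c, reduction=4, rng=None, name="se"):
        mid = max(1, int(round(c / reduction)))
        self.c, self.mid = c, mid
        self.fc1 = Linear(c, mid, rng=rng, name=name + ".fc1")
        self.relu = ReLU()
        self.fc2 = Linear(mid, c, rng=rng, name=name + ".fc2")
        self.gate = HardSigmoid()
        self.name = name

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def flop_walk(self, in_shape, prefix=""):
        pre = prefix or self.name
        return [(pre + ".fc1", self.c * self.mid),
                (pre + ".fc2", self.mid * self.c)], in_shape

    def forward(self, x, train=False):
        z = x.mean(axis=(2, 3))
        a = self.gate.forward(
            self.fc2.forward(self.relu.forward(self.fc1.forward(z, train), train), train),
            train)
        if train:
            self._x, self._a = x, a
        return x * a[:, :, None, None]

    def backward(self, dy):
        x, a = self._x, self._a
        h, w = x.shape[2], x.shape[3]
        dx1 = dy * a[:, :, None, None]
        da = (dy * x).sum(axis=(2, 3))
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(self.gate.backward(da))))
        dx2 = np.broadcast_to(dz[:, :, None, None] / (h * w), x.shape)
        return (dx1 + dx2).astype(np.float32)


class GhostModule(Layer):
    """Ghost convolution block.

    A primary (pointwise by default) convolution produces ``m = cout/ratio``
    intrinsic feature maps; a cheap depthwise convolution derives the
    remaining ``(ratio-1)*m`` ghost maps from them; the output is their
    channel concatenation, always exactly ``cout`` channels wide.
    """

    def __init__(self, cin, cout, ratio=2, primary_kernel=1, cheap_kernel=3,
                 relu=True, rng=None, name="ghost"):
        if ratio < 1:
            raise ValueError("ratio must be >= 1")
        if cout % ratio:
            raise ValueError(f"out_channels {cout} not divisible by ratio {ratio}")
        self.cin, self.cout, self.ratio = cin, cout, ratio
        m = cout // ratio
        self.m = m
        act = [ReLU()] if relu else []
        self.primary = Sequential(
            [Conv2d(cin, m, primary_kernel, bias=False, rng=rng, name=name + ".primary"),
             BatchNorm2d(m)] + act, name=name + ".primary")
        if ratio > 1:
            self.cheap = Sequential(
                [Conv2d(m, m * (ratio - 1), cheap_kernel, groups=m, bias=False,
                        rng=rng, name=name + ".cheap"),
                 BatchNorm2d(m * (ratio - 1))] + ([ReLU()] if relu else []),
                name=name + ".cheap")
        else:
            self.cheap = None
        self.name = name

    def params(self):
        ps = self.primary.params()
        if self.cheap is not None:
            ps += self.cheap.params()
        return ps

    def out_shape(self, in_shape):
        _, h, w = in_shape
        return (self.cout, h, w)

    def flop_walk(self, in_shape, prefix=""):
        pre = prefix or self.name
        entries, mid = self.primary.flop_walk(in_shape, pre + ".primary")
        if self.cheap is not None:
            sub, _ = self.cheap.flop_walk(mid, pre + ".cheap")
            entries.extend(sub)
        return entries, self.out_shape(in_shape)

    def forward(self, x, train=False):
        p = self.primary.forward(x, train=train)
        if self.cheap is None:
            return p
        g = self.cheap.forward(p, train=train)
        return np.concatenate([p, g], axis=1)

    def backward(self, dy):
        if self.cheap is None:
            return self.primary.backward(dy)
        dp = dy[:, :self.m]
        dg = dy[:, self.m:]
        dp = dp + self.cheap.backward(dg)
        return self.primary.backward(dp)


def iter_layers(layer: Layer):
    """Depth-first walk over a layer tree (follows attributes and lists)."""
    yield layer
    if not hasattr(layer, "__dict__"):
        return
    for attr in vars(layer).values():
        if isinstance(attr, Layer):
            yield from iter_layers(attr)
        elif isinstance(attr, (list, tuple)):
            for item in attr:
                if isinstance(item, Layer):
                    yield from iter_layers(item)


def set_rng(layer: Layer, rng: np.random.Generator) -> None:
    """Point every Dropout in a layer tree at a shared seeded generator."""
    for sub in iter_layers(layer):
        if isinstance(sub, Dropout):
            sub.rng = rng
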