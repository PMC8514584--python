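"""Minimal feed-forward layer library on numpy.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.g`` during ``backward``.
All arithmetic is float32; convolutions are lowered to GEMM via im2col.
Layouts are NCHW for feature maps and (N, F) for dense activations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=F32)
        self.g = np.zeros_like(self.v)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> contiguous (N, Ho, Wo, C*k*k) of sliding k x k windows."""
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    n, c, ho, wo = v.shape[:4]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho, wo, c * k * k)


class Conv2d(Layer):
    """k x k convolution, stride 1, symmetric zero padding, He-initialised."""

    def __init__(self, cin: int, cout: int, k: int, pad: int = 0, *, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.pad = k, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if x.shape[1] != self.cin:
            raise ValueError(f"Conv2d expected {self.cin} input channels, got {x.shape[1]}")
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._xshape = x.shape
        col = _im2col(x, self.k)
        self._col = col
        out = col @ self.W.v.reshape(self.cout, -1).T + self.b.v
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, gy):
        n, co, ho, wo = gy.shape
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, co)
        col2 = self._col.reshape(-1, self._col.shape[-1])
        self.W.g += (g.T @ col2).reshape(self.W.v.shape)
        self.b.g += g.sum(axis=0)
        gcol = (g @ self.W.v.reshape(co, -1)).reshape(n, ho, wo, -1, self.k, self.k)
        gx = np.zeros(self._xshape, dtype=F32)
        # scatter-add each kernel offset back onto the (padded) input
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i:i + ho, j:j + wo] += gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            p = self.pad
            gx = gx[:, :, p:-p, p:-p]
        self._col = None
        return gx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, gy):
        return np.where(self._mask, gy, F32(0.0))


class MaxPool2(Layer):
    """2 x 2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :, :ho * 2, :wo * 2].reshape(n, c, ho, 2, wo, 2)
        xr = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)).reshape(n, c, ho, wo, 4)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, ho, wo = gy.shape
        flat = np.zeros((n, c, ho, wo, 4), dtype=F32)
        np.put_along_axis(flat, self._idx[..., None], gy[..., None], axis=-1)
        gx = np.zeros(self._in_shape, dtype=F32)
        gx[:, :, :ho * 2, :wo * 2] = (
            flat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        )
        return gx


class AvgPool2(Layer):
    """2 x 2 average pooling, stride 2 (DenseNet transition)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        self._in_shape = x.shape
        return x[:, :, :ho * 2, :wo * 2].reshape(n, c, ho, 2, wo, 2).mean(axis=(3, 5))

    def backward(self, gy):
        n, c, ho, wo = gy.shape
        gx = np.zeros(self._in_shape, dtype=F32)
        gx[:, :, :ho * 2, :wo * 2] = np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) * F32(0.25)
        return gx


class AvgPool3s1(Layer):
    """3 x 3 average pooling, stride 1, zero padding 1 (inception pool branch).

    Zero padding counts toward the divisor (count_include_pad), which keeps the
    backward pass a plain transposed accumulation.
    """

    def forward(self, x, train=False):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        v = sliding_window_view(xp, (3, 3), axis=(2, 3))
        return v.mean(axis=(4, 5)).astype(F32)

    def backward(self, gy):
        n, c, h, w = gy.shape
        gp = np.zeros((n, c, h + 2, w + 2), dtype=F32)
        g9 = gy * F32(1.0 / 9.0)
        for i in range(3):
            for j in range(3):
                gp[:, :, i:i + h, j:j + w] += g9
        return gp[:, :, 1:-1, 1:-1]


class AdaptiveAvgPool(Layer):
    """Average-pool any spatial size down to out x out bins (integer edges)."""

    def __init__(self, out: int):
        self.out = out

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        o = self.out
        if h < o or w < o:
            raise ValueError(f"spatial size {h}x{w} smaller than adaptive pool output {o}x{o}")
        self._in_shape = x.shape
        re = [h * i // o for i in range(o + 1)]
        ce = [w * j // o for j in range(o + 1)]
        self._edges = (re, ce)
        y = np.empty((n, c, o, o), dtype=F32)
        for i in range(o):
            for j in range(o):
                y[:, :, i, j] = x[:, :, re[i]:re[i + 1], ce[j]:ce[j + 1]].mean(axis=(2, 3))
        return y

    def backward(self, gy):
        re, ce = self._edges
        gx = np.zeros(self._in_shape, dtype=F32)
        o = self.out
        for i in range(o):
            for j in range(o):
                area = (re[i + 1] - re[i]) * (ce[j + 1] - ce[j])
                gx[:, :, re[i]:re[i + 1], ce[j]:ce[j + 1]] += gy[:, :, i, j, None, None] / F32(area)
        return gx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, *, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.W = Param(rng.normal(0.0, std, size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, gy):
        self.W.g += self._x.T @ gy
        self.b.g += gy.sum(axis=0)
        gx = gy @ self.W.v.T
        self._x = None
        return gx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class InceptionBlock(Layer):
    """Four parallel branches (1x1 / 1x1-3x3 / 1x1-5x5 / avgpool-1x1), concatenated."""

    def __init__(self, cin: int, c1: int, c3r: int, c3: int, c5r: int, c5: int, cp: int,
                 *, rng: np.random.Generator):
        self.b1 = Sequential(Conv2d(cin, c1, 1, rng=rng), ReLU())
        self.b3 = Sequential(Conv2d(cin, c3r, 1, rng=rng), ReLU(),
                             Conv2d(c3r, c3, 3, pad=1, rng=rng), ReLU())
        self.b5 = Sequential(Conv2d(cin, c5r, 1, rng=rng), ReLU(),
                             Conv2d(c5r, c5, 5, pad=2, rng=rng), ReLU())
        self.bp = Sequential(AvgPool3s1(), Conv2d(cin, cp, 1, rng=rng), ReLU())
        self._splits = np.cumsum([c1, c3, c5])[:2 + 1]
        self.cout = c1 + c3 + c5 + cp

    def params(self):
        return (self.b1.params() + self.b3.params() + self.b5.params() + self.bp.params())

    def forward(self, x, train=False):
        ys = [b.forward(x, train=train) for b in (self.b1, self.b3, self.b5, self.bp)]
        return np.concatenate(ys, axis=1)

    def backward(self, gy):
        parts = np.split(gy, self._splits, axis=1)
        gx = None
        for b, g in zip((self.b1, self.b3, self.b5, self.bp), parts):
            gb = b.backward(np.ascontiguousarray(g))
            gx = gb if gx is None else gx + gb
        return gx


class ResidualBlock(Layer):
    """conv3-relu-conv3 with identity (or 1x1-projected) shortcut, final ReLU."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        self.main = Sequential(Conv2d(cin, cout, 3, pad=1, rng=rng), ReLU(),
                               Conv2d(cout, cout, 3, pad=1, rng=rng))
        self.proj = Conv2d(cin, cout, 1, rng=rng) if cin != cout else None
        self.relu = ReLU()

    def params(self):
        ps = self.main.params()
        if self.proj is not None:
            ps = ps + self.proj.params()
        return ps

    def forward(self, x, train=False):
        s = x if self.proj is None else self.proj.forward(x, train=train)
        return self.relu.forward(self.main.forward(x, train=train) + s, train=train)

    def backward(self, gy):
        g = self.relu.backward(gy)
        gx = self.main.backward(g)
        gx = gx + (g if self.proj is None else self.proj.backward(g))
        return gx


class DenseBlock(Layer):
    """DenseNet-style block: each conv3 sees the concatenation of all earlier maps."""

    def __init__(self, cin: int, growth: int, nlayers: int, *, rng: np.random.Generator):
        self.convs = [Sequential(Conv2d(cin + i * growth, growth, 3, pad=1, rng=rng), ReLU())
                      for i in range(nlayers)]
        self.cin, self.growth = cin, growth
        self.cout = cin + nlayers * growth

    def params(self):
        out = []
        for c in self.convs:
            out.extend(c.params())
        return out

    def forward(self, x, train=False):
        feats = x
        for conv in self.convs:
            y = conv.forward(feats, train=train)
            feats = np.concatenate([feats, y], axis=1)
        return feats

    def backward(self, gy):
        # walk layers in reverse, splitting the gradient of each concatenation
        g = gy
        for conv in reversed(self.convs):
            cin_i = g.shape[1] - self.growth
            g_in, g_new = g[:, :cin_i], g[:, cin_i:]
            g = np.ascontiguousarray(g_in) + conv.backward(np.ascontiguousarray(g_new))
        return g
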