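"""Minimal NumPy convolutional-network core for gland segmentation.

Implements exactly the pieces a small encoder-decoder (U-Net-style)
segmentation network needs — 3x3/1x1 convolutions via im2col, ReLU,
2x2 max pooling, nearest-neighbour upsampling with skip concatenation,
and the Adam optimizer — with hand-written backpropagation. Arrays are
(N, C, H, W) float32 throughout. Everything is deterministic given the
seed of the generator used for initialization and data shuffling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2D:
    """Same-padding convolution, kernel 3x3 or 1x1, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        assert k in (1, 3)
        self.k = k
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._xshape = x.shape
        if self.k == 1:
            self._cols = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n,c,h,w,3,3)
            self._cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * h * w, c * 9
            )
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = self._cols @ wmat.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        c_out = self.W.shape[0]
        d2 = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        wmat = self.W.reshape(c_out, -1)
        self.dW += (d2.T @ self._cols).reshape(self.W.shape)
        self.db += d2.sum(axis=0)
        dcols = d2 @ wmat  # (n*h*w, c*k*k)
        if self.k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """Two 3x3 convolutions with ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.c1, self.r1 = Conv2D(c_in, c_out, 3, rng), ReLU()
        self.c2, self.r2 = Conv2D(c_out, c_out, 3, rng), ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet:
    """Small plain U-Net: ``depth`` pooling levels, ``base_channels``
    channels at the top, doubling per level; single-channel logit head.

    Input height and width must be divisible by 2**depth. ``forward``
    returns logits; apply a sigmoid for gland probabilities.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.depth = depth
        self.base_channels = base_channels
        ch = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        c_in = 1
        for i in range(depth):
            self.enc.append((ConvBlock(c_in, ch[i], rng), MaxPool2()))
            c_in = ch[i]
        self.bottom = ConvBlock(c_in, ch[depth], rng)
        self.dec = []
        c_in = ch[depth]
        for i in reversed(range(depth)):
            self.dec.append((Upsample2(), ConvBlock(c_in + ch[i], ch[i], rng)))
            c_in = ch[i]
        self.head = Conv2D(c_in, 1, 1, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        skips = []
        for block, pool in self.enc:
            s = block.forward(x)
            skips.append(s)
            x = pool.forward(s)
        x = self.bottom.forward(x)
        self._skip_channels = []
        for (up, block), s in zip(self.dec, reversed(skips)):
            u = up.forward(x)
            self._skip_channels.append(s.shape[1])
            x = block.forward(np.concatenate([u, s], axis=1))
        return self.head.forward(x)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None].astype(np.float32))
        dskips = []
        for (up, block), cs in zip(reversed(self.dec), reversed(self._skip_channels)):
            dcat = block.backward(d)
            du, ds = dcat[:, :-cs], dcat[:, -cs:]
            dskips.append(ds)
            d = up.backward(du)
        d = self.bottom.backward(d)
        # dskips were collected top-level-first; deepest encoder comes first
        for (block, pool), ds in zip(reversed(self.enc), reversed(dskips)):
            d = block.backward(pool.backward(d) + ds)

    def params(self):
        ps = []
        for block, _ in self.enc:
            ps += block.params()
        ps += self.bottom.params()
        for _, block in self.dec:
            ps += block.params()
        ps += self.head.params()
        return ps

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0

    # --- checkpoint (de)serialization -------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match model architecture")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("checkpoint does not match model architecture")
            dst[...] = src


class Adam:
    """Adam optimizer over a parameter list of (param, grad) pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
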