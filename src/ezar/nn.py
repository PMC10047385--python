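"""Minimal numpy convolutional encoder-decoder for band segmentation.

A small, fully deterministic U-shaped network (double-conv blocks, 2x2 max
pooling, nearest-neighbour upsampling with skip concatenation, per-pixel
sigmoid output) trained with pixel-wise binary cross-entropy and an
RMSprop-style adaptive-gradient update.  Convolutions are im2col matrix
products; gradients are exact analytic backprop.  Everything runs
single-threaded on the CPU and is reproducible from the seed alone.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Conv2D", "MaxPool2x2", "UpsampleNearest2x", "ConvEncoderDecoder"]

_DTYPE = np.float32


class Conv2D:
    """Same-padded stride-1 convolution with bias, He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.w = rng.standard_normal((fan_in, c_out)).astype(_DTYPE) * np.sqrt(
            2.0 / fan_in
        )
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H, W, k, k) -> (B, H, W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        b, c, h, w = x.shape
        return (
            win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h, w, c * k * k)
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        cols = self._im2col(x).reshape(b * h * w, -1)
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._xshape
        dflat = dout.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.w.T).reshape(b, h, w, c, self.k, self.k)
        k, p = self.k, self.k // 2
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=_DTYPE)
        # col2im: accumulate each kernel offset as one shifted slice add.
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]

    def params_and_grads(self):
        yield self.w, self.dw
        yield self.b, self.db


class MaxPool2x2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        if train:
            # route the gradient to exactly one element per block even on
            # ties, otherwise tied blocks double-count the gradient
            self._argmax = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=_DTYPE)
        np.put_along_axis(
            dflat, self._argmax[..., None], dout[..., None].astype(_DTYPE), -1
        )
        dx = dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        )
        return dx.reshape(b, c, h, w)


class UpsampleNearest2x:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


#: Negative-side slope of the leaky rectifier.  A strictly positive slope
#: keeps gradients flowing everywhere: with hard ReLU a large early
#: adaptive-gradient step can silence every unit at once, collapsing the
#: network to a constant output it can never escape.
LEAKY_SLOPE = np.float32(0.1)


def _leaky(x):
    return np.where(x > 0, x, LEAKY_SLOPE * x)


class _DoubleConv:
    """conv -> leaky ReLU -> conv -> leaky ReLU."""

    def __init__(self, c_in, c_out, k, rng):
        self.conv1 = Conv2D(c_in, c_out, k, rng)
        self.conv2 = Conv2D(c_out, c_out, k, rng)

    def forward(self, x, train=True):
        a = self.conv1.forward(x, train)
        self._m1 = a > 0
        a = _leaky(a)
        z = self.conv2.forward(a, train)
        self._m2 = z > 0
        return _leaky(z)

    def backward(self, dout):
        one = np.float32(1.0)
        dout = dout * np.where(self._m2, one, LEAKY_SLOPE)
        da = self.conv2.backward(dout)
        da = da * np.where(self._m1, one, LEAKY_SLOPE)
        return self.conv1.backward(da)

    def layers(self):
        return [self.conv1, self.conv2]


class ConvEncoderDecoder:
    """U-shaped segmentation network producing per-pixel logits.

    Parameters
    ----------
    in_channels : input image channels (grayscale: 1).
    base_filters : channel count of the first encoder block; doubles per
        level.
    depth : number of 2x2 poolings; input side length must be a multiple
        of ``2**depth``.
    kernel : odd convolution kernel width.
    seed : initialisation seed.
    """

    def __init__(
        self,
        in_channels: int = 1,
        base_filters: int = 8,
        depth: int = 3,
        kernel: int = 5,
        seed: int = 0,
    ):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc: list[_DoubleConv] = []
        self.pools = [MaxPool2x2() for _ in range(depth)]
        self.ups = [UpsampleNearest2x() for _ in range(depth)]
        c = in_channels
        enc_channels = []
        for i in range(depth):
            c_out = base_filters * (2**i)
            self.enc.append(_DoubleConv(c, c_out, kernel, rng))
            enc_channels.append(c_out)
            c = c_out
        self.bottleneck = _DoubleConv(c, base_filters * 2**depth, kernel, rng)
        c = base_filters * 2**depth
        self.dec: list[_DoubleConv] = []
        for i in reversed(range(depth)):
            c_out = enc_channels[i]
            self.dec.append(_DoubleConv(c + c_out, c_out, kernel, rng))
            c = c_out
        self.head = Conv2D(c, 1, 1, rng)
        self._opt_cache: list[np.ndarray] | None = None

    # -- plumbing ---------------------------------------------------------
    def _all_convs(self) -> list[Conv2D]:
        convs: list[Conv2D] = []
        for block in self.enc:
            convs += block.layers()
        convs += self.bottleneck.layers()
        for block in self.dec:
            convs += block.layers()
        convs.append(self.head)
        return convs

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self._all_convs())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for c in self._all_convs():
            out += [c.w.copy(), c.b.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for c in self._all_convs():
            c.w = next(it).astype(_DTYPE).copy()
            c.b = next(it).astype(_DTYPE).copy()

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 3:
            x = x[:, None, :, :]
        side = x.shape[-1]
        if side % (2**self.depth) or x.shape[-2] % (2**self.depth):
            raise ValueError(
                f"input sides must be multiples of {2 ** self.depth}"
            )
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for block, up, skip in zip(self.dec, self.ups, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = block.forward(h, train)
        return self.head.forward(h, train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities, shape (B, H, W)."""
        z = self.forward_logits(x, train=False)
        return expit(z[:, 0])

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits.astype(_DTYPE))
        dskips = []
        # Walk the decoder in reverse build order.
        for idx in range(len(self.dec) - 1, -1, -1):
            d = self.dec[idx].backward(d)
            c_skip = self._skip_channels[idx]
            d_skip, d = d[:, :c_skip], d[:, c_skip:]
            dskips.append(d_skip)
            d = self.ups[idx].backward(d)
        d = self.bottleneck.backward(d)
        # dskips was appended from the last decoder block (shallowest level)
        # first, so it is already indexed like self.enc.
        for idx in range(self.depth - 1, -1, -1):
            d = self.pools[idx].backward(d)
            d = d + dskips[idx]
            d = self.enc[idx].backward(d)

    # -- training step ----------------------------------------------------
    def bce_loss_and_grad(
        self, logits: np.ndarray, targets: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Mean pixel-wise binary cross-entropy and d(loss)/d(logits)."""
        y = np.asarray(targets, dtype=_DTYPE)
        if y.ndim == 3:
            y = y[:, None]
        z = logits
        # log(1+exp(z)) computed stably
        loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
        p = expit(z)
        grad = (p - y) / y.size
        return float(loss), grad.astype(_DTYPE)

    def rmsprop_step(
        self, lr: float, rho: float = 0.9, eps: float = 1e-8
    ) -> None:
        convs = self._all_convs()
        if self._opt_cache is None:
            self._opt_cache = []
            for c in convs:
                self._opt_cache += [np.zeros_like(c.w), np.zeros_like(c.b)]
        i = 0
        for c in convs:
            for arr, grad in ((c.w, c.dw), (c.b, c.db)):
                cache = self._opt_cache[i]
                cache *= rho
                cache += (1 - rho) * grad * grad
                arr -= lr * grad / (np.sqrt(cache) + eps)
                i += 1

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One gradient step on a batch; returns the batch BCE loss."""
        logits = self.forward_logits(x, train=True)
        loss, grad = self.bce_loss_and_grad(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss (divergence)")
        self.backward_from_logits(grad)
        self.rmsprop_step(lr)
        return loss

    def eval_loss(self, x: np.ndarray, y: np.ndarray, batch: int = 16) -> float:
        total, n = 0.0, 0
        for i in range(0, len(x), batch):
            logits = self.forward_logits(x[i : i + batch], train=False)
            loss, _ = self.bce_loss_and_grad(logits, y[i : i + batch])
            total += loss * len(x[i : i + batch])
            n += len(x[i : i + batch])
        return total / max(n, 1)
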