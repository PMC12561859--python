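"""Minimal convolutional network framework (numpy, manual backprop).

Implements exactly what the segmentation task needs: 2-D convolution,
depthwise convolution, 2x2 transpose convolution, SiLU/ReLU, an encoder-
decoder network with skip connections, Adam, and binary cross-entropy on
logits.  Everything is float32, single-threaded numpy, and fully
deterministic for a fixed seed, which keeps training runs reproducible
bit-for-bit on one machine.

Array layout is NCHW.  The backward pass can record gradients at named
activations, which is what the saliency and Grad-CAM procedures consume.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError

__all__ = [
    "Conv2d", "DepthwiseConv2d", "ConvTranspose2x2", "UNet", "Adam",
    "bce_with_logits", "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Numerically stable mean BCE on logits; returns (loss, dlogits)."""
    z, y = logits, targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]              # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            out_hw) -> np.ndarray:
    n, c, h, w = x_shape
    ho, wo = out_hw
    dpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, k, k, ho, wo)
    for a in range(k):
        for b in range(k):
            dpad[:, :, a:a + stride * ho:stride,
                 b:b + stride * wo:stride] += d6[:, :, a, b]
    if pad:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class _Layer:
    def params(self) -> list[Param]:
        return [v for v in vars(self).values() if isinstance(v, Param)]


class Conv2d(_Layer):
    """Standard k x k convolution, stride/pad, He-normal init."""

    def __init__(self, cin, cout, k, stride, pad, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.standard_normal((cout, cin * k * k)) * std)
        self.b = Param(np.zeros(cout))
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self._cache = None

    def forward(self, x):
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.w.value, cols) + self.b.value[:, None]
        self._cache = (x.shape, cols, (ho, wo))
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, d, need_dx=True):
        x_shape, cols, out_hw = self._cache
        n = x_shape[0]
        d2 = d.reshape(n, self.cout, -1)
        self.w.grad += np.tensordot(d2, cols, axes=([0, 2], [0, 2]))
        self.b.grad += d2.sum(axis=(0, 2))
        if not need_dx:
            return None
        dcols = np.matmul(self.w.value.T, d2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_hw)


class DepthwiseConv2d(_Layer):
    """Per-channel k x k convolution (the EfficientNet-style spatial step)."""

    def __init__(self, c, k, stride, pad, rng: np.random.Generator):
        std = np.sqrt(2.0 / (k * k))
        self.w = Param(rng.standard_normal((c, k * k)) * std)
        self.b = Param(np.zeros(c))
        self.c, self.k, self.stride, self.pad = c, k, stride, pad
        self._cache = None

    def forward(self, x):
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        cols4 = cols.reshape(n, self.c, self.k * self.k, ho * wo)
        out = np.einsum("cj,ncjl->ncl", self.w.value, cols4)
        out += self.b.value[:, None]
        self._cache = (x.shape, cols4, (ho, wo))
        return out.reshape(n, self.c, ho, wo)

    def backward(self, d, need_dx=True):
        x_shape, cols4, out_hw = self._cache
        n = x_shape[0]
        d2 = d.reshape(n, self.c, -1)
        self.w.grad += np.einsum("ncl,ncjl->cj", d2, cols4)
        self.b.grad += d2.sum(axis=(0, 2))
        if not need_dx:
            return None
        dcols4 = self.w.value[None, :, :, None] * d2[:, :, None, :]
        dcols = dcols4.reshape(n, self.c * self.k * self.k, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_hw)


class ConvTranspose2x2(_Layer):
    """2x up-sampling transpose convolution (kernel 2, stride 2)."""

    def __init__(self, cin, cout, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 4))
        self.w = Param(rng.standard_normal((cin, cout, 2, 2)) * std)
        self.b = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        out = np.einsum("nchw,cfab->nfhawb", x, self.w.value)
        out = out.reshape(n, self.cout, 2 * h, 2 * w)
        out += self.b.value[None, :, None, None]
        self._cache = x
        return out

    def backward(self, d, need_dx=True):
        x = self._cache
        n, c, h, w = x.shape
        d6 = d.reshape(n, self.cout, h, 2, w, 2)
        self.w.grad += np.einsum("nchw,nfhawb->cfab", x, d6)
        self.b.grad += d.sum(axis=(0, 2, 3))
        if not need_dx:
            return None
        return np.einsum("nfhawb,cfab->nchw", d6, self.w.value)


class _SiLU:
    def forward(self, x):
        s = sigmoid(x)
        self._cache = (x, s)
        return x * s

    def backward(self, d):
        x, s = self._cache
        return d * (s * (1.0 + x * (1.0 - s)))


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


class _DWSepBlock(_Layer):
    """Depthwise 3x3 (optionally strided) + SiLU + pointwise 1x1 + SiLU."""

    def __init__(self, cin, cout, stride, rng):
        self.dw = DepthwiseConv2d(cin, 3, stride, 1, rng)
        self.act1 = _SiLU()
        self.pw = Conv2d(cin, cout, 1, 1, 0, rng)
        self.act2 = _SiLU()

    def forward(self, x):
        return self.act2.forward(self.pw.forward(self.act1.forward(self.dw.forward(x))))

    def backward(self, d, need_dx=True):
        d = self.pw.backward(self.act2.backward(d))
        return self.dw.backward(self.act1.backward(d), need_dx=need_dx)

    def params(self):
        return self.dw.params() + self.pw.params()


# ---------------------------------------------------------------------------
# The segmentation network
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder with skip connections and a 1-channel logit head.

    The encoder is a compact depthwise-separable convolutional hierarchy
    (widths w, 2w, 4w at resolutions 1, 1/2, 1/4); the decoder uses 2x2
    transpose convolutions with concatenated skip connections.  Input height
    and width must be multiples of 4.

    Grad-CAM layer selectors: ``"bottleneck"``, ``"dec1"`` (half
    resolution), ``"dec2"`` (full resolution).
    """

    GRADCAM_LAYERS = ("bottleneck", "dec1", "dec2")

    def __init__(self, width: int = 8, seed: int = 0, in_channels: int = 3):
        rng = np.random.default_rng(seed)
        w = int(width)
        self.width = w
        self.in_channels = in_channels
        self.stem = Conv2d(in_channels, w, 3, 1, 1, rng)
        self.stem_act = _SiLU()
        self.enc0 = _DWSepBlock(w, w, 1, rng)
        self.enc1 = _DWSepBlock(w, 2 * w, 2, rng)
        self.enc1b = _DWSepBlock(2 * w, 2 * w, 1, rng)
        self.enc2 = _DWSepBlock(2 * w, 4 * w, 2, rng)
        self.enc2b = _DWSepBlock(4 * w, 4 * w, 1, rng)
        self.up1 = ConvTranspose2x2(4 * w, 2 * w, rng)
        self.dec1 = Conv2d(4 * w, 2 * w, 3, 1, 1, rng)
        self.dec1_act = _ReLU()
        self.up2 = ConvTranspose2x2(2 * w, w, rng)
        self.dec2 = Conv2d(2 * w, w, 3, 1, 1, rng)
        self.dec2_act = _ReLU()
        self.head = Conv2d(w, 1, 1, 1, 0, rng)
        self._layers = [
            self.stem, self.enc0, self.enc1, self.enc1b, self.enc2,
            self.enc2b, self.up1, self.dec1, self.up2, self.dec2, self.head,
        ]
        self.activations: dict[str, np.ndarray] = {}

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        return [p for layer in self._layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise InputError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            v = np.asarray(state[f"p{i}"], dtype=np.float32)
            if v.shape != p.value.shape:
                raise InputError("checkpoint does not match model architecture")
            p.value = v.copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise InputError(f"expected (N, {self.in_channels}, H, W) input")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise InputError("input height/width must be multiples of 4")
        e0 = self.enc0.forward(self.stem_act.forward(self.stem.forward(x)))
        e1 = self.enc1b.forward(self.enc1.forward(e0))
        e2 = self.enc2b.forward(self.enc2.forward(e1))
        u1 = self.up1.forward(e2)
        d1 = self.dec1_act.forward(self.dec1.forward(np.concatenate([u1, e1], axis=1)))
        u2 = self.up2.forward(d1)
        d2 = self.dec2_act.forward(self.dec2.forward(np.concatenate([u2, e0], axis=1)))
        logits = self.head.forward(d2)
        self.activations = {"bottleneck": e2, "dec1": d1, "dec2": d2}
        return logits

    __call__ = forward

    def backward(self, dlogits: np.ndarray, need_input_grad: bool = False,
                 record: tuple[str, ...] = ()) -> np.ndarray | None:
        """Backpropagate; optionally return d(input) and record activation
        gradients (available afterwards in ``self.activation_grads``)."""
        self.activation_grads: dict[str, np.ndarray] = {}
        w2 = self.width
        d_d2 = self.head.backward(dlogits)
        if "dec2" in record:
            self.activation_grads["dec2"] = d_d2.copy()
        d_cat2 = self.dec2.backward(self.dec2_act.backward(d_d2))
        d_u2, d_e0 = d_cat2[:, :w2], d_cat2[:, w2:]
        d_d1 = self.up2.backward(d_u2)
        if "dec1" in record:
            self.activation_grads["dec1"] = d_d1.copy()
        d_cat1 = self.dec1.backward(self.dec1_act.backward(d_d1))
        d_u1, d_e1 = d_cat1[:, :2 * w2], d_cat1[:, 2 * w2:]
        d_e2 = self.up1.backward(d_u1)
        if "bottleneck" in record:
            self.activation_grads["bottleneck"] = d_e2.copy()
        d_e1 = d_e1 + self.enc2.backward(self.enc2b.backward(d_e2))
        d_e0 = d_e0 + self.enc1.backward(self.enc1b.backward(d_e1))
        d_stem = self.stem_act.backward(self.enc0.backward(d_e0))
        return self.stem.backward(d_stem, need_dx=need_input_grad)


class Adam:
    """Adam with in-place updates; ``lr`` is mutable for scheduling."""

    def __init__(self, params: list[Param], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
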