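"""Convolutional detector turning an 8-echo spectral stack into per-point
signal confidences.

The model reads a (1 × W × H) stack — W frequency points, H echo spectra —
and emits one confidence in [0, 1] per frequency point.  Three stages:

1. residual convolutional feature extraction along the frequency axis,
   applied to every echo row with shared weights (dilated kernels widen the
   receptive field to cover full multiplets);
2. echo down-sampling: strided convolutions fuse the echo dimension
   H → H/2 → … → 1 while expanding channels 1 → C, correlating the phase
   behaviour of the same resonance across echo times;
3. step-wise channel merging C → … → 1, each step followed by a softmax over
   the frequency axis (rescaled by W) that sparsifies the features, and a
   final per-point sigmoid bounding the output to [0, 1].

Everything — layers, backprop, initialization — is implemented directly on
NumPy arrays in (batch, channel, echo, frequency) layout, with convolutions
expressed as sums of shifted tensor contractions so the heavy lifting stays
in BLAS.  The network is fully convolutional along the frequency axis, so a
model trained at one width runs unchanged on any other width (e.g. spectra
zero-filled to a multiple of 4096 points).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkConfig", "ModelState", "build_model", "forward", "count_parameters"]

DTYPE = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    width is the nominal frequency size (the net runs at any width);
    n_echoes is H; stem_channels the per-echo feature width; channels the
    width C after echo fusion; merge_schedule the step-wise channel
    reduction, which must be strictly decreasing and end at 1.
    """

    width: int = 4096
    n_echoes: int = 8
    stem_channels: int = 16
    channels: int = 64
    n_res_blocks: int = 4
    kernel_w: int = 3
    head_kernel_w: int = 3  # widening the head smooths the confidence map
    # (fewer one-bin holes) at the cost of blurring wide-multiplet centers
    res_dilations: tuple[int, ...] = (1, 2, 4, 8)
    merge_schedule: tuple[int, ...] = (16, 4, 1)

    def __post_init__(self) -> None:
        if self.n_echoes < 1 or self.n_echoes & (self.n_echoes - 1):
            raise ValueError("n_echoes must be a positive power of two")
        if self.kernel_w % 2 != 1 or self.head_kernel_w % 2 != 1:
            raise ValueError("kernel widths must be odd")
        sched = (self.channels,) + tuple(self.merge_schedule)
        if any(b >= a for a, b in zip(sched, sched[1:])):
            raise ValueError("merge_schedule must be strictly decreasing from channels")
        if sched[-1] != 1:
            raise ValueError("merge_schedule must end at 1")
        if self.n_res_blocks < 0 or self.stem_channels < 1:
            raise ValueError("invalid stem configuration")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("res_dilations", "merge_schedule"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ----------------------------------------------------------------------------
# Layers (NumPy, manual backprop; layout N × C × H × W)
# ----------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Convolution with kernel (kh × kw); 'same' zero padding along W (with
    dilation), no padding and optional stride along the echo axis H."""

    def __init__(self, in_c, out_c, kh=1, kw=3, stride_h=1, dilation_w=1,
                 bias=True, rng=None, weight_scale=None, bias_init=0.0):
        self.in_c, self.out_c = in_c, out_c
        self.kh, self.kw = kh, kw
        self.stride_h = stride_h
        self.dilation_w = dilation_w
        fan_in = in_c * kh * kw
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, scale, size=(out_c, in_c, kh, kw)))
        self.bias = Param(np.full(out_c, bias_init)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad_w(self) -> int:
        return self.dilation_w * (self.kw // 2)

    def _im2col(self, x):
        """Gather kernel taps into (N, C·kh·kw, H_out·W) for one batched GEMM."""
        n, c, h, w = x.shape
        h_out = (h - self.kh) // self.stride_h + 1
        pw = self._pad_w()
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pw, pw))) if pw else x
        col = np.empty((n, c, self.kh, self.kw, h_out, w), dtype=DTYPE)
        for i in range(self.kh):
            rows = xp[:, :, i : i + self.stride_h * (h_out - 1) + 1 : self.stride_h, :]
            for j in range(self.kw):
                col[:, :, i, j] = rows[..., j * self.dilation_w : j * self.dilation_w + w]
        return col.reshape(n, c * self.kh * self.kw, h_out * w), h_out

    def forward(self, x, train):
        n, c, h, w = x.shape
        if c != self.in_c:
            raise ValueError(f"expected {self.in_c} channels, got {c}")
        if h < self.kh:
            raise ValueError(f"echo dimension {h} smaller than kernel {self.kh}")
        col, h_out = self._im2col(x)
        w2 = self.weight.value.reshape(self.out_c, -1)
        out = np.matmul(w2[None], col).reshape(n, self.out_c, h_out, w)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        if train:
            self._cache = (col, x.shape, h_out)
        return out

    def backward(self, grad):
        col, x_shape, h_out = self._cache
        n, c, h, w = x_shape
        g = np.ascontiguousarray(grad).reshape(n, self.out_c, h_out * w)
        self.weight.grad += np.tensordot(
            g, col, axes=([0, 2], [0, 2])
        ).reshape(self.weight.value.shape)
        w2 = self.weight.value.reshape(self.out_c, -1)
        dcol = np.matmul(w2.T[None], g).reshape(n, c, self.kh, self.kw, h_out, w)
        # scatter-add the taps back onto the (padded) input grid
        pw = self._pad_w()
        dxp = np.zeros((n, c, h, w + 2 * pw), dtype=DTYPE)
        for i in range(self.kh):
            drows = dxp[:, :, i : i + self.stride_h * (h_out - 1) + 1 : self.stride_h, :]
            for j in range(self.kw):
                drows[..., j * self.dilation_w : j * self.dilation_w + w] += dcol[:, :, i, j]
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        self._cache = None
        return dxp[..., pw : pw + w] if pw else dxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out.astype(DTYPE)

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        # batch-norm backward: dL/dx = γ·inv/m · (m·dy − Σdy − x̂·Σ(dy·x̂))
        sum_grad = grad.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_grad_xhat = (grad * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (g * inv[None, :, None, None] / m) * (m * grad - sum_grad - xhat * sum_grad_xhat)
        self._cache = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class SoftmaxW(Layer):
    """Softmax over the frequency axis within each channel, rescaled by W so
    a flat input stays at magnitude 1 while localized features sharpen."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        y = (p * x.shape[-1]).astype(DTYPE)
        if train:
            self._cache = p
        return y

    def backward(self, grad):
        p = self._cache
        w = grad.shape[-1]
        dot = (grad * p).sum(axis=-1, keepdims=True)
        dx = w * p * (grad - dot)
        self._cache = None
        return dx.astype(DTYPE)


class Sigmoid(Layer):
    """Final confidence activation.

    Evaluated in float64: saturated detections (broad lines firing over many
    points) stay strictly ordered by their logits instead of rounding to a
    flat 1.0 plateau, so downstream run-collapse can localize the maximum.
    """

    def __init__(self):
        self._y = None

    def forward(self, x, train):
        xd = x.astype(np.float64)
        z = np.exp(-np.abs(xd))
        y = np.where(xd >= 0, 1.0 / (1.0 + z), z / (1.0 + z))
        if train:
            y = y.astype(DTYPE)
            self._y = y
        return y

    def backward(self, grad):
        g = grad * self._y * (1 - self._y)
        self._y = None
        return g.astype(DTYPE)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = [l for l in layers if l is not None]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Residual(Layer):
    """y = relu(x + body(x)); body must preserve shape."""

    def __init__(self, body: Sequential):
        self.body = body
        self._mask = None

    def params(self):
        return self.body.params()

    def forward(self, x, train):
        s = x + self.body.forward(x, train)
        out = np.maximum(s, 0)
        if train:
            self._mask = s > 0
        return out

    def backward(self, grad):
        grad = grad * self._mask
        self._mask = None
        return grad + self.body.backward(grad)


# ----------------------------------------------------------------------------
# Model assembly
# ----------------------------------------------------------------------------

@dataclass
class ModelState:
    """A built network plus the metadata needed to rebuild / verify it."""

    net: Sequential
    config: NetworkConfig
    config_hash: str
    seed: int
    step: int = 0

    def params(self) -> list[Param]:
        return self.net.params()

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


def _res_block(c, kw, dilation, rng):
    return Residual(Sequential(
        Conv2d(c, c, 1, kw, dilation_w=dilation, bias=False, rng=rng),
        BatchNorm2d(c),
        ReLU(),
        Conv2d(c, c, 1, kw, dilation_w=dilation, bias=False, rng=rng),
        BatchNorm2d(c),
    ))


def build_model(cfg: NetworkConfig, seed: int = 0) -> ModelState:
    """Construct the network with seeded He initialization.

    Two builds from the same config and seed produce identical parameters.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    kw = cfg.kernel_w

    # stage 1: per-echo residual feature extraction
    layers += [Conv2d(1, cfg.stem_channels, 1, kw, bias=False, rng=rng),
               BatchNorm2d(cfg.stem_channels), ReLU()]
    dil = cfg.res_dilations
    for b in range(cfg.n_res_blocks):
        layers.append(_res_block(cfg.stem_channels, kw, dil[b % len(dil)], rng))

    # stage 2: echo down-sampling H → 1 with channel expansion → C
    n_down = int(np.log2(cfg.n_echoes))
    c_prev = cfg.stem_channels
    for i in range(1, n_down + 1):
        c_next = int(round(cfg.stem_channels *
                           (cfg.channels / cfg.stem_channels) ** (i / n_down)))
        layers += [Conv2d(c_prev, c_next, 2, kw, stride_h=2, bias=False, rng=rng),
                   BatchNorm2d(c_next), ReLU()]
        c_prev = c_next
    if cfg.n_echoes == 1:  # degenerate single-spectrum configuration
        layers += [Conv2d(c_prev, cfg.channels, 1, kw, bias=False, rng=rng),
                   BatchNorm2d(cfg.channels), ReLU()]
        c_prev = cfg.channels

    # stage 3: step-wise channel merging with a softmax per step; batch norm
    # keeps the softmax inputs O(1) so it sparsifies instead of saturating
    for c_next in cfg.merge_schedule[:-1]:
        layers += [Conv2d(c_prev, c_next, 1, kw, bias=False, rng=rng),
                   BatchNorm2d(c_next), SoftmaxW()]
        c_prev = c_next

    # final merge to one channel is the confidence head itself: reading the
    # full channel stack avoids a scalar bottleneck, and the negative bias
    # starts the detector sparse (labels are overwhelmingly 0), the usual
    # prior for dense detection
    layers += [Conv2d(c_prev, 1, 1, cfg.head_kernel_w, rng=rng,
                      weight_scale=0.1, bias_init=-4.0),
               Sigmoid()]

    return ModelState(net=Sequential(*layers), config=cfg,
                      config_hash=cfg.hash(), seed=seed)


def _as_nchw(x: np.ndarray, n_echoes: int) -> np.ndarray:
    """Accept (H,W), (N,H,W) or (N,1,W,H) input and return (N,1,H,W)."""
    x = np.asarray(x, dtype=DTYPE)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        if x.shape[1] != n_echoes:
            raise ValueError(f"expected {n_echoes} echo rows, got {x.shape[1]}")
        return x[:, None, :, :]
    if x.ndim == 4:
        if x.shape[1] == 1 and x.shape[3] == n_echoes:
            return x.transpose(0, 1, 3, 2)
        if x.shape[1] == 1 and x.shape[2] == n_echoes:
            return x
    raise ValueError(f"cannot interpret input of shape {x.shape}")


def forward(model: ModelState, x: np.ndarray, train: bool = False) -> np.ndarray:
    """Run the network; returns confidences of shape (N, W) in [0, 1]."""
    xb = _as_nchw(x, model.config.n_echoes)
    out = model.net.forward(xb, train)
    return out[:, 0, 0, :]


def count_parameters(model: ModelState) -> int:
    return model.n_parameters
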