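"""Minimal CNN layer zoo with hand-derived backward passes.

Everything runs on numpy arrays in NCHW layout.  Each layer caches what its
backward pass needs; ``forward``/``backward`` must therefore be called in
strict alternation for gradient computation.  Parameters are ``Param``
objects carrying value and gradient side by side, which keeps the optimizer
trivially generic.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "Dropout",
    "Sequential",
    "relu",
]


def relu(x):
    """Rectified linear unit, ``max(0, x)``, elementwise."""
    return np.maximum(0, np.asarray(x))


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class; stateless layers simply do not override ``params``."""

    def params(self) -> List[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution with 'same'-style padding and optional stride.

    Padding is ``(k - 1) // 2``, so odd kernels preserve spatial size at
    stride 1 and halve it (rounding up) at stride 2.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = True, name: str = "conv"):
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel_size, stride
        self.pad = (kernel_size - 1) // 2
        self.weight = Param(np.zeros((out_channels, in_channels, kernel_size, kernel_size)),
                            name=f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def params(self) -> List[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=True, rng=None):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p, s = self.pad, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win[:, :, ::s, ::s]                      # (n, c, ho, wo, k, k)
        out = np.einsum("nchwij,ocij->nohw", cols, self.weight.value, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        self._cols, self._xshape = cols, x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._xshape
        p, s, k = self.pad, self.stride, self.k
        self.weight.grad += np.einsum("nchwij,nohw->ocij", self._cols, grad, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        ho, wo = grad.shape[2], grad.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                contrib = np.tensordot(grad, self.weight.value[:, :, i, j], axes=([1], [0]))
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += contrib.transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel == stride (exact upsampling).

    Each input pixel paints a ``k x k`` output block, so spatial size is
    multiplied by ``k`` with no overlap — the classic U-Net 2x2 up-convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 bias: bool = True, name: str = "upconv"):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.weight = Param(np.zeros((in_channels, out_channels, kernel_size, kernel_size)),
                            name=f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self._x: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=True, rng=None):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k = self.k
        out = np.einsum("nchw,coij->nohiwj", x, self.weight.value, optimize=True)
        out = out.reshape(n, self.cout, h * k, w * k)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        self._x = x
        return out

    def backward(self, grad):
        n, _, hk, wk = grad.shape
        k = self.k
        g = grad.reshape(n, self.cout, hk // k, k, wk // k, k)  # n,o,h,i,w,j
        self.weight.grad += np.einsum("nchw,nohiwj->coij", self._x, g, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = np.einsum("nohiwj,coij->nchw", g, self.weight.value, optimize=True)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel normalization using minibatch statistics.

    With the training protocol's minibatch of one this normalizes over the
    spatial extent of the single slice, and the same batch statistics are
    used at prediction time, keeping train and test behaviour identical.
    Running statistics are tracked for completeness but are not trainable.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.c, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Param(np.ones(channels), name=f"{name}.scale")
        self.beta = Param(np.zeros(channels), name=f"{name}.offset")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, train=True, rng=None):
        axes = (0, 2, 3)
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
        self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        dmean = grad.mean(axis=axes)[None, :, None, None]
        dproj = (grad * xhat).mean(axis=axes)[None, :, None, None]
        dx = g / std[None, :, None, None] * (grad - dmean - xhat * dproj)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True, rng=None):
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 max pooling; input spatial dimensions must be even."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=True, rng=None):
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool size {s}")
        xr = x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // s, w // s, s * s)
        self._argmax = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._inshape
        s = self.size
        flat = np.zeros((n, c, h // s, w // s, s * s))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        out = flat.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Dropout(Layer):
    """Inverted dropout applied in both training and prediction.

    Keeping dropout active at test time follows the image-translation
    convention of treating it as the generator's noise source; prediction
    determinism then comes from seeding the generator's random stream.
    """

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=True, rng=None):
        if self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout requires a random generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=True, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
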