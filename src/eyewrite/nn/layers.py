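"""Minimal numpy layer library with manual backpropagation.

Just the pieces the eye-writing classifier needs: 1-D convolutions
(standard, depthwise-dilated-causal, pointwise), batch normalization, max
pooling, ELU/ReLU/sigmoid activations, dropout, a linear head, and a
squeeze-and-excitation gate.  Every layer implements ``forward`` (caching
what its backward pass needs) and ``backward`` (returning the gradient
with respect to its input and accumulating parameter gradients).

Feature maps are channels-first: ``(batch, channels, time)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv1d",
    "DepthwiseConv1d",
    "DepthwiseSeparableCausalConv",
    "Linear",
    "BatchNorm1d",
    "MaxPool1d",
    "ReLU",
    "ELU",
    "Dropout",
    "Flatten",
    "SEBlock",
]


class Param:
    """A learnable array and its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def astype(self, dtype) -> None:
        self.data = self.data.astype(dtype)
        self.grad = self.grad.astype(dtype)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base layer: stateless by default, trains unless told otherwise."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Conv1d(Layer):
    """Standard 1-D convolution with 'same' or 'causal' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, padding: str = "same", bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        span = (kernel - 1) * dilation
        if padding == "same":
            if span % 2:
                raise ValueError("'same' padding needs odd kernel span")
            self.pad_left = self.pad_right = span // 2
        elif padding == "causal":
            self.pad_left, self.pad_right = span, 0
        else:
            raise ValueError(f"unknown padding {padding!r}")
        fan_in = in_channels * kernel
        self.W = Param(_uniform_init(rng, (out_channels, in_channels, kernel),
                                     fan_in), "conv.W")
        self.b = Param(_uniform_init(rng, (out_channels,), fan_in),
                       "conv.b") if bias else None

    def forward(self, x, training=False):
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        if self.kernel == 1:
            y = np.einsum("oi,bit->bot", self.W.data[:, :, 0], xp,
                          optimize=True)
            self._xw = xp[:, :, :, None]
        else:
            span = (self.kernel - 1) * self.dilation + 1
            xw = np.lib.stride_tricks.sliding_window_view(
                xp, span, axis=-1)[..., ::self.dilation]  # (B, C, T, k)
            y = np.einsum("bitk,oik->bot", xw, self.W.data, optimize=True)
            self._xw = xw
        if self.b is not None:
            y += self.b.data[None, :, None]
        self._pad_shape = xp.shape
        self._T = T
        return y

    def backward(self, dy):
        T = self._T
        self.W.grad += np.einsum("bot,bitk->oik", dy, self._xw,
                                 optimize=True)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros(self._pad_shape, dtype=dy.dtype)
        dxw = np.einsum("bot,oik->bitk", dy, self.W.data, optimize=True)
        for u in range(self.kernel):
            off = u * self.dilation
            dxp[:, :, off:off + T] += dxw[..., u]
        end = dxp.shape[2] - self.pad_right
        return dxp[:, :, self.pad_left:end]

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class DepthwiseConv1d(Layer):
    """Depthwise dilated causal convolution: one k-tap filter per channel.

    Left-only zero padding of (k-1)*dilation samples makes the output at
    time t depend only on inputs at times <= t.
    """

    def __init__(self, channels: int, kernel: int, dilation: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel = kernel
        self.dilation = dilation
        self.pad_left = (kernel - 1) * dilation
        self.W = Param(_uniform_init(rng, (channels, kernel), kernel), "dw.W")
        self.b = Param(np.zeros(channels), "dw.b") if bias else None

    def forward(self, x, training=False):
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, 0)))
        y = np.zeros_like(x)
        for u in range(self.kernel):
            off = u * self.dilation
            y += self.W.data[None, :, u, None] * xp[:, :, off:off + T]
        if self.b is not None:
            y += self.b.data[None, :, None]
        self._xp = xp
        self._T = T
        return y

    def backward(self, dy):
        xp, T = self._xp, self._T
        dxp = np.zeros_like(xp)
        for u in range(self.kernel):
            off = u * self.dilation
            self.W.grad[:, u] += np.einsum("bct,bct->c", dy,
                                           xp[:, :, off:off + T],
                                           optimize=True)
            dxp[:, :, off:off + T] += dy * self.W.data[None, :, u, None]
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2))
        return dxp[:, :, self.pad_left:]

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class DepthwiseSeparableCausalConv(Layer):
    """Depthwise dilated causal filter followed by pointwise 1x1 mixing.

    The factorisation costs C_in*k + C_in*C_out weights (no biases)
    against C_in*C_out*k for the standard convolution it replaces, while
    keeping the causal receptive-field structure.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv1d(in_channels, kernel, dilation,
                                         bias=False, rng=rng)
        self.pointwise = Conv1d(in_channels, out_channels, kernel=1,
                                padding="same", bias=False, rng=rng)

    def forward(self, x, training=False):
        return self.pointwise.forward(self.depthwise.forward(x, training),
                                      training)

    def backward(self, dy):
        return self.depthwise.backward(self.pointwise.backward(dy))

    def parameters(self):
        return self.depthwise.parameters() + self.pointwise.parameters()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_uniform_init(rng, (out_features, in_features),
                                     in_features), "linear.W")
        self.b = Param(_uniform_init(rng, (out_features,), in_features),
                       "linear.b")

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data

    def parameters(self):
        return [self.W, self.b]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        y = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        self._cache = (xhat, std, training)
        return y

    def backward(self, dy):
        xhat, std, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.data[None, :, None]
        if not training:
            return dy * g / std[None, :, None]
        mean_dy = dy.mean(axis=(0, 2), keepdims=True)
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 2), keepdims=True)
        return g / std[None, :, None] * (dy - mean_dy - xhat * mean_dy_xhat)

    def parameters(self):
        return [self.gamma, self.beta]


class MaxPool1d(Layer):
    """Temporal max pooling; edges padded with -inf so real samples win."""

    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def out_length(self, T: int) -> int:
        return (T + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x, training=False):
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel,
                                                       axis=-1)
        win = win[:, :, ::self.stride, :]
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        B, C, T = self._in_shape
        T_out = dy.shape[2]
        dx = np.zeros((B, C, T), dtype=dy.dtype)
        starts = np.arange(T_out) * self.stride - self.padding
        # for each window tap u the target positions are distinct, so the
        # scatter decomposes into k masked gathers (no atomic add needed)
        for u in range(self.kernel):
            pos = starts + u  # index into unpadded x
            valid = (pos >= 0) & (pos < T)
            contrib = dy * (self._arg == u)
            dx[:, :, pos[valid]] += contrib[:, :, valid]
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training=False):
        neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        self._y_neg = neg
        self._mask = x > 0
        return np.where(self._mask, x, neg)

    def backward(self, dy):
        return dy * np.where(self._mask, 1.0, self._y_neg + self.alpha)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.p
        self._mask = keep.astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Global average pooling over time gives per-channel statistics; a
    bottleneck C -> C/r -> C with ReLU then sigmoid produces gates in
    (0, 1) that rescale each channel uniformly over time.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by the SE "
                f"reduction ratio ({reduction})")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x, training=False):
        B, C, T = x.shape
        s = x.mean(axis=2)
        h = self.fc1.forward(s, training)
        h_act = np.maximum(h, 0.0)
        z = self.fc2.forward(h_act, training)
        g = 1.0 / (1.0 + np.exp(-z))
        self._cache = (x, h, g, T)
        return x * g[:, :, None]

    def backward(self, dy):
        x, h, g, T = self._cache
        dg = (dy * x).sum(axis=2)
        dx = dy * g[:, :, None]
        dz = dg * g * (1.0 - g)
        dh_act = self.fc2.backward(dz)
        dh = dh_act * (h > 0)
        ds = self.fc1.backward(dh)
        dx += ds[:, :, None] / T
        return dx

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()
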