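"""Layer primitives with explicit forward/backward passes.

Activations are kept in channels-last layout (N, H, W, C): 3x3 convolution
is computed as nine tap-shifted matrix products over the channel axis,
which keeps every large operation a contiguous BLAS call on one CPU.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """3x3 stride-1 same-size convolution with bias, He-initialized.

    Borders are replicate-padded ("edge"): plot imagery continues past the
    crop, and zero padding would manufacture a salient dark frame that
    distorts class-activation maps at the image border.

    ``first=True`` marks the input layer: its input gradient is never
    needed, so backward skips the transposed convolution.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        first: bool = False,
    ):
        if k != 3:
            raise ValueError("only 3x3 kernels are supported")
        std = np.sqrt(2.0 / (c_in * k * k))
        # tap-major layout: (k, k, C_in, C_out)
        self.weight = Param(rng.normal(0.0, std, (k, k, c_in, c_out)).astype(np.float32))
        self.bias = Param(np.zeros(c_out, dtype=np.float32))
        self.k = k
        self.first = first
        self._taps: list[np.ndarray] | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="edge")
        out = np.empty((n * h * w, self.weight.value.shape[-1]), dtype=np.float32)
        out[:] = self.bias.value
        taps = []
        wv = self.weight.value
        for u in range(k):
            for v in range(k):
                s = np.ascontiguousarray(xp[:, u : u + h, v : v + w, :]).reshape(-1, c)
                taps.append(s)
                out += s @ wv[u, v]
        self._taps = taps
        self._in_shape = (n, h, w, c)
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        n, h, w, c = self._in_shape
        k, p = self.k, self.k // 2
        c_out = dout.shape[-1]
        doutr = dout.reshape(-1, c_out)
        dw = self.weight.grad
        for i, s in enumerate(self._taps):
            dw[i // k, i % k] += s.T @ doutr
        self.bias.grad += doutr.sum(axis=0)
        self._taps = None
        if self.first:
            return None
        wv = self.weight.value
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for u in range(k):
            for v in range(k):
                dxp[:, u : u + h, v : v + w, :] += (doutr @ wv[u, v].T).reshape(
                    n, h, w, c
                )
        # fold the pad-ring gradient back onto the replicated border pixels
        dx = np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])
        dx[:, 0, :, :] += dxp[:, 0, p : p + w, :]
        dx[:, -1, :, :] += dxp[:, h + p, p : p + w, :]
        dx[:, :, 0, :] += dxp[:, p : p + h, 0, :]
        dx[:, :, -1, :] += dxp[:, p : p + h, w + p, :]
        dx[:, 0, 0, :] += dxp[:, 0, 0, :]
        dx[:, 0, -1, :] += dxp[:, 0, w + p, :]
        dx[:, -1, 0, :] += dxp[:, h + p, 0, :]
        dx[:, -1, -1, :] += dxp[:, h + p, w + p, :]
        return dx


class ReLU:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 stride-2 max pooling; input sides must be even.

    Backward routes gradient to locations equal to the window maximum
    (exact positive-value ties, vanishingly rare for conv activations,
    would each receive the full gradient).
    """

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        m = np.maximum(x[:, 0::2], x[:, 1::2])
        out = np.maximum(m[:, :, 0::2], m[:, :, 1::2])
        self._x = x
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        up_out = self._out.repeat(2, axis=1).repeat(2, axis=2)
        up_d = dout.repeat(2, axis=1).repeat(2, axis=2)
        return np.where(self._x == up_out, up_d, 0.0).astype(dout.dtype)


class GlobalAvgPool:
    """Spatial mean of each feature map (GAP)."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(
            dout[:, None, None, :] / (h * w), (n, h, w, c)
        ).astype(dout.dtype)


class Linear:
    """Fully connected layer ``y = x W^T (+ b)``."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias: bool = True,
        dtype=np.float32,
    ):
        std = np.sqrt(1.0 / n_in)
        self.weight = Param(rng.normal(0.0, std, (n_out, n_in)).astype(dtype))
        self.bias = Param(np.zeros(n_out, dtype=dtype)) if bias else None

    @property
    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += (dout.T @ self._x).astype(self.weight.grad.dtype)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0).astype(self.bias.grad.dtype)
        return (dout @ self.weight.value).astype(self._x.dtype)
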