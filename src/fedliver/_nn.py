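"""Minimal CNN layer stack with manual backpropagation.

Array convention is channels-last: activations are (N, H, W, C) float32.
Each layer owns its parameters and, after a backward pass, their gradients.
Only what the classifier family needs is implemented: 3x3 same-padding
convolution, 2x2 max pooling, dense layers, ReLU, and a flatten.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def init(self, rng: np.random.Generator) -> None:
        pass


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """3x3 convolution with stride 1 and zero same-padding."""

    def __init__(self, name: str, in_ch: int, out_ch: int, k: int = 3) -> None:
        super().__init__()
        self.name = name
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.params = {
            f"{name}/W": np.zeros((k, k, in_ch, out_ch), dtype=np.float32),
            f"{name}/b": np.zeros(out_ch, dtype=np.float32),
        }

    def init(self, rng: np.random.Generator) -> None:
        k, ci, co = self.k, self.in_ch, self.out_ch
        self.params[f"{self.name}/W"] = _glorot(rng, (k, k, ci, co), k * k * ci, k * k * co)
        self.params[f"{self.name}/b"] = np.zeros(co, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * self.in_ch)
        self._cols, self._shape = cols, (n, h, w)
        W = self.params[f"{self.name}/W"].transpose(0, 1, 2, 3).reshape(-1, self.out_ch)
        out = cols @ W + self.params[f"{self.name}/b"]
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w = self._shape
        dcols = dy.reshape(n * h * w, self.out_ch)
        Wname, bname = f"{self.name}/W", f"{self.name}/b"
        self.grads[bname] = dcols.sum(axis=0)
        dW = self._cols.T @ dcols
        self.grads[Wname] = dW.reshape(k, k, self.in_ch, self.out_ch)
        W = self.params[Wname].reshape(-1, self.out_ch)
        dx_cols = (dcols @ W.T).reshape(n, h, w, k, k, self.in_ch)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_ch), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dx_cols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties share the gradient equally."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {(h, w)}")
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        mask = r == out[:, :, None, :, None, :]
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        self._shape = (n, h, w, c)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        d = self._mask * dy[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, name: str, n_in: int, n_out: int) -> None:
        super().__init__()
        self.name = name
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            f"{name}/W": np.zeros((n_in, n_out), dtype=np.float32),
            f"{name}/b": np.zeros(n_out, dtype=np.float32),
        }

    def init(self, rng: np.random.Generator) -> None:
        self.params[f"{self.name}/W"] = _glorot(
            rng, (self.n_in, self.n_out), self.n_in, self.n_out
        )
        self.params[f"{self.name}/b"] = np.zeros(self.n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[f"{self.name}/W"] + self.params[f"{self.name}/b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[f"{self.name}/W"] = self._x.T @ dy
        self.grads[f"{self.name}/b"] = dy.sum(axis=0)
        return dy @ self.params[f"{self.name}/W"].T
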