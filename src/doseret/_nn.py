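"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the dose encoder needs: stride-1 "same" 3D convolution, ReLU,
batch normalization (running statistics for evaluation), 2x2x2 max pooling,
a fully connected layer, L2 output normalization, and Adam.  Data layout is
``(batch, channels, x, y, z)`` in float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d",
    "ReLU",
    "BatchNorm3d",
    "MaxPool3d",
    "Flatten",
    "Linear",
    "L2Normalize",
    "Sequential",
    "Adam",
    "glorot_normal",
]


def glorot_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Layer:
    """A layer with optional parameters; subclasses cache what backward needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]
    #: state carried between train and eval but not optimized (BN stats)
    buffers: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}
        self.buffers = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero 'same' padding, via im2col."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        k = 27 * in_channels
        w = glorot_normal(rng, (out_channels, in_channels, 3, 3, 3), k, 27 * out_channels)
        self.params = {"w": w, "b": np.zeros(out_channels, dtype=np.float32)}

    def _wmat(self) -> np.ndarray:
        # (cin*27, cout) layout matching the im2col column order
        return self.params["w"].reshape(self.cout, -1).T

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, X, Y, Z = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
        # -> (b, X, Y, Z, c*27)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            b * X * Y * Z, c * 27
        )
        out = cols @ self._wmat() + self.params["b"]
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            out.reshape(b, X, Y, Z, self.cout).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        b, c, X, Y, Z = xshape
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        dwmat = cols.T @ gflat  # (c*27, cout)
        self.grads["w"] = np.ascontiguousarray(dwmat.T).reshape(self.params["w"].shape)
        self.grads["b"] = gflat.sum(axis=0)
        dcols = (gflat @ self._wmat().T).reshape(b, X, Y, Z, c, 3, 3, 3)
        dxp = np.zeros((b, c, X + 2, Y + 2, Z + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    dxp[:, :, i : i + X, j : j + Y, k : k + Z] += dcols[
                        :, :, :, :, :, i, j, k
                    ].transpose(0, 4, 1, 2, 3)
        del self._cache
        return dxp[:, :, 1:-1, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm3d(Layer):
    """Per-channel normalization over (batch, x, y, z).

    Training uses batch statistics and updates exponential running
    estimates; evaluation uses the frozen running statistics, so a single
    sample can be embedded reproducibly.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"] + m * mean).astype(np.float32)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"] + m * var).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        out = self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)
        self._cache = (xhat.astype(np.float32), inv_std.astype(np.float32), training)
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"].reshape(shape)
        if not training:
            return grad * g * inv_std.reshape(shape)
        n = grad.size / grad.shape[1]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv_std.reshape(shape)
        del self._cache
        return dx.astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2. Ties share the gradient equally."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, X, Y, Z = x.shape
        xr = x.reshape(b, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        self._cache = (xr, out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        mask = xr == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None, :, None] / counts)
        b, c = xr.shape[:2]
        X, Y, Z = xr.shape[2] * 2, xr.shape[4] * 2, xr.shape[6] * 2
        del self._cache
        return g.reshape(b, c, X, Y, Z).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": glorot_normal(rng, (in_features, out_features), in_features, out_features),
            "b": np.zeros(out_features, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"].T


class L2Normalize(Layer):
    """Project each row onto the unit sphere."""

    def __init__(self, eps: float = 1e-12):
        super().__init__()
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        norm = np.maximum(norm, self.eps)
        y = x / norm
        self._cache = (y, norm)
        return y.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y, norm = self._cache
        return ((grad - y * (y * grad).sum(axis=1, keepdims=True)) / norm).astype(np.float32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v
            for k, v in layer.buffers.items():
                state[f"layer{i}.buf.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = np.array(state[f"layer{i}.{k}"], dtype=np.float32)
            for k in layer.buffers:
                layer.buffers[k] = np.array(state[f"layer{i}.buf.{k}"], dtype=np.float32)

    def parameters(self):
        for layer in self.layers:
            for k in layer.params:
                yield layer, k


class Adam:
    """Adam with the customary defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, net: Sequential, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for i, layer in enumerate(net.layers):
            for k, p in layer.params.items():
                self.m[(i, k)] = np.zeros_like(p)
                self.v[(i, k)] = np.zeros_like(p)

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.net.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                g = g.astype(np.float32)
                self.m[(i, k)] = b1 * self.m[(i, k)] + (1 - b1) * g
                self.v[(i, k)] = b2 * self.v[(i, k)] + (1 - b2) * g * g
                mhat = self.m[(i, k)] / (1 - b1**self.t)
                vhat = self.v[(i, k)] / (1 - b2**self.t)
                layer.params[k] = p - lr * mhat / (np.sqrt(vhat) + self.eps)
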