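"""A compact NumPy CNN engine for one-dimensional one-hot sequence input.

Implements exactly the layer set the classifier needs — valid (unpadded)
1-D convolution, batch normalisation, ReLU, non-overlapping max pooling,
inverted dropout, dense layers — together with reverse-mode gradients and a
plain stochastic-gradient-descent update with optional momentum.  Convolutions
are evaluated as an im2col reshape followed by one BLAS matrix product, which
is where essentially all the training time goes.

All layers follow the same contract: ``forward(x, train)`` caches whatever
``backward(dout)`` needs; parameters live in ``layer.params`` and their
gradients, filled by ``backward``, in ``layer.grads`` under the same keys.
Tensors are ``(batch, length, channels)`` between convolutional layers and
``(batch, features)`` after flattening.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid cross-correlation along the length axis, stride 1."""

    def __init__(
        self,
        kernel: int,
        in_channels: int,
        filters: int,
        rng: np.random.Generator,
        dtype,
        input_layer: bool = False,
    ):
        super().__init__()
        self.kernel = kernel
        self.in_channels = in_channels
        # the gradient w.r.t. the network input is never consumed
        self.input_layer = input_layer
        # He initialisation: fan-in = kernel * in_channels
        std = np.sqrt(2.0 / (kernel * in_channels))
        self.params["W"] = rng.normal(0.0, std, size=(kernel * in_channels, filters)).astype(dtype)
        self.params["b"] = np.zeros(filters, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, cin = x.shape
        k = self.kernel
        # (B, L', Cin, k) -> (B, L', k, Cin) so the flat layout matches W's (k*Cin) rows
        win = sliding_window_view(x, k, axis=1).transpose(0, 1, 3, 2)
        lp = length - k + 1
        col = np.ascontiguousarray(win).reshape(b * lp, k * cin)
        out = col @ self.params["W"] + self.params["b"]
        self._cache = (col, x.shape)
        return out.reshape(b, lp, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, x_shape = self._cache
        b, length, cin = x_shape
        k = self.kernel
        lp = length - k + 1
        dflat = dout.reshape(b * lp, -1)
        self.grads["W"] = col.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        if self.input_layer:
            self._cache = None
            return None
        dcol = (dflat @ self.params["W"].T).reshape(b, lp, k, cin)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for j in range(k):
            dx[:, j : j + lp, :] += dcol[:, :, j, :]
        self._cache = None
        return dx


class BatchNorm(Layer):
    """Per-channel normalisation over batch and length, with running inference stats."""

    def __init__(self, channels: int, dtype, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if train:
            self._cache = (xhat, inv_std.astype(x.dtype), axes)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        n = np.prod([dout.shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv_std
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the kernel is dropped."""

    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        p = self.kernel
        lp = length // p
        xr = x[:, : lp * p, :].reshape(b, lp, p, c)
        idx = xr.argmax(axis=2)
        out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        b, length, c = x_shape
        p = self.kernel
        lp = length // p
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dxr = dx[:, : lp * p, :].reshape(b, lp, p, c)
        np.put_along_axis(dxr, idx[:, :, None, :], dout[:, :, None, :], axis=2)
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator, dtype):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, std, size=(in_features, units)).astype(dtype)
        self.params["b"] = np.zeros(units, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class Sequential:
    """A forward/backward layer stack with a sigmoid + cross-entropy head.

    The final layer emits one logit per sample; probabilities come from a
    sigmoid and the training loss is binary cross-entropy, whose gradient with
    respect to the logit is simply ``p - y``.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    @staticmethod
    def sigmoid(z: np.ndarray) -> np.ndarray:
        out = np.empty_like(z, dtype=np.float64)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    @staticmethod
    def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
        p = np.clip(p, eps, 1.0 - eps)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    def train_batch_gradients(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """One forward/backward pass; fills every layer's grads. Returns (loss, probs)."""
        z = self.forward_logits(x, train=True)
        p = self.sigmoid(z)
        loss = self.bce_loss(p, y)
        dz = ((p - y) / len(y)).astype(z.dtype)
        dout = dz[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss, p

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.sigmoid(self.forward_logits(x, train=False))

    # -- parameter bookkeeping -------------------------------------------------
    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{i}.{name}", layer, name, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: value.copy() for key, _, _, value in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, value in self.parameters():
            layer.params[name] = state[key].astype(value.dtype).copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"{i}.running_mean"], dtype=np.float64).copy()
                layer.running_var = np.asarray(state[f"{i}.running_var"], dtype=np.float64).copy()


class SGD:
    """Plain stochastic gradient descent with optional classical momentum."""

    def __init__(self, net: Sequential, learning_rate: float, momentum: float = 0.0):
        self.net = net
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity: dict[str, np.ndarray] = {}

    def step(self) -> None:
        for key, layer, name, value in self.net.parameters():
            grad = layer.grads[name]
            if self.momentum > 0.0:
                v = self.velocity.get(key)
                if v is None:
                    v = np.zeros_like(value)
                v = self.momentum * v - self.lr * grad
                self.velocity[key] = v
                layer.params[name] = value + v
            else:
                layer.params[name] = value - self.lr * grad
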