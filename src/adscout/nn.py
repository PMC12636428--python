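"""Minimal numpy neural-network layers for the activity regressor.

Implements exactly what the residual convolutional regressor needs: 1-D
convolution over sequence positions, batch normalization, ReLU, identity-skip
residual blocks, global average pooling, a dense head, and an Adam optimizer.
All arithmetic is float64 and fully deterministic given the initialization
``numpy.random.Generator``. Backward passes are hand-written and verified
against numerical differentiation in the test suite.

Array convention: activations are ``(batch, positions, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm",
    "ReLU",
    "ResidualBlock",
    "GlobalAvgPool",
    "Dense",
    "Network",
    "Adam",
]


class Layer:
    """Base class: a differentiable module with (possibly empty) parameters."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        """List of {"value": array, "grad": array} dicts, updated in place."""
        return []


def _param(value: np.ndarray) -> dict:
    return {"value": value, "grad": np.zeros_like(value)}


class Conv1d(Layer):
    """Same-padded 1-D convolution along the position axis (odd kernel only)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = kernel * in_channels
        # He initialization: appropriate for the ReLU nonlinearities downstream
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.weight = _param(w)
        self.bias = _param(np.zeros(out_channels))
        self._cols: np.ndarray | None = None
        self._length = 0

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        p = self.kernel // 2
        xp = np.zeros((n, length + 2 * p, c))
        xp[:, p:p + length, :] = x
        cols = np.empty((n, length, self.kernel, c))
        for i in range(self.kernel):
            cols[:, :, i, :] = xp[:, i:i + length, :]
        return cols.reshape(n, length, self.kernel * c)

    def forward(self, x, train):
        self._length = x.shape[1]
        self._cols = self._im2col(x)
        return self._cols @ self.weight["value"] + self.bias["value"]

    def backward(self, grad):
        n, length, out = grad.shape
        cols2d = self._cols.reshape(-1, self.kernel * self.in_channels)
        grad2d = grad.reshape(-1, out)
        self.weight["grad"] += cols2d.T @ grad2d
        self.bias["grad"] += grad2d.sum(axis=0)
        dcols = (grad2d @ self.weight["value"].T).reshape(
            n, length, self.kernel, self.in_channels)
        p = self.kernel // 2
        dxp = np.zeros((n, length + 2 * p, self.in_channels))
        for i in range(self.kernel):
            dxp[:, i:i + length, :] += dcols[:, :, i, :]
        return dxp[:, p:p + length, :]

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, position)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._xhat: np.ndarray | None = None
        self._std: np.ndarray | None = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma["value"] * self._xhat + self.beta["value"]

    def backward(self, grad):
        xhat = self._xhat
        self.gamma["grad"] += (grad * xhat).sum(axis=(0, 1))
        self.beta["grad"] += grad.sum(axis=(0, 1))
        g = grad * self.gamma["value"]
        if not self._train:
            return g / self._std
        # batch statistics participate in the forward pass, so their
        # dependence on x must be differentiated through
        m = grad.shape[0] * grad.shape[1]
        return (g - g.mean(axis=(0, 1)) - xhat * (g * xhat).sum(axis=(0, 1)) / m) / self._std

    def parameters(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN with identity skip, ReLU after the sum."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1d(channels, channels, kernel, rng)
        self.bn1 = BatchNorm(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(channels, channels, kernel, rng)
        self.bn2 = BatchNorm(channels)
        self.relu_out = ReLU()

    def forward(self, x, train):
        h = self.bn1.forward(self.conv1.forward(x, train), train)
        h = self.relu1.forward(h, train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        return self.relu_out.forward(x + h, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g = self.bn2.backward(grad)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return grad + g

    def parameters(self):
        return (self.conv1.parameters() + self.bn1.parameters()
                + self.conv2.parameters() + self.bn2.parameters())


class GlobalAvgPool(Layer):
    """Mean over the position axis: (N, L, C) -> (N, C)."""

    def forward(self, x, train):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._length, axis=1) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features))
        self.weight = _param(w)
        self.bias = _param(np.zeros(out_features))

    def forward(self, x, train):
        self._x = x
        return x @ self.weight["value"] + self.bias["value"]

    def backward(self, grad):
        self.weight["grad"] += self._x.T @ grad
        self.bias["grad"] += grad.sum(axis=0)
        return grad @ self.weight["value"].T

    def parameters(self):
        return [self.weight, self.bias]


class Network(Layer):
    """Plain sequential container with weight (de)serialization."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p["grad"][...] = 0.0

    # -- persistence ------------------------------------------------------
    def _stateful(self):
        out = []

        def walk(layer):
            if isinstance(layer, Network):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, ResidualBlock):
                for sub in (layer.conv1, layer.bn1, layer.conv2, layer.bn2):
                    walk(sub)
            else:
                out.append(layer)

        walk(self)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._stateful()):
            for j, p in enumerate(layer.parameters()):
                state[f"layer{i}_param{j}"] = p["value"].copy()
            if isinstance(layer, BatchNorm):
                state[f"layer{i}_running_mean"] = layer.running_mean.copy()
                state[f"layer{i}_running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._stateful()):
            for j, p in enumerate(layer.parameters()):
                p["value"][...] = state[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}_running_mean"]
                layer.running_var[...] = state[f"layer{i}_running_var"]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[dict], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
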