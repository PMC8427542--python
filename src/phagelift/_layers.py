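"""Internal trainable layer stack: forward/backward passes and Adam.

Everything is float32 and batch-first. The final dense layer outputs the
pre-sigmoid logit; the trainer fuses sigmoid with binary cross-entropy so the
output-layer gradient is simply (score - label) / batch, which is numerically
stable for saturated scores.
"""

from __future__ import annotations

import numpy as np

from .network import (
    BatchNormParams,
    LayerWeights,
    NetworkConfig,
    _conv_cols,
    _pooled_length,
)

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class AdamOptimizer:
    def __init__(self, params: list[Param], learning_rate: float = 1e-4):
        self.params = params
        self.lr = learning_rate
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - _ADAM_BETA1**self.t
        bc2 = 1.0 - _ADAM_BETA2**self.t
        for p in self.params:
            p.m *= _ADAM_BETA1
            p.m += (1.0 - _ADAM_BETA1) * p.grad
            p.v *= _ADAM_BETA2
            p.v += (1.0 - _ADAM_BETA2) * np.square(p.grad)
            p.value -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + _ADAM_EPS)


class _Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, d: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvReluLayer(_Layer):
    """Conv1D (zero right-padding, output length L) fused with ReLU."""

    def __init__(self, F: int, M: int, rng: np.random.Generator):
        super().__init__()
        self.F, self.M = F, M
        limit = np.sqrt(6.0 / (M * 4 + F))
        self.W = Param(rng.uniform(-limit, limit, size=(M * 4, F)))
        self.b = Param(np.zeros(F))
        self.params = [self.W, self.b]

    def forward(self, x, train, rng):
        B, L, _ = x.shape
        self._cols = _conv_cols(x, self.M).reshape(B * L, self.M * 4)
        z = self._cols @ self.W.value
        z += self.b.value
        self._mask = z > 0
        z *= self._mask
        return z.reshape(B, L, self.F)

    def backward(self, d):
        B, L, F = d.shape
        dz = d.reshape(B * L, F) * self._mask
        self.W.grad = self._cols.T @ dz
        self.b.grad = dz.sum(axis=0)
        return None  # input layer: no upstream gradient needed


class MaxPoolLayer(_Layer):
    def __init__(self, S1: int, S2: int):
        super().__init__()
        self.S1, self.S2 = S1, S2

    def forward(self, x, train, rng):
        B, L, F = x.shape
        self._in_shape = x.shape
        n = _pooled_length(L, self.S1, self.S2)
        self._n = n
        if self.S1 <= self.S2:
            # non-overlapping windows: contiguous reshape is much faster
            win = np.ascontiguousarray(x[:, : n * self.S2]).reshape(B, n, self.S2, F)[:, :, : self.S1]
        else:
            win = np.lib.stride_tricks.sliding_window_view(x, self.S1, axis=1)[:, :: self.S2][:, :n]
            win = np.moveaxis(win, -1, 2)  # (B, n, S1, F)
        self._win = win
        self._out = win.max(axis=2)
        return self._out

    def backward(self, d):
        # route the gradient to the first position attaining the window max
        B, n, F = d.shape
        dx = np.zeros(self._in_shape, dtype=d.dtype)
        win, out = self._win, self._out
        remaining = np.ones(out.shape, dtype=bool)
        if self.S1 <= self.S2:
            dwin = np.zeros((B, n, self.S2, F), dtype=d.dtype)
            for j in range(self.S1):
                hit = (win[:, :, j] == out) & remaining
                dwin[:, :, j] = d * hit
                remaining &= ~hit
            dx[:, : n * self.S2] = dwin.reshape(B, n * self.S2, F)
        else:
            for j in range(self.S1):
                hit = (win[:, :, j] == out) & remaining
                contrib = d * hit
                for l in range(n):
                    dx[:, l * self.S2 + j, :] += contrib[:, l, :]
                remaining &= ~hit
        return dx


class BatchNormLayer(_Layer):
    """Normalises over all axes but the last (channels/units)."""

    def __init__(self, n_channels: int, epsilon: float, momentum: float):
        super().__init__()
        self.eps, self.momentum = epsilon, momentum
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.params = [self.gamma, self.beta]

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1.0 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1.0 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._n = int(np.prod([x.shape[a] for a in axes])) if train else 0
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, d):
        axes = tuple(range(d.ndim - 1))
        self.gamma.grad = (d * self._xhat).sum(axis=axes)
        self.beta.grad = d.sum(axis=axes)
        if not self._train:
            return d * self.gamma.value * self._inv_std
        n = self._n
        dxhat = d * self.gamma.value
        return (self._inv_std / n) * (
            n * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class DropoutLayer(_Layer):
    def __init__(self, P: float):
        super().__init__()
        if not 0.0 <= P < 1.0:
            raise ValueError("P must be in [0, 1)")
        self.P = P

    def forward(self, x, train, rng):
        if not train or self.P == 0.0:
            self._scale = None
            return x
        keep = (rng.random(x.shape, dtype=np.float32) >= self.P).astype(x.dtype)
        self._scale = keep / np.float32(1.0 - self.P)
        return x * self._scale

    def backward(self, d):
        if self._scale is None:
            return d
        return d * self._scale


class GlobalAvgPoolLayer(_Layer):
    def forward(self, x, train, rng):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, d):
        return np.repeat(d[:, None, :], self._L, axis=1) / self._L


class FlattenLayer(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class DenseLayer(_Layer):
    """activation in {'relu', 'linear'}; the sigmoid of the output layer is
    fused into the loss by the trainer."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self.activation = activation
        self.params = [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, d):
        if self.activation == "relu":
            d = d * self._mask
        self.W.grad = self._x.T @ d
        self.b.grad = d.sum(axis=0)
        return d @ self.W.value.T


class NetStack:
    """The configured layer stack, buildable for every ablation variant."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        layers: list[_Layer] = []
        self._names: list[str] = []
        for name in config.layers:
            if name == "conv1d":
                layer = ConvReluLayer(config.F, config.M, rng)
            elif name == "maxpool":
                layer = MaxPoolLayer(config.S1, config.S2)
            elif name == "bn1":
                layer = BatchNormLayer(config.F, config.bn_epsilon, config.bn_momentum)
            elif name == "dropout":
                layer = DropoutLayer(config.P)
            elif name == "globalpool":
                layer = GlobalAvgPoolLayer()
            elif name == "flatten":
                layer = FlattenLayer()
            elif name == "dense1":
                layer = DenseLayer(config.dense1_input_dim, config.R, "relu", rng)
            elif name == "bn2":
                layer = BatchNormLayer(config.R, config.bn_epsilon, config.bn_momentum)
            elif name == "dense2":
                layer = DenseLayer(config.R, 1, "linear", rng)
            else:  # pragma: no cover
                raise AssertionError(name)
            layers.append(layer)
            self._names.append(name)
        self.layers = layers

    def forward_logits(self, X: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        h = np.asarray(X, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h, train, rng)
        return h[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        d = dlogit[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)
            if d is None:
                break

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def export_weights(self) -> LayerWeights:
        by_name = dict(zip(self._names, self.layers))
        conv = by_name.get("conv1d")
        conv_W = conv_b = None
        if conv is not None:
            conv_W = conv.W.value.T.reshape(self.config.F, self.config.M, 4).astype(np.float64)
            conv_b = conv.b.value.astype(np.float64)

        def bn_params(name: str) -> BatchNormParams | None:
            layer = by_name.get(name)
            if layer is None:
                return None
            return BatchNormParams(
                layer.gamma.value.astype(np.float64),
                layer.beta.value.astype(np.float64),
                layer.running_mean.astype(np.float64),
                layer.running_var.astype(np.float64),
            )

        d1, d2 = by_name["dense1"], by_name["dense2"]
        return LayerWeights(
            conv_W=conv_W,
            conv_b=conv_b,
            bn1=bn_params("bn1"),
            dense1_W=d1.W.value.T.astype(np.float64),
            dense1_b=d1.b.value.astype(np.float64),
            bn2=bn_params("bn2"),
            dense2_W=d2.W.value[:, 0].astype(np.float64),
            dense2_b=float(d2.b.value[0]),
        )

    def load_weights(self, weights: LayerWeights) -> None:
        by_name = dict(zip(self._names, self.layers))
        if "conv1d" in by_name and weights.conv_W is not None:
            conv = by_name["conv1d"]
            conv.W.value = np.ascontiguousarray(
                weights.conv_W.reshape(self.config.F, -1).T, dtype=np.float32
            )
            conv.b.value = np.ascontiguousarray(weights.conv_b, dtype=np.float32)
        for name, bn in (("bn1", weights.bn1), ("bn2", weights.bn2)):
            if name in by_name and bn is not None:
                layer = by_name[name]
                layer.gamma.value = np.ascontiguousarray(bn.gamma, dtype=np.float32)
                layer.beta.value = np.ascontiguousarray(bn.beta, dtype=np.float32)
                layer.running_mean = np.ascontiguousarray(bn.running_mean, dtype=np.float32)
                layer.running_var = np.ascontiguousarray(bn.running_var, dtype=np.float32)
        d1, d2 = by_name["dense1"], by_name["dense2"]
        d1.W.value = np.ascontiguousarray(weights.dense1_W.T, dtype=np.float32)
        d1.b.value = np.ascontiguousarray(weights.dense1_b, dtype=np.float32)
        d2.W.value = np.ascontiguousarray(weights.dense2_W[:, None], dtype=np.float32)
        d2.b.value = np.asarray([weights.dense2_b], dtype=np.float32)

    def snapshot(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNormLayer):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def restore(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, value in zip(params, state):
            p.value = value.copy()
        i = len(params)
        for layer in self.layers:
            if isinstance(layer, BatchNormLayer):
                layer.running_mean = state[i].copy()
                layer.running_var = state[i + 1].copy()
                i += 2
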