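"""The eight-layer 1D CNN that scores a DNA fragment.

Layer order: Conv1D -> Maxpooling -> BN1 -> Dropout -> Globalpooling ->
Dense1 -> BN2 -> Dense2 (sigmoid). The convolutional kernels act as position
weight matrices over the one-hot input; global average pooling makes the
representation length-invariant; the final sigmoid score in (0, 1) is the
probability that the fragment derives from a virulent phage.

Conventions that the layer equations leave open, fixed here:

* Conv1D uses zero right-padding so the output length equals the input
  length L (the equation indexes X[l+m] for l up to L-1).
* Maxpooling drops an incomplete trailing window; pooled length is
  floor(L / S2) for the default S1 == S2.
* Dropout uses the inverted convention (kept activations scaled by 1/(1-P)
  at train time); at inference it is the identity.
* Batch normalisation at inference uses running statistics (momentum 0.99,
  epsilon 1e-3 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

WEIGHT_FORMAT_VERSION = 1

VARIANTS = ("full", "kmer4", "no_maxpool", "no_dropout", "no_globalpool", "no_bn")

#: layer stacks per ablation variant, in forward order
_VARIANT_LAYERS: dict[str, tuple[str, ...]] = {
    "full": ("conv1d", "maxpool", "bn1", "dropout", "globalpool", "dense1", "bn2", "dense2"),
    "kmer4": ("dense1", "bn2", "dense2"),
    "no_maxpool": ("conv1d", "bn1", "dropout", "globalpool", "dense1", "bn2", "dense2"),
    "no_dropout": ("conv1d", "maxpool", "bn1", "globalpool", "dense1", "bn2", "dense2"),
    "no_globalpool": ("conv1d", "maxpool", "bn1", "dropout", "flatten", "dense1", "bn2", "dense2"),
    "no_bn": ("conv1d", "maxpool", "dropout", "globalpool", "dense1", "dense2"),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults follow the published setting: F=64 kernels of width M=6,
    pooling size S1=3 with stride S2=3, dropout proportion P=0.3, and
    R=64 dense units; L is the per-group input length in bp.
    """

    L: int
    F: int = 64
    M: int = 6
    S1: int = 3
    S2: int = 3
    P: float = 0.3
    R: int = 64
    bn_epsilon: float = 1e-3
    bn_momentum: float = 0.99
    variant: str = "full"

    def __post_init__(self) -> None:
        for name in ("F", "M", "S1", "S2", "R"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.P < 1.0:
            raise ValueError(f"dropout proportion P must be in [0, 1), got {self.P}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.variant != "kmer4" and self.L < self.M:
            raise ValueError(f"input length L={self.L} shorter than kernel width M={self.M}")

    @property
    def layers(self) -> tuple[str, ...]:
        return build_variant(self)

    @property
    def pooled_length(self) -> int:
        L = self.L
        if "maxpool" in self.layers:
            return _pooled_length(L, self.S1, self.S2)
        return L

    @property
    def dense1_input_dim(self) -> int:
        if self.variant == "kmer4":
            return 256
        if self.variant == "no_globalpool":
            return self.pooled_length * self.F
        return self.F


def build_variant(config: NetworkConfig) -> tuple[str, ...]:
    """The ordered layer names for the configured (ablation) variant."""
    return _VARIANT_LAYERS[config.variant]


@dataclass
class BatchNormParams:
    gamma: np.ndarray  # scale
    beta: np.ndarray  # shift
    running_mean: np.ndarray
    running_var: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.running_var < 0):
            raise ValueError("running variance must be non-negative")


@dataclass
class LayerWeights:
    """All trainable tensors plus BN running statistics.

    Layers absent from a variant hold ``None``. ``dense1_W`` is
    (R, dense1_input_dim); ``conv_W`` is (F, M, 4).
    """

    conv_W: np.ndarray | None
    conv_b: np.ndarray | None
    bn1: BatchNormParams | None
    dense1_W: np.ndarray
    dense1_b: np.ndarray
    bn2: BatchNormParams | None
    dense2_W: np.ndarray
    dense2_b: float


def relu(x):
    """max(x, 0), elementwise."""
    return np.maximum(x, 0)


def sigmoid(x):
    """1 / (1 + exp(-x)), numerically stable for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _conv_cols(X: np.ndarray, M: int) -> np.ndarray:
    """im2col with zero right-padding: (..., L, 4) -> (..., L, M*4)."""
    *lead, L, A = X.shape
    pad = np.zeros((*lead, L + M - 1, A), dtype=X.dtype)
    pad[..., :L, :] = X
    windows = np.lib.stride_tricks.sliding_window_view(pad, (M, A), axis=(-2, -1))
    return windows.reshape(*lead, L, M * A)


def conv1d_forward(X: np.ndarray, conv_W: np.ndarray, conv_b: np.ndarray) -> np.ndarray:
    """ReLU(Conv1D) over a one-hot matrix.

    Y[l, f] = ReLU( sum_{m,n} W[f, m, n] * X[l+m, n] + b[f] ), with X taken
    as zero beyond its end, so the output length equals the input length.
    """
    X = np.asarray(X)
    conv_W = np.asarray(conv_W)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError(f"X must be L×4, got {X.shape}")
    F, M, A = conv_W.shape
    if A != 4 or conv_b.shape != (F,):
        raise ValueError("kernel tensor must be F×M×4 with an F-vector bias")
    cols = _conv_cols(X, M)
    return relu(cols @ conv_W.reshape(F, M * A).T + conv_b)


def _pooled_length(L: int, S1: int, S2: int) -> int:
    if L < S1:
        raise ValueError(f"input length {L} shorter than pooling size {S1}")
    n_full = (L - S1) // S2 + 1
    return min(L // S2, n_full)


def maxpool1d(Y: np.ndarray, S1: int, S2: int) -> np.ndarray:
    """Per-channel max over windows of size S1 at stride S2; trailing
    windows that would overrun the end are dropped."""
    if S1 < 1 or S2 < 1:
        raise ValueError("S1 and S2 must be >= 1")
    Y = np.asarray(Y)
    L = Y.shape[0]
    n = _pooled_length(L, S1, S2)
    windows = np.lib.stride_tricks.sliding_window_view(Y, S1, axis=0)[:: S2][:n]
    return windows.max(axis=-1)


def batchnorm_inference(x: np.ndarray, bn: BatchNormParams, epsilon: float) -> np.ndarray:
    """gamma * (x - running_mean) / sqrt(running_var + epsilon) + beta,
    per channel (last axis)."""
    inv = 1.0 / np.sqrt(bn.running_var + epsilon)
    return bn.gamma * (np.asarray(x) - bn.running_mean) * inv + bn.beta


def dropout_train(x: np.ndarray, P: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Inverted dropout: zero a Bernoulli(P) mask of entries, scale the rest
    by 1/(1-P). Returns (output, keep mask). Inference mode is the identity
    and does not go through this function."""
    if not 0.0 <= P < 1.0:
        raise ValueError(f"P must be in [0, 1), got {P}")
    x = np.asarray(x)
    if P == 0.0:
        return x.copy(), np.ones_like(x)
    keep = (rng.random(x.shape) >= P).astype(x.dtype)
    return x * keep / (1.0 - P), keep


def global_avg_pool(Y: np.ndarray) -> np.ndarray:
    """Channel-wise mean over positions: (L', F) -> (F,)."""
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError(f"expected a non-empty L'×F matrix, got shape {Y.shape}")
    return Y.mean(axis=0)


def dense_forward(x: np.ndarray, W: np.ndarray, b, activation: str = "linear"):
    """activation(W @ x + b); activation in {'linear', 'relu', 'sigmoid'}."""
    z = np.asarray(W) @ np.asarray(x) + b
    if activation == "linear":
        return z
    if activation == "relu":
        return relu(z)
    if activation == "sigmoid":
        return sigmoid(z)
    raise ValueError(f"unknown activation {activation!r}")


def forward(
    config: NetworkConfig,
    weights: LayerWeights,
    X: np.ndarray,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
    return_trace: bool = False,
):
    """Score one encoded sequence (L×4 one-hot, or a 256-vector for the
    kmer4 variant).

    ``mode='infer'`` is deterministic (dropout identity, BN running stats);
    ``mode='train'`` applies the dropout mask drawn from ``rng``. Training
    proper (batch statistics, gradients) lives in the training module; this
    composed pass is the per-sequence reference used for prediction.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    if mode == "train" and rng is None:
        raise ValueError("train mode requires an rng for the dropout mask")
    X = np.asarray(X, dtype=np.float64)
    if config.variant == "kmer4":
        if X.shape != (256,):
            raise ValueError(f"kmer4 variant expects a 256-vector, got {X.shape}")
    elif X.shape != (config.L, 4):
        raise ValueError(f"expected a {config.L}×4 one-hot matrix, got {X.shape}")

    trace: dict[str, np.ndarray] = {}
    h = X
    for layer in config.layers:
        if layer == "conv1d":
            h = conv1d_forward(h, weights.conv_W, weights.conv_b)
        elif layer == "maxpool":
            h = maxpool1d(h, config.S1, config.S2)
        elif layer == "bn1":
            h = batchnorm_inference(h, weights.bn1, config.bn_epsilon)
        elif layer == "dropout":
            if mode == "train":
                h, mask = dropout_train(h, config.P, rng)
                trace["dropout_mask"] = mask
            # inference: identity
        elif layer == "globalpool":
            h = global_avg_pool(h)
        elif layer == "flatten":
            h = h.reshape(-1)
        elif layer == "dense1":
            h = dense_forward(h, weights.dense1_W, weights.dense1_b, "relu")
        elif layer == "bn2":
            h = batchnorm_inference(h, weights.bn2, config.bn_epsilon)
        elif layer == "dense2":
            h = dense_forward(h, weights.dense2_W, weights.dense2_b, "sigmoid")
        else:  # pragma: no cover
            raise AssertionError(f"unknown layer {layer}")
        trace[layer] = h
    score = float(h)
    if return_trace:
        return score, trace
    return score


def forward_batch(config: NetworkConfig, weights: LayerWeights, X: np.ndarray) -> np.ndarray:
    """Vectorised inference over a batch: (B, L, 4) -> (B,) scores.

    Agrees with per-sequence :func:`forward` in infer mode; batch composition
    cannot change a sequence's score (BN uses running statistics).
    """
    X = np.asarray(X, dtype=np.float32)
    if config.variant == "kmer4":
        h = X.reshape(X.shape[0], 256)
    else:
        F, M = config.F, config.M
        cols = _conv_cols(X, M)  # (B, L, M*4)
        h = relu(cols @ weights.conv_W.reshape(F, M * 4).T.astype(np.float32)
                 + weights.conv_b.astype(np.float32))
    for layer in config.layers:
        if layer in ("conv1d", "dropout"):
            continue
        if layer == "maxpool":
            n = _pooled_length(h.shape[1], config.S1, config.S2)
            win = np.lib.stride_tricks.sliding_window_view(h, config.S1, axis=1)[:, :: config.S2][:, :n]
            h = win.max(axis=-1)
        elif layer == "bn1":
            h = batchnorm_inference(h, weights.bn1, config.bn_epsilon)
        elif layer == "globalpool":
            h = h.mean(axis=1)
        elif layer == "flatten":
            h = h.reshape(h.shape[0], -1)
        elif layer == "dense1":
            h = relu(h @ weights.dense1_W.T + weights.dense1_b)
        elif layer == "bn2":
            h = batchnorm_inference(h, weights.bn2, config.bn_epsilon)
        elif layer == "dense2":
            h = sigmoid(h @ weights.dense2_W + weights.dense2_b)
    return np.asarray(h, dtype=np.float64)


def initialize_weights(config: NetworkConfig, rng: np.random.Generator) -> LayerWeights:
    """Glorot-uniform initial weights; BN starts as the identity transform."""

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    layers = config.layers
    conv_W = conv_b = bn1 = bn2 = None
    if "conv1d" in layers:
        conv_W = glorot((config.F, config.M, 4), config.M * 4, config.F)
        conv_b = np.zeros(config.F)
    if "bn1" in layers:
        bn1 = _identity_bn(config.F)
    d_in = config.dense1_input_dim
    dense1_W = glorot((config.R, d_in), d_in, config.R)
    dense1_b = np.zeros(config.R)
    if "bn2" in layers:
        bn2 = _identity_bn(config.R)
    dense2_W = glorot((config.R,), config.R, 1)
    dense2_b = 0.0
    return LayerWeights(conv_W, conv_b, bn1, dense1_W, dense1_b, bn2, dense2_W, float(dense2_b))


def _identity_bn(n: int) -> BatchNormParams:
    return BatchNormParams(np.ones(n), np.zeros(n), np.zeros(n), np.ones(n))


def save_weights(weights: LayerWeights, config: NetworkConfig, path: str | Path) -> None:
    """Persist all tensors plus the config in a versioned npz archive."""
    arrays: dict[str, np.ndarray] = {
        "dense1_W": weights.dense1_W,
        "dense1_b": weights.dense1_b,
        "dense2_W": weights.dense2_W,
        "dense2_b": np.asarray(weights.dense2_b),
    }
    if weights.conv_W is not None:
        arrays["conv_W"] = weights.conv_W
        arrays["conv_b"] = weights.conv_b
    for name, bn in (("bn1", weights.bn1), ("bn2", weights.bn2)):
        if bn is not None:
            arrays[f"{name}_gamma"] = bn.gamma
            arrays[f"{name}_beta"] = bn.beta
            arrays[f"{name}_mean"] = bn.running_mean
            arrays[f"{name}_var"] = bn.running_var
    meta = {"format_version": WEIGHT_FORMAT_VERSION, "config": _config_to_dict(config)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_weights(path: str | Path) -> tuple[LayerWeights, NetworkConfig]:
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:
        raise ValueError(f"cannot read weight archive {path}: {exc}") from exc
    if "meta_json" not in arrays:
        raise ValueError(f"weight archive {path} lacks metadata; not a valid archive")
    meta = json.loads(arrays["meta_json"].tobytes().decode())
    version = meta.get("format_version")
    if version != WEIGHT_FORMAT_VERSION:
        raise ValueError(
            f"weight archive {path} has format version {version}; "
            f"this build reads version {WEIGHT_FORMAT_VERSION}"
        )
    config = NetworkConfig(**meta["config"])

    def bn_of(name: str) -> BatchNormParams | None:
        if f"{name}_gamma" not in arrays:
            return None
        return BatchNormParams(
            arrays[f"{name}_gamma"], arrays[f"{name}_beta"],
            arrays[f"{name}_mean"], arrays[f"{name}_var"],
        )

    weights = LayerWeights(
        conv_W=arrays.get("conv_W"),
        conv_b=arrays.get("conv_b"),
        bn1=bn_of("bn1"),
        dense1_W=arrays["dense1_W"],
        dense1_b=arrays["dense1_b"],
        bn2=bn_of("bn2"),
        dense2_W=arrays["dense2_W"],
        dense2_b=float(arrays["dense2_b"]),
    )
    return weights, config


def _config_to_dict(config: NetworkConfig) -> dict:
    return {
        "L": config.L, "F": config.F, "M": config.M, "S1": config.S1,
        "S2": config.S2, "P": config.P, "R": config.R,
        "bn_epsilon": config.bn_epsilon, "bn_momentum": config.bn_momentum,
        "variant": config.variant,
    }
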