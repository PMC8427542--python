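"""Scikit-learn style estimators.

:class:`CNNFragmentClassifier` trains one CNN for a single length group on
DNA fragment strings; :class:`PhageLifestyleClassifier` is the length-routed
ensemble that handles arbitrary-length sequences (one model per stratum,
splitting of long sequences, length-weighted score combination, and the
uncertainty cut-off). Both follow the fit/predict contract, expose
``get_params``/``set_params`` and fitted attributes with a trailing
underscore, and compose with sklearn model selection.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import network
from ._layers import AdamOptimizer, NetStack
from .encoding import kmer_frequencies, one_hot_encode
from .network import LayerWeights, NetworkConfig
from .seqio import NucleotideSequence

POSITIVE_CLASS = "virulent"
NEGATIVE_CLASS = "temperate"


@dataclass
class TrainingLog:
    """Per-epoch history of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    wall_time: float = 0.0
    seed: int | None = None


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with scores clipped into [eps, 1-eps]."""
    s = np.clip(np.asarray(scores, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=np.float64)
    return float(np.mean(-(y * np.log(s) + (1.0 - y) * np.log1p(-s))))


def _as_bases(x) -> str:
    return x.bases if isinstance(x, NucleotideSequence) else str(x)


class CNNFragmentClassifier(ClassifierMixin, BaseEstimator):
    """Single length-group CNN classifier over DNA fragment strings.

    Parameters mirror the architecture (``n_kernels``=F, ``kernel_width``=M,
    ``pool_size``=S1, ``pool_stride``=S2, ``dropout``=P, ``dense_units``=R)
    and the training protocol (Adam with ``learning_rate`` 1e-4, binary
    cross-entropy, ``batch_size`` 32). ``input_length`` is the group's model
    input length L; shorter fragments are zero-padded on the 3' side.

    ``fit(X, y, groups=...)`` accepts fragment strings (or
    :class:`NucleotideSequence`) and labels in {'virulent', 'temperate'} or
    {1, 0}; ``groups`` carries genome-of-origin ids so the early-stopping
    validation split is genome-disjoint from the updated portion.
    """

    def __init__(
        self,
        input_length: int = 1800,
        n_kernels: int = 64,
        kernel_width: int = 6,
        pool_size: int = 3,
        pool_stride: int = 3,
        dropout: float = 0.3,
        dense_units: int = 64,
        variant: str = "full",
        bn_epsilon: float = 1e-3,
        bn_momentum: float = 0.99,
        learning_rate: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int | None = 0,
    ):
        self.input_length = input_length
        self.n_kernels = n_kernels
        self.kernel_width = kernel_width
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.dropout = dropout
        self.dense_units = dense_units
        self.variant = variant
        self.bn_epsilon = bn_epsilon
        self.bn_momentum = bn_momentum
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- encoding -----------------------------------------------------------

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            L=self.input_length, F=self.n_kernels, M=self.kernel_width,
            S1=self.pool_size, S2=self.pool_stride, P=self.dropout,
            R=self.dense_units, bn_epsilon=self.bn_epsilon,
            bn_momentum=self.bn_momentum, variant=self.variant,
        )

    def _encode(self, X) -> np.ndarray:
        if self.variant == "kmer4":
            return np.stack(
                [kmer_frequencies(_as_bases(x), 4) for x in X]
            ).astype(np.float32)
        out = np.zeros((len(X), self.input_length, 4), dtype=np.float32)
        for i, x in enumerate(X):
            bases = _as_bases(x)
            if len(bases) > self.input_length:
                raise ValueError(
                    f"fragment {i} is {len(bases)} bp > input_length {self.input_length}"
                )
            out[i] = one_hot_encode(bases, self.input_length)
        return out

    def _binarize(self, y) -> np.ndarray:
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("fit requires both classes present")
        if set(classes) <= {NEGATIVE_CLASS, POSITIVE_CLASS}:
            self.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS], dtype=object)
            return (y == POSITIVE_CLASS).astype(np.float32)
        if set(np.asarray(classes).tolist()) <= {0, 1}:
            self.classes_ = np.array([0, 1])
            return y.astype(np.float32)
        raise ValueError(
            f"labels must be {{'virulent','temperate'}} or {{0,1}}, got {classes}"
        )

    # -- training -----------------------------------------------------------

    def _validation_split(self, y01, groups, rng):
        """Genome-disjoint, per-class split of indices into (train, val)."""
        n = len(y01)
        if groups is None:
            groups = np.arange(n)
        groups = np.asarray(groups)
        val_idx: list[int] = []
        for cls in (0.0, 1.0):
            cls_groups = np.unique(groups[y01 == cls])
            n_val = max(1, int(round(self.validation_fraction * len(cls_groups))))
            if n_val >= len(cls_groups):
                raise ValueError(
                    "not enough genomes per class for a genome-disjoint validation split"
                )
            chosen = rng.choice(cls_groups, size=n_val, replace=False)
            val_idx.extend(np.flatnonzero(np.isin(groups, chosen) & (y01 == cls)))
        val = np.sort(np.asarray(val_idx, dtype=int))
        train = np.setdiff1d(np.arange(n), val)
        if not len(val) or not len(train):
            raise ValueError("validation split produced an empty partition")
        return train, val

    def fit(self, X, y, groups=None):
        t0 = time.monotonic()
        if len(X) == 0:
            raise ValueError("cannot fit on an empty corpus")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")
        y01 = self._binarize(y)
        config = self._network_config()
        rng = np.random.default_rng(self.random_state)
        Xenc = self._encode(X)
        tr, va = self._validation_split(y01, groups, rng)
        Xtr, ytr = Xenc[tr], y01[tr]
        Xva, yva = Xenc[va], y01[va]

        stack = NetStack(config, rng)
        optimizer = AdamOptimizer(stack.parameters(), self.learning_rate)
        log = TrainingLog(seed=self.random_state)
        best_val = np.inf
        best_state = stack.snapshot()
        since_best = 0
        n_tr = len(tr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            losses = []
            for lo in range(0, n_tr, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                logits = stack.forward_logits(Xtr[idx], train=True, rng=rng)
                scores = network.sigmoid(logits)
                losses.append(bce_loss(scores, ytr[idx]) * len(idx))
                stack.backward((scores - ytr[idx]) / len(idx))
                optimizer.step()
            val_scores = network.sigmoid(stack.forward_logits(Xva, train=False, rng=None))
            val_loss = bce_loss(val_scores, yva)
            log.train_loss.append(float(np.sum(losses) / n_tr))
            log.val_loss.append(val_loss)
            log.val_acc.append(float(np.mean((val_scores > 0.5) == (yva > 0.5))))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = stack.snapshot()
                log.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        stack.restore(best_state)
        self.config_ = config
        self.weights_ = stack.export_weights()
        self.history_ = log
        self.history_.wall_time = time.monotonic() - t0
        self.n_features_in_ = 1
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise NotFittedError("this CNNFragmentClassifier instance is not fitted yet")

    def decision_function(self, X) -> np.ndarray:
        """P(virulent) per fragment, in [0, 1]."""
        self._check_fitted()
        if len(X) == 0:
            return np.zeros(0)
        scores = []
        batch = 512
        Xenc = self._encode(X)
        for lo in range(0, len(Xenc), batch):
            scores.append(network.forward_batch(self.config_, self.weights_, Xenc[lo : lo + batch]))
        return np.concatenate(scores)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return self.classes_[(s > 0.5).astype(int)]

    @classmethod
    def from_weights(cls, weights: LayerWeights, config: NetworkConfig) -> "CNNFragmentClassifier":
        est = cls(
            input_length=config.L, n_kernels=config.F, kernel_width=config.M,
            pool_size=config.S1, pool_stride=config.S2, dropout=config.P,
            dense_units=config.R, variant=config.variant,
            bn_epsilon=config.bn_epsilon, bn_momentum=config.bn_momentum,
        )
        est.config_ = config
        est.weights_ = weights
        est.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS], dtype=object)
        est.history_ = TrainingLog()
        est.n_features_in_ = 1
        return est


class PhageLifestyleClassifier(ClassifierMixin, BaseEstimator):
    """Length-routed ensemble: one :class:`CNNFragmentClassifier` per stratum.

    ``fit`` buckets training fragments into the four length strata and trains
    a model for each stratum present. ``predict`` accepts sequences of any
    length: in-range sequences are padded and scored by their stratum's model,
    sequences shorter than 100 bp fall back to the group-A model, and longer
    sequences are split into 1800-bp pieces whose scores are combined by a
    length-weighted average. Scores inside the band
    (0.5 - cutoff/2, 0.5 + cutoff/2) are labelled 'uncertain'.
    """

    def __init__(self, cutoff: float = 0.0, random_state: int | None = 0,
                 cnn_params: dict | None = None):
        self.cutoff = cutoff
        self.random_state = random_state
        self.cnn_params = cnn_params

    def fit(self, X, y, groups=None):
        from .simulate import GROUPS, model_group_for_length

        if not 0.0 <= self.cutoff < 1.0:
            raise ValueError("cutoff must be in [0, 1)")
        X = list(X)
        y = np.asarray(y)
        groups = np.asarray(groups) if groups is not None else None
        by_group: dict[str, list[int]] = {}
        for i, x in enumerate(X):
            name = model_group_for_length(len(_as_bases(x))).name
            by_group.setdefault(name, []).append(i)
        self.models_: dict[str, CNNFragmentClassifier] = {}
        for name, idx in sorted(by_group.items()):
            est = CNNFragmentClassifier(
                input_length=GROUPS[name].model_input_length,
                random_state=self.random_state,
                **(self.cnn_params or {}),
            )
            est.fit(
                [X[i] for i in idx],
                y[idx],
                groups=None if groups is None else groups[idx],
            )
            self.models_[name] = est
        self.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS], dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        from .predict import route_and_score

        if not hasattr(self, "models_"):
            raise NotFittedError("this PhageLifestyleClassifier instance is not fitted yet")
        return np.array([route_and_score(_as_bases(x), self.models_) for x in X])

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        from .predict import CutoffPolicy, classify

        policy = CutoffPolicy(self.cutoff)
        return np.array([classify(s, policy) for s in self.decision_function(X)], dtype=object)

    @classmethod
    def from_models(cls, models: dict[str, CNNFragmentClassifier], cutoff: float = 0.0):
        est = cls(cutoff=cutoff)
        est.models_ = dict(models)
        est.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS], dtype=object)
        return est
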