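"""Training protocol: one model per length group.

Thin functional wrappers around :class:`~phagelift.model.CNNFragmentClassifier`.
The published protocol: Adam (learning rate 1e-4), binary cross-entropy, batch
size 32. Epoch count and validation protocol are not part of the published
setting; we default to at most 100 epochs with early stopping (patience 10) on
a genome-disjoint validation split of 10% of the training genomes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .model import CNNFragmentClassifier, TrainingLog, bce_loss  # noqa: F401  (re-export)
from .network import LayerWeights, NetworkConfig, load_weights, save_weights
from .simulate import GROUPS, LabeledFragment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainSpec:
    """Optimisation settings (Adam / BCE / batch 32 are the published ones)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")


def _estimator_for(config: NetworkConfig, spec: TrainSpec) -> CNNFragmentClassifier:
    return CNNFragmentClassifier(
        input_length=config.L, n_kernels=config.F, kernel_width=config.M,
        pool_size=config.S1, pool_stride=config.S2, dropout=config.P,
        dense_units=config.R, variant=config.variant,
        bn_epsilon=config.bn_epsilon, bn_momentum=config.bn_momentum,
        learning_rate=spec.learning_rate, batch_size=spec.batch_size,
        max_epochs=spec.max_epochs, patience=spec.patience,
        validation_fraction=spec.validation_fraction, random_state=spec.seed,
    )


def train_model(
    fragments: Sequence[LabeledFragment],
    config: NetworkConfig,
    spec: TrainSpec = TrainSpec(),
) -> tuple[LayerWeights, TrainingLog]:
    """Train one group's model on labelled fragments.

    The early-stopping validation split is genome-disjoint from the updated
    portion. Deterministic given ``spec.seed`` (single-threaded contract).
    """
    if not fragments:
        raise ValueError("cannot train on an empty corpus")
    bad = [f for f in fragments if f.seq.length > config.L]
    if bad:
        raise ValueError(
            f"{len(bad)} fragments exceed the model input length {config.L}"
        )
    est = _estimator_for(config, spec)
    est.fit(
        [f.seq.bases for f in fragments],
        [f.lifestyle for f in fragments],
        groups=[f.genome_id for f in fragments],
    )
    return est.weights_, est.history_


def train_all_groups(
    corpora: Mapping[str, Sequence[LabeledFragment]],
    config_template: NetworkConfig | None = None,
    spec: TrainSpec = TrainSpec(),
) -> dict[str, tuple[LayerWeights, NetworkConfig, TrainingLog]]:
    """Train one model per length group A-D; each model's input length L is
    the group's upper bound."""
    missing = [name for name in GROUPS if name not in corpora or not corpora[name]]
    if missing:
        raise ValueError(f"missing or empty corpus for group(s) {missing}")
    out: dict[str, tuple[LayerWeights, NetworkConfig, TrainingLog]] = {}
    for name, group in GROUPS.items():
        if config_template is None:
            config = NetworkConfig(L=group.model_input_length)
        else:
            from dataclasses import replace

            config = replace(config_template, L=group.model_input_length)
        logger.info("training group %s (L=%d, %d fragments)", name, config.L, len(corpora[name]))
        weights, log = train_model(corpora[name], config, spec)
        out[name] = (weights, config, log)
    return out


def save_manifest(
    models: Mapping[str, tuple[LayerWeights, NetworkConfig, TrainingLog]] | Mapping[str, CNNFragmentClassifier],
    directory: str | Path,
) -> Path:
    """Write one weight archive per group plus a manifest.json mapping
    group name -> archive filename; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, entry in models.items():
        if isinstance(entry, CNNFragmentClassifier):
            weights, config = entry.weights_, entry.config_
        else:
            weights, config = entry[0], entry[1]
        filename = f"group_{name}.npz"
        save_weights(weights, config, directory / filename)
        manifest[name] = filename
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_manifest(manifest_path: str | Path) -> dict[str, CNNFragmentClassifier]:
    """Load per-group models referenced by a manifest.json."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    models: dict[str, CNNFragmentClassifier] = {}
    for name, filename in manifest.items():
        weights, config = load_weights(manifest_path.parent / filename)
        models[name] = CNNFragmentClassifier.from_weights(weights, config)
    return models
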