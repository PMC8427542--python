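import numpy as np
import pytest

from phagelift.network import LayerWeights, NetworkConfig, initialize_weights
from phagelift.simulate import (
    GROUP_A,
    GROUP_D,
    extract_fragments,
    synthetic_genome_set,
)


def random_weights(config: NetworkConfig, rng: np.random.Generator) -> LayerWeights:
    """Random weights with non-trivial BN statistics for oracle comparisons."""
    w = initialize_weights(config, rng)
    for bn in (w.bn1, w.bn2):
        if bn is not None:
            n = len(bn.gamma)
            bn.gamma[:] = rng.normal(1.0, 0.2, n)
            bn.beta[:] = rng.normal(0.0, 0.2, n)
            bn.running_mean[:] = rng.normal(0.0, 0.5, n)
            bn.running_var[:] = rng.random(n) + 0.2
    return w


def random_onehot(L: int, rng: np.random.Generator) -> np.ndarray:
    """Random one-hot matrix, with occasional all-zero (ambiguous) rows."""
    cols = rng.integers(0, 4, size=L)
    mat = np.zeros((L, 4))
    keep = rng.random(L) > 0.02
    mat[np.arange(L)[keep], cols[keep]] = 1.0
    return mat


@pytest.fixture(scope="session")
def synthetic_pair():
    """Small synthetic two-class genome set (8 genomes/class of 20 kb)."""
    genomes, labels = synthetic_genome_set(n_per_class=8, genome_length=20_000, seed=11)
    return genomes, labels


@pytest.fixture(scope="session")
def tiny_fragment_corpus(synthetic_pair):
    """A small balanced group-D corpus for training smoke tests."""
    genomes, labels = synthetic_pair
    lifestyle_of = dict(zip(labels["genome_id"], labels["lifestyle"]))
    rng = np.random.default_rng(7)
    frags = []
    for gid, genome in sorted(genomes.items()):
        frags.extend(extract_fragments(genome, lifestyle_of[gid], GROUP_D, 12, rng))
    return frags


@pytest.fixture(scope="session")
def tiny_fragment_corpus_a(synthetic_pair):
    genomes, labels = synthetic_pair
    lifestyle_of = dict(zip(labels["genome_id"], labels["lifestyle"]))
    rng = np.random.default_rng(8)
    frags = []
    for gid, genome in sorted(genomes.items()):
        frags.extend(extract_fragments(genome, lifestyle_of[gid], GROUP_A, 12, rng))
    return frags
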