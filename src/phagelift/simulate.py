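"""Synthetic corpora: fragment extraction, genome-level CV folds, and a
two-class Markov-chain genome generator.

Fragments are extracted from labelled genomes into four length strata,
mirroring shotgun read/contig length distributions:

    A: [100, 400) bp    B: [400, 800) bp    C: [800, 1200) bp    D: [1200, 1800] bp

Each stratum has its own model input length (the stratum's upper bound).
Cross-validation is partitioned by *genome*, never by fragment, so no genome
contributes fragments to both a training and a test split.

The synthetic generator draws genomes from order-k nucleotide Markov chains.
Two chains whose transition rows are mixed toward a GC-rich row by different
amounts emulate the compositional ("sequence signature") divergence between
virulent and temperate phage genomes that the classifier exploits; they do not
emulate shared mobile elements, mosaic structure, or sequencing error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .seqio import LIFESTYLES, NucleotideSequence, validate_label_table

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LengthGroup:
    """One fragment-length stratum with its model input length L."""

    name: str
    low: int  # inclusive
    high: int  # exclusive, except the top group where it is inclusive
    model_input_length: int
    top_closed: bool = False

    @property
    def max_length(self) -> int:
        return self.high if self.top_closed else self.high - 1

    def contains(self, length: int) -> bool:
        return self.low <= length <= self.max_length


GROUP_A = LengthGroup("A", 100, 400, 400)
GROUP_B = LengthGroup("B", 400, 800, 800)
GROUP_C = LengthGroup("C", 800, 1200, 1200)
GROUP_D = LengthGroup("D", 1200, 1800, 1800, top_closed=True)

GROUPS: dict[str, LengthGroup] = {g.name: g for g in (GROUP_A, GROUP_B, GROUP_C, GROUP_D)}

MIN_GROUP_LENGTH = GROUP_A.low  # 100 bp
MAX_GROUP_LENGTH = GROUP_D.max_length  # 1800 bp

#: routing directive for sequences shorter than the lowest stratum:
#: score with the group-A model.
SHORT_TO_A = "short->A"
#: routing directive for sequences longer than the top stratum:
#: split into 1800-bp pieces.
SPLIT = "split"


def assign_length_group(length: int) -> LengthGroup | str:
    """Map a sequence length to its stratum or to a routing directive."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if length < MIN_GROUP_LENGTH:
        return SHORT_TO_A
    if length > MAX_GROUP_LENGTH:
        return SPLIT
    for group in GROUPS.values():
        if group.contains(length):
            return group
    raise AssertionError("unreachable: strata cover [100, 1800]")


def model_group_for_length(length: int) -> LengthGroup:
    """The stratum whose model scores an in-range or short sequence."""
    group = assign_length_group(length)
    if group == SHORT_TO_A:
        return GROUP_A
    if group == SPLIT:
        raise ValueError(f"length {length} exceeds {MAX_GROUP_LENGTH}; split it first")
    return group


@dataclass(frozen=True)
class LabeledFragment:
    """A simulated contig: an exact substring of a labelled source genome."""

    seq: NucleotideSequence
    lifestyle: str
    genome_id: str
    group: LengthGroup
    start: int


def extract_fragments(
    genome: NucleotideSequence,
    lifestyle: str,
    group: LengthGroup,
    n: int,
    seed: int | np.random.Generator,
) -> list[LabeledFragment]:
    """Draw ``n`` fragments with uniform lengths in the stratum range and
    uniform start positions; deterministic given the seed.

    Genomes shorter than the stratum minimum are skipped with a warning.
    Lengths are capped at the genome length if the genome is shorter than the
    stratum maximum.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if lifestyle not in LIFESTYLES:
        raise ValueError(f"unknown lifestyle {lifestyle!r}")
    if genome.length < group.low:
        logger.warning(
            "genome %s (%d bp) shorter than group %s minimum %d bp; skipped",
            genome.id, genome.length, group.name, group.low,
        )
        return []
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hi = min(group.max_length, genome.length)
    lengths = rng.integers(group.low, hi + 1, size=n)
    starts = rng.integers(0, genome.length - lengths + 1)
    out = []
    for i, (length, start) in enumerate(zip(lengths, starts)):
        length, start = int(length), int(start)
        frag = NucleotideSequence(
            id=f"{genome.id}|{group.name}|{i}",
            bases=genome.bases[start : start + length],
        )
        out.append(LabeledFragment(frag, lifestyle, genome.id, group, start))
    return out


@dataclass(frozen=True)
class CVFoldPlan:
    """Genome-level fold assignment: curated genomes are partitioned into
    folds stratified by lifestyle; auto-labelled genomes are training-only."""

    n_folds: int
    assignments: Mapping[str, int]
    always_train: frozenset[str] = frozenset()

    def test_genomes(self, fold: int) -> list[str]:
        return sorted(g for g, f in self.assignments.items() if f == fold)

    def train_genomes(self, fold: int) -> list[str]:
        train = sorted(g for g, f in self.assignments.items() if f != fold)
        return train + sorted(self.always_train)


def make_cv_folds(labels: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> CVFoldPlan:
    """Stratified genome-level folds over the curated set.

    Auto-labelled genomes (dataset == 'auto') go to ``always_train`` and are
    never placed in any test fold.
    """
    labels = validate_label_table(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    curated = labels[labels["dataset"] == "curated"]
    for lifestyle in LIFESTYLES:
        n = int((curated["lifestyle"] == lifestyle).sum())
        if n < n_folds:
            raise ValueError(
                f"class {lifestyle!r} has only {n} curated genomes; need >= {n_folds}"
            )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = curated["genome_id"].to_numpy()
    y = curated["lifestyle"].to_numpy()
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(ids, y)):
        for g in ids[test_idx]:
            assignments[str(g)] = fold
    always_train = frozenset(labels.loc[labels["dataset"] == "auto", "genome_id"])
    return CVFoldPlan(n_folds=n_folds, assignments=assignments, always_train=always_train)


def _balanced_counts(total: int, genome_ids: Sequence[str], rng: np.random.Generator) -> dict[str, int]:
    """Spread ``total`` fragments as evenly as possible over genomes."""
    ids = list(genome_ids)
    base, extra = divmod(total, len(ids))
    order = rng.permutation(len(ids))
    return {ids[j]: base + (1 if rank < extra else 0) for rank, j in enumerate(order)}


def _sample_class_fragments(
    genomes: Mapping[str, NucleotideSequence],
    genome_ids: Sequence[str],
    lifestyle: str,
    group: LengthGroup,
    total: int,
    rng: np.random.Generator,
) -> list[LabeledFragment]:
    usable = [g for g in genome_ids if genomes[g].length >= group.low]
    if not usable:
        raise ValueError(f"no {lifestyle} genome long enough for group {group.name}")
    counts = _balanced_counts(total, usable, rng)
    frags: list[LabeledFragment] = []
    for gid in usable:
        frags.extend(extract_fragments(genomes[gid], lifestyle, group, counts[gid], rng))
    return frags


def build_benchmark(
    labels: pd.DataFrame,
    genomes: Mapping[str, NucleotideSequence],
    plan: CVFoldPlan,
    fold: int,
    group: LengthGroup,
    n_train: int = 8000,
    n_test: int = 2000,
    seed: int = 0,
) -> tuple[list[LabeledFragment], list[LabeledFragment]]:
    """Build one fold's (train, test) fragment corpora for one stratum.

    Per-class fragment counts are balanced within ±1; train fragments come
    only from the fold's training genomes and test fragments only from its
    held-out genomes, so the genome-leakage invariant holds by construction.
    """
    if not 0 <= fold < plan.n_folds:
        raise ValueError(f"fold {fold} out of range for {plan.n_folds}-fold plan")
    labels = validate_label_table(labels)
    lifestyle_of = dict(zip(labels["genome_id"], labels["lifestyle"]))
    rng = np.random.default_rng(seed)

    def _build(genome_ids: Sequence[str], total: int) -> list[LabeledFragment]:
        frags: list[LabeledFragment] = []
        half = total // 2
        per_class = {"virulent": half, "temperate": total - half}
        for lifestyle, class_total in per_class.items():
            ids = [g for g in genome_ids if lifestyle_of.get(g) == lifestyle]
            if not ids:
                raise ValueError(f"no {lifestyle} genomes available in split")
            frags.extend(
                _sample_class_fragments(genomes, ids, lifestyle, group, class_total, rng)
            )
        return frags

    train = _build(plan.train_genomes(fold), n_train)
    test = _build(plan.test_genomes(fold), n_test)
    return train, test


@dataclass(frozen=True)
class SyntheticClassModel:
    """Order-k nucleotide Markov chain for one lifestyle class."""

    transition: np.ndarray  # (4^order, 4) row-stochastic
    genome_length: int
    label: str
    order: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=np.float64)
        if t.shape != (4**self.order, 4):
            raise ValueError(f"transition must be {4**self.order}×4, got {t.shape}")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        object.__setattr__(self, "transition", t)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary base distribution (order-1 chains) via eigen-analysis."""
        if self.order != 1:
            raise NotImplementedError("stationary distribution only for order 1")
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


# Transition matrix of the synthetic "virulent" class (rows/cols A, C, G, T):
# mildly AT-leaning with some first-order structure.
VIRULENT_TRANSITION = np.array(
    [
        [0.35, 0.15, 0.20, 0.30],
        [0.30, 0.20, 0.15, 0.35],
        [0.25, 0.25, 0.25, 0.25],
        [0.30, 0.20, 0.20, 0.30],
    ]
)

#: GC-rich row used to perturb the virulent chain into the temperate one.
GC_BIASED_ROW = np.array([0.10, 0.40, 0.40, 0.10])


def default_class_models(
    genome_length: int = 50_000, mix: float = 0.15
) -> tuple[SyntheticClassModel, SyntheticClassModel]:
    """The canonical synthetic study pair: the temperate chain's rows are the
    virulent rows mixed ``1-mix : mix`` with a GC-biased row, emulating the
    amelioration of temperate phage composition toward host chromosomes."""
    virulent = SyntheticClassModel(VIRULENT_TRANSITION, genome_length, "virulent")
    temperate = SyntheticClassModel(
        (1.0 - mix) * VIRULENT_TRANSITION + mix * GC_BIASED_ROW[None, :],
        genome_length,
        "temperate",
    )
    return virulent, temperate


def generate_synthetic_genomes(
    model: SyntheticClassModel, n_genomes: int, seed: int | np.random.Generator
) -> list[tuple[NucleotideSequence, str]]:
    """Sample genomes from the class chain (uniform initial state)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cum = np.cumsum(model.transition, axis=1)
    cum[:, -1] = 1.0
    n_states = model.transition.shape[0]
    # plain-tuple thresholds keep the sequential sampling loop cheap
    rows = [tuple(float(c) for c in cum[s, :3]) for s in range(n_states)]
    out = []
    for g in range(n_genomes):
        L = model.genome_length
        u = rng.random(L).tolist()
        codes = bytearray(L)
        state = int(rng.integers(n_states))
        # seed the first `order` bases from the uniform initial state
        s = state
        for j in range(model.order - 1, -1, -1):
            codes[j] = s % 4
            s //= 4
        if model.order == 1:
            for i in range(1, L):
                c0, c1, c2 = rows[state]
                ui = u[i]
                state = 0 if ui < c0 else 1 if ui < c1 else 2 if ui < c2 else 3
                codes[i] = state
        else:
            for i in range(model.order, L):
                c0, c1, c2 = rows[state]
                ui = u[i]
                b = 0 if ui < c0 else 1 if ui < c1 else 2 if ui < c2 else 3
                codes[i] = b
                state = (state * 4 + b) % n_states
        bases = _ACGT[np.frombuffer(bytes(codes), dtype=np.uint8)].tobytes().decode("ascii")
        out.append(
            (NucleotideSequence(id=f"{model.label}_g{g}", bases=bases), model.label)
        )
    return out


def synthetic_genome_set(
    n_per_class: int = 20,
    genome_length: int = 50_000,
    mix: float = 0.15,
    seed: int = 0,
) -> tuple[dict[str, NucleotideSequence], pd.DataFrame]:
    """Generate the paired synthetic corpus plus its label table."""
    virulent, temperate = default_class_models(genome_length, mix)
    rng = np.random.default_rng(seed)
    genomes: dict[str, NucleotideSequence] = {}
    rows = []
    for model in (virulent, temperate):
        for seq, label in generate_synthetic_genomes(model, n_per_class, rng):
            genomes[seq.id] = seq
            rows.append((seq.id, label, "curated"))
    labels = pd.DataFrame(rows, columns=["genome_id", "lifestyle", "dataset"])
    return genomes, labels


def fragments_to_frame(fragments: Iterable[LabeledFragment]) -> pd.DataFrame:
    """Sidecar table (fragment_id, genome_id, lifestyle, group, start, length)."""
    rows = [
        (f.seq.id, f.genome_id, f.lifestyle, f.group.name, f.start, f.seq.length)
        for f in fragments
    ]
    return pd.DataFrame(
        rows, columns=["fragment_id", "genome_id", "lifestyle", "group", "start", "length"]
    )
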