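"""Scoring arbitrary-length sequences: routing, splitting, cut-off labelling.

A sequence inside the trained strata (100-1800 bp) is zero-padded to its
stratum's input length and scored by that stratum's model; a sequence shorter
than 100 bp falls back to the group-A model; a longer sequence is split into
non-overlapping 1800-bp pieces (plus a remainder), each piece is scored by its
own length's model, and the piece scores are combined by a length-weighted
average. The final score is P(virulent). Scores inside the open band
(0.5 - t/2, 0.5 + t/2) are labelled "uncertain" under cut-off t; the
recommended cut-off for filtered calls is 0.5, the default (t=0) reports all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import CNNFragmentClassifier
from .seqio import (
    NucleotideSequence,
    PredictionRecord,
    read_fasta,
    write_prediction_report,
)
from .simulate import MAX_GROUP_LENGTH, model_group_for_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutoffPolicy:
    """Uncertainty band (0.5 - t/2, 0.5 + t/2); t=0 reports every call."""

    t: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t < 1.0:
            raise ValueError(f"cut-off must be in [0, 1), got {self.t}")


def split_long_sequence(seq: NucleotideSequence) -> list[NucleotideSequence]:
    """Split a >1800 bp sequence into consecutive 1800-bp pieces plus a
    remainder; concatenating the pieces reproduces the input."""
    if seq.length <= MAX_GROUP_LENGTH:
        raise ValueError(
            f"split_long_sequence requires length > {MAX_GROUP_LENGTH}, got {seq.length}"
        )
    pieces = []
    for i, start in enumerate(range(0, seq.length, MAX_GROUP_LENGTH)):
        chunk = seq.bases[start : start + MAX_GROUP_LENGTH]
        pieces.append(NucleotideSequence(id=f"{seq.id}|piece{i}", bases=chunk))
    return pieces


def combine_scores(pieces: Sequence[tuple[int, float]]) -> float:
    """Length-weighted average of (length, score) piece results."""
    if not pieces:
        raise ValueError("combine_scores requires at least one piece")
    lengths = np.array([p[0] for p in pieces], dtype=np.float64)
    scores = np.array([p[1] for p in pieces], dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("piece lengths must be positive")
    return float(np.sum(lengths * scores) / np.sum(lengths))


def _score_in_range(bases: str, models: Mapping[str, CNNFragmentClassifier]) -> float:
    group = model_group_for_length(len(bases))
    if group.name not in models:
        raise KeyError(f"no model available for group {group.name}")
    return float(models[group.name].decision_function([bases])[0])


def route_and_score(
    seq: NucleotideSequence | str, models: Mapping[str, CNNFragmentClassifier]
) -> float:
    """Score one sequence of any length with the per-group model ensemble."""
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
    if not bases:
        raise ValueError("cannot score an empty sequence")
    if len(bases) <= MAX_GROUP_LENGTH:
        return _score_in_range(bases, models)
    record = seq if isinstance(seq, NucleotideSequence) else NucleotideSequence("seq", bases)
    pieces = split_long_sequence(record)
    piece_scores = [(p.length, _score_in_range(p.bases, models)) for p in pieces]
    return combine_scores(piece_scores)


def classify(score: float, policy: CutoffPolicy = CutoffPolicy()) -> str:
    """Label a score: virulent above the band, temperate below, uncertain
    inside (an exact 0.5 is uncertain even at t=0)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0, 1], got {score}")
    half = policy.t / 2.0
    if score > 0.5 + half:
        return "virulent"
    if score < 0.5 - half:
        return "temperate"
    return "uncertain"


def _batched_scores(
    seqs: Sequence[NucleotideSequence], models: Mapping[str, CNNFragmentClassifier]
) -> list[float]:
    """Score many sequences, batching in-range sequences per group."""
    scores: list[float | None] = [None] * len(seqs)
    by_group: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        if s.length > MAX_GROUP_LENGTH:
            scores[i] = route_and_score(s, models)
        else:
            by_group.setdefault(model_group_for_length(s.length).name, []).append(i)
    for name, idx in by_group.items():
        if name not in models:
            raise KeyError(f"no model available for group {name}")
        batch = models[name].decision_function([seqs[i].bases for i in idx])
        for i, s in zip(idx, batch):
            scores[i] = float(s)
    return scores  # type: ignore[return-value]


def predict_records(
    seqs: Iterable[NucleotideSequence],
    models: Mapping[str, CNNFragmentClassifier],
    policy: CutoffPolicy = CutoffPolicy(),
    batch_size: int = 1024,
) -> list[PredictionRecord]:
    seqs = list(seqs)
    records: list[PredictionRecord] = []
    for lo in range(0, len(seqs), batch_size):
        chunk = seqs[lo : lo + batch_size]
        for s, score in zip(chunk, _batched_scores(chunk, models)):
            records.append(PredictionRecord(s.id, s.length, score, classify(score, policy)))
    return records


def predict_file(
    fasta_path: str | Path,
    models: Mapping[str, CNNFragmentClassifier],
    policy: CutoffPolicy = CutoffPolicy(),
    out_path: str | Path | None = None,
) -> dict[str, int]:
    """Predict every sequence in a FASTA file; optionally write the TSV
    report; return label counts."""
    records = predict_records(read_fasta(fasta_path), models, policy)
    if out_path is not None:
        write_prediction_report(records, out_path)
    summary = {"virulent": 0, "temperate": 0, "uncertain": 0, "total": 0}
    for r in records:
        summary[r.label] += 1
        summary["total"] += 1
    return summary
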