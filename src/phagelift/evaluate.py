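"""Performance metrics and the genome-level cross-validation experiment.

Virulent is the positive class throughout:

    Sn  = TP / (TP + FN)        (virulent recall)
    Sp  = TN / (TN + FP)        (temperate recall)
    Acc = (TP + TN) / (TP + TN + FP + FN)

AUC is the tie-aware Mann-Whitney statistic normalised by n_pos * n_neg.
Evaluation defaults to cut-off t=0 (no "uncertain" withholding); records
labelled uncertain under a nonzero cut-off are excluded from the confusion
counts and reported separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import CNNFragmentClassifier, POSITIVE_CLASS
from .network import NetworkConfig
from .predict import CutoffPolicy, classify
from .seqio import NucleotideSequence, PredictionRecord
from .simulate import CVFoldPlan, GROUPS, LengthGroup, build_benchmark
from .training import TrainSpec, train_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    n_uncertain_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(
    records: Sequence[PredictionRecord], truths: Sequence[str]
) -> ConfusionCounts:
    """Count TP/FP/TN/FN over non-uncertain records (virulent = positive)."""
    if len(records) != len(truths):
        raise ValueError("records and truths must align")
    tp = fp = tn = fn = unc = 0
    for rec, truth in zip(records, truths):
        if rec.label == "uncertain":
            unc += 1
            continue
        pos_pred = rec.label == POSITIVE_CLASS
        pos_true = truth == POSITIVE_CLASS
        if pos_pred and pos_true:
            tp += 1
        elif pos_pred:
            fp += 1
        elif pos_true:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp, fp, tn, fn, unc)
    if counts.total == 0:
        raise ValueError("no non-uncertain records to evaluate")
    return counts


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(Sn, Sp, Acc); an undefined ratio (zero denominator) is NaN with a
    logged warning."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined: zero denominator", name)
            return math.nan
        return num / den

    sn = ratio(counts.TP, counts.TP + counts.FN, "Sn")
    sp = ratio(counts.TN, counts.TN + counts.FP, "Sp")
    acc = ratio(counts.TP + counts.TN, counts.total, "Acc")
    return sn, sp, acc


def roc_auc(scores: Sequence[float], truths: Sequence) -> float:
    """AUC = normalised Mann-Whitney U; ties count 1/2. Truths may be
    lifestyle strings or 0/1."""
    y = np.asarray([t == POSITIVE_CLASS if isinstance(t, str) else bool(t) for t in truths])
    if y.all() or not y.any():
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Per fold × group metrics plus mean ± SD per group."""

    per_fold: pd.DataFrame  # columns: fold, group, Sn, Sp, Acc, AUC, n_test, n_uncertain_excluded
    summary: pd.DataFrame  # columns: group, metric, mean, sd

    def to_json_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
        }


def _summarize(per_fold: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, sub in per_fold.groupby("group"):
        for metric in ("Sn", "Sp", "Acc", "AUC"):
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "mean": float(sub[metric].mean()),
                    "sd": float(sub[metric].std(ddof=1)) if len(sub) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def evaluate_fragments(
    est: CNNFragmentClassifier,
    fragments,
    policy: CutoffPolicy = CutoffPolicy(),
) -> dict[str, float]:
    """Score labelled fragments with a fitted model and compute the metrics."""
    scores = est.decision_function([f.seq.bases for f in fragments])
    truths = [f.lifestyle for f in fragments]
    records = [
        PredictionRecord(f.seq.id, f.seq.length, float(s), classify(float(s), policy))
        for f, s in zip(fragments, scores)
    ]
    counts = confusion(records, truths)
    sn, sp, acc = metrics(counts)
    return {
        "Sn": sn,
        "Sp": sp,
        "Acc": acc,
        "AUC": roc_auc(scores, truths),
        "n_test": len(fragments),
        "n_uncertain_excluded": counts.n_uncertain_excluded,
    }


def run_cross_validation(
    genomes: Mapping[str, NucleotideSequence],
    labels: pd.DataFrame,
    plan: CVFoldPlan,
    groups: Sequence[LengthGroup] | None = None,
    n_train: int = 8000,
    n_test: int = 2000,
    config_template: NetworkConfig | None = None,
    spec: TrainSpec = TrainSpec(),
    seed: int = 0,
    policy: CutoffPolicy = CutoffPolicy(),
) -> MetricsReport:
    """Genome-level k-fold CV: per fold × group, simulate a leakage-free
    benchmark, train from scratch, and evaluate on the held-out fragments."""
    from dataclasses import replace

    groups = list(GROUPS.values()) if groups is None else list(groups)
    rows = []
    for group in groups:
        for fold in range(plan.n_folds):
            train_frags, test_frags = build_benchmark(
                labels, genomes, plan, fold, group, n_train, n_test,
                seed=seed + 1000 * fold,
            )
            leaked = {f.genome_id for f in train_frags} & {f.genome_id for f in test_frags}
            if leaked:
                raise AssertionError(f"genome leakage in fold {fold}: {sorted(leaked)}")
            if config_template is None:
                config = NetworkConfig(L=group.model_input_length)
            else:
                config = replace(config_template, L=group.model_input_length)
            weights, _ = train_model(train_frags, config, replace(spec, seed=spec.seed + fold))
            est = CNNFragmentClassifier.from_weights(weights, config)
            result = evaluate_fragments(est, test_frags, policy)
            logger.info("group %s fold %d: Acc=%.3f", group.name, fold, result["Acc"])
            rows.append({"fold": fold, "group": group.name, **result})
    per_fold = pd.DataFrame(rows)
    return MetricsReport(per_fold=per_fold, summary=_summarize(per_fold))


def run_ablation(
    benchmark: tuple[Sequence, Sequence],
    variants: Sequence[str],
    config_template: NetworkConfig,
    spec: TrainSpec = TrainSpec(),
) -> pd.DataFrame:
    """Train and evaluate each architecture variant on the identical
    benchmark with identical seeds; one metrics row per variant."""
    from dataclasses import replace

    train_frags, test_frags = benchmark
    rows = []
    for variant in variants:
        config = replace(config_template, variant=variant)
        weights, _ = train_model(train_frags, config, spec)
        est = CNNFragmentClassifier.from_weights(weights, config)
        result = evaluate_fragments(est, test_frags)
        rows.append({"variant": variant, **result})
    return pd.DataFrame(rows)
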