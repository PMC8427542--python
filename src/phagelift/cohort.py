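"""Cross-sectional comparison of temperate-phage proportions between sample
groups ("phage transformation" analysis).

Each sample's prediction report is reduced to the proportion of its classified
contigs that are temperate (uncertain calls excluded); two groups of samples
are compared with a two-sided Wilcoxon rank-sum test, reporting the
Hodges-Lehmann difference in location with a 95% confidence interval.

Proportions are per contig, unweighted by contig length, with an optional
base-pair-weighted variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy import stats

from .seqio import PredictionRecord

#: largest per-group size for which the exact permutation null is used
EXACT_MAX_N = 12


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    source: str  # "metagenome_phage" | "virome"
    n_virulent: int
    n_temperate: int
    n_uncertain: int
    temperate_proportion: float | None  # None when no classified contigs

    @property
    def defined(self) -> bool:
        return self.temperate_proportion is not None


def summarize_sample(
    records: Sequence[PredictionRecord],
    sample_id: str,
    source: str = "virome",
    length_weighted: bool = False,
) -> SampleSummary:
    """Reduce one sample's predictions to counts and a temperate proportion.

    The proportion excludes uncertain calls; it is flagged undefined (None)
    when no contig is classified.
    """
    n_v = sum(1 for r in records if r.label == "virulent")
    n_t = sum(1 for r in records if r.label == "temperate")
    n_u = sum(1 for r in records if r.label == "uncertain")
    if n_v + n_t + n_u != len(records):
        raise ValueError("records contain labels outside virulent/temperate/uncertain")
    if length_weighted:
        bp_t = sum(r.length for r in records if r.label == "temperate")
        bp_vt = sum(r.length for r in records if r.label in ("virulent", "temperate"))
        proportion = bp_t / bp_vt if bp_vt else None
    else:
        proportion = n_t / (n_t + n_v) if (n_t + n_v) else None
    return SampleSummary(sample_id, source, n_v, n_t, n_u, proportion)


@dataclass(frozen=True)
class GroupComparison:
    p_value: float
    location_shift: float  # Hodges-Lehmann estimate, group1 - group2
    ci_low: float
    ci_high: float
    method: str  # "exact" | "asymptotic"
    confidence: float = 0.95


def _rank_sum_null(ranks: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation null of the group-1 rank sum (midranks, so ties are
    handled exactly): unique rank-sum values and their probabilities."""
    sums: dict[float, int] = {}
    for idx in combinations(range(len(ranks)), n1):
        w = round(float(ranks[list(idx)].sum()), 8)
        sums[w] = sums.get(w, 0) + 1
    total = comb(len(ranks), n1)
    values = np.array(sorted(sums))
    probs = np.array([sums[v] for v in values], dtype=float) / total
    return values, probs


def _exact_p_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Doubled smaller tail of the exact (tie-aware) rank-sum null."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = round(float(ranks[: len(x)].sum()), 8)
    values, probs = _rank_sum_null(ranks, len(x))
    lower = probs[values <= w_obs + 1e-9].sum()
    upper = probs[values >= w_obs - 1e-9].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _u_quantile_exact(n1: int, n2: int, alpha: float) -> int:
    """Largest k with P(U <= k-1) <= alpha under the no-ties exact null of the
    Mann-Whitney U; used for the confidence interval's order statistics."""
    # generating-function convolution: ways to reach each U value
    poly = np.array([1.0])
    for _ in range(n1):
        poly = np.convolve(poly, np.ones(n2 + 1))[: n1 * n2 + 1]
    poly = poly / comb(n1 + n2, n1)
    cdf = np.cumsum(poly)
    k = int(np.searchsorted(cdf, alpha, side="right"))
    return k


def _hl_shift_and_ci(
    x: np.ndarray, y: np.ndarray, exact: bool, confidence: float
) -> tuple[float, float, float]:
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    shift = float(np.median(diffs))
    m = len(diffs)
    alpha = (1.0 - confidence) / 2.0
    if exact:
        k = _u_quantile_exact(len(x), len(y), alpha)
    else:
        n1, n2 = len(x), len(y)
        mu = n1 * n2 / 2.0
        sigma = sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        k = max(0, int(np.floor(mu + stats.norm.ppf(alpha) * sigma)))
    k = min(k, (m - 1) // 2)
    return shift, float(diffs[k]), float(diffs[m - 1 - k])


def compare_groups(
    group1: Sequence[float],
    group2: Sequence[float],
    confidence: float = 0.95,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two sets of per-sample
    proportions, with the Hodges-Lehmann location shift (group1 - group2) and
    its confidence interval.

    The exact permutation null (tie-aware) is used when both groups have at
    most 12 samples; larger groups use the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray([v for v in group1 if v is not None], dtype=float)
    y = np.asarray([v for v in group2 if v is not None], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 defined proportions")
    exact = len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
    if exact:
        p = _exact_p_two_sided(x, y)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True).pvalue
        )
        method = "asymptotic"
    shift, lo, hi = _hl_shift_and_ci(x, y, exact, confidence)
    return GroupComparison(p, shift, lo, hi, method, confidence)
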