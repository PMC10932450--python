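"""Nonparametric group comparisons: summaries, Kruskal-Wallis, Dunn's post hoc.

Peak-area distributions are right-skewed, so classes are summarised by
median and IQR and compared by rank tests.  Quantiles use numpy's linear
interpolation rule throughout (the choice matters for the IQR and is
pinned here).  The omnibus Kruskal-Wallis H uses mid-ranks with tie
correction and a chi-square reference distribution; Dunn's pairwise z-tests
run on the pooled mid-ranks with the same tie correction and a Bonferroni
adjustment over all k(k-1)/2 pairs — the conventional, conservative
companion to Dunn's test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .core import ElectrolyteFeatures, TissueClass, ValidationError

__all__ = [
    "GroupSummary",
    "KWResult",
    "DunnResult",
    "summarize_groups",
    "kruskal_wallis",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class GroupSummary:
    tissue: TissueClass
    n: int
    median: float
    iqr: float


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float


@dataclass(frozen=True)
class DunnResult:
    pair: tuple
    z: float
    p_raw: float
    p_adj: float


def summarize_groups(
    features: list[ElectrolyteFeatures], element: str
) -> list[GroupSummary]:
    """Median and IQR (Q75 - Q25, linear interpolation) of one element per class."""
    groups: dict[TissueClass, list[float]] = {}
    for f in features:
        if f.tissue is None:
            raise ValidationError(f"spectrum {f.spectrum_id!r} is unlabelled")
        groups.setdefault(f.tissue, []).append(f.value(element))
    out = []
    for tissue in TissueClass:
        if tissue not in groups:
            continue
        values = np.asarray(groups[tissue])
        q25, q50, q75 = np.percentile(values, [25, 50, 75])
        out.append(
            GroupSummary(tissue=tissue, n=len(values), median=float(q50), iqr=float(q75 - q25))
        )
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square (df = k - 1) p-value."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("all groups must be nonempty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # Degenerate input: every observation identical -> no evidence at all.
        return KWResult(H=0.0, df=df, p=1.0)
    H, p = sps.kruskal(*arrays)
    return KWResult(H=float(H), df=df, p=float(p))


def _rank_state(arrays: list[np.ndarray]):
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)  # mid-ranks
    N = len(pooled)
    # Tie correction term sum(t^3 - t) over tie groups.
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + len(a)].mean()))
        start += len(a)
    return mean_ranks, N, tie_term


def dunn_posthoc(groups: dict[TissueClass, np.ndarray] | dict[str, np.ndarray]) -> list[DunnResult]:
    """Dunn's pairwise z-tests on pooled mid-ranks, Bonferroni-adjusted.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)``; two-sided normal p, then ``p_adj = min(1, m p_raw)``
    over the m = k(k-1)/2 comparisons.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("all groups must be nonempty")
    mean_ranks, N, tie_term = _rank_state(arrays)
    m = len(labels) * (len(labels) - 1) // 2
    variance_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    results = []
    for i, j in combinations(range(len(labels)), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        if variance_core <= 0:  # all observations tied
            z = 0.0
        else:
            se = np.sqrt(variance_core * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        results.append(
            DunnResult(
                pair=(labels[i], labels[j]),
                z=float(z),
                p_raw=p_raw,
                p_adj=min(1.0, m * p_raw),
            )
        )
    return results
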