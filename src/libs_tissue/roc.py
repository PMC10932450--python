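"""Pairwise ROC analysis, Youden cutoffs, and the ordered metric scales.

The diagnostic question is always pairwise: can peak areas of one element
separate two tissue classes?  The empirical AUC is computed through the
Mann-Whitney identity (probability that a random positive outranks a random
negative, ties counted half), oriented so AUC >= 0.5 with the orientation
reported.  Confidence intervals use DeLong's structural-components
variance; p-values come from the normal approximation to the Mann-Whitney
null.  Optimal cutoffs maximise the Youden index J = sensitivity +
specificity - 1 over midpoints between adjacent distinct observed values.

A *metric scale* stitches three adjacent-pair Youden cutoffs into a partition
of the biomarker axis into four ordered class intervals ``[c_{i-1}, c_i)``
(boundaries belong to the upper class), one scale per element.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .core import ElectrolyteFeatures, STUDY_CLASSES, TissueClass, ValidationError

__all__ = [
    "RocResult",
    "MetricScale",
    "YoudenResult",
    "auc_mann_whitney",
    "auc_ci_delong",
    "mann_whitney_p",
    "youden_cutoff",
    "pairwise_roc_report",
    "build_metric_scale",
    "classify",
]

HIGHER = "higher-is-positive"
LOWER = "lower-is-positive"


def _as_arrays(pos, neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both samples must be nonempty")
    return pos, neg


def auc_mann_whitney(pos, neg) -> tuple[float, str]:
    """Empirical AUC by the rank-sum identity, oriented so AUC >= 0.5.

    Returns ``(auc, direction)`` where direction says whether higher or lower
    scores indicate the positive class.
    """
    pos, neg = _as_arrays(pos, neg)
    m, n = len(pos), len(neg)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    auc = u / (m * n)
    if auc >= 0.5:
        return float(auc), HIGHER
    return float(1.0 - auc), LOWER


def _oriented(pos: np.ndarray, neg: np.ndarray, direction: str) -> tuple[np.ndarray, np.ndarray]:
    if direction == HIGHER:
        return pos, neg
    if direction == LOWER:
        return -pos, -neg
    raise ValidationError(f"unknown direction {direction!r}")


def _placement_values(scores: np.ndarray, against: np.ndarray) -> np.ndarray:
    """P(against < s) + 0.5 P(against = s) for each score s."""
    srt = np.sort(against)
    left = np.searchsorted(srt, scores, side="left")
    right = np.searchsorted(srt, scores, side="right")
    return (left + 0.5 * (right - left)) / len(against)


def auc_ci_delong(pos, neg, *, level: float = 0.95) -> tuple[float, float]:
    """DeLong 95% (by default) confidence interval for the oriented AUC.

    With a degenerate zero variance at AUC = 1 (perfect separation), the
    interval collapses to ``(auc, auc)``.
    """
    pos, neg = _as_arrays(pos, neg)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("DeLong CI requires at least 2 values per sample")
    auc, direction = auc_mann_whitney(pos, neg)
    p, n = _oriented(pos, neg, direction)
    v10 = _placement_values(p, n)  # per-positive components
    v01 = _placement_values(-n, -p)  # per-negative components (P(pos > y) etc.)
    var = v10.var(ddof=1) / len(p) + v01.var(ddof=1) / len(n)
    if var <= 0:
        return (auc, auc)
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    half = z * float(np.sqrt(var))
    return (max(0.0, auc - half), min(1.0, auc + half))


def mann_whitney_p(pos, neg) -> float:
    """Two-sided p against the null AUC = 0.5 (normal approximation, tie-corrected)."""
    pos, neg = _as_arrays(pos, neg)
    return float(sps.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue)


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str
    j: float


def youden_cutoff(pos, neg, direction: str | None = None) -> YoudenResult:
    """Cutoff maximising J over midpoints between adjacent distinct values.

    Orientation defaults to the AUC-selected direction; ties in J break
    toward higher sensitivity, then the lower cutoff (on the oriented axis).
    Positive calls are ``value >= cutoff`` for higher-is-positive and
    ``value <= cutoff`` for lower-is-positive.
    """
    pos, neg = _as_arrays(pos, neg)
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        raise ValidationError("all values identical: no informative threshold exists")
    if direction is None:
        _, direction = auc_mann_whitney(pos, neg)
    tp, tn = _oriented(pos, neg, direction)
    distinct = np.unique(np.concatenate([tp, tn]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    sp = np.sort(tp)
    sn = np.sort(tn)
    sens = 1.0 - np.searchsorted(sp, mids, side="left") / len(sp)
    spec = np.searchsorted(sn, mids, side="left") / len(sn)
    j = sens + spec - 1.0
    best = sorted(range(len(mids)), key=lambda i: (-j[i], -sens[i], mids[i]))[0]
    cutoff = float(mids[best]) if direction == HIGHER else float(-mids[best])
    return YoudenResult(
        cutoff=cutoff,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        direction=direction,
        j=float(j[best]),
    )


@dataclass(frozen=True)
class RocResult:
    """One pairwise discrimination row: AUC, CI, p, Youden cutoff and rates."""

    positive_class: TissueClass
    negative_class: TissueClass
    element: str
    auc: float
    ci95: tuple[float, float]
    p: float
    direction: str
    cutoff: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class.value,
            "negative_class": self.negative_class.value,
            "element": self.element,
            "auc": self.auc,
            "ci95": list(self.ci95),
            "p": self.p,
            "direction": self.direction,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _values_by_class(
    features: list[ElectrolyteFeatures], element: str
) -> dict[TissueClass, np.ndarray]:
    out: dict[TissueClass, list[float]] = {}
    for f in features:
        if f.tissue is not None:
            out.setdefault(f.tissue, []).append(f.value(element))
    return {t: np.asarray(v) for t, v in out.items()}


def pairwise_roc_report(
    features: list[ElectrolyteFeatures], elements: tuple[str, ...] = ("Ca", "K")
) -> list[RocResult]:
    """All 6 study-class pairs x requested elements (12 rows by default)."""
    results = []
    for element in elements:
        values = _values_by_class(features, element)
        missing = [c.value for c in STUDY_CLASSES if c not in values]
        if missing:
            raise ValidationError(f"missing study class(es) {missing} for element {element}")
        for a, b in combinations(STUDY_CLASSES, 2):
            pos, neg = values[a], values[b]
            auc, direction = auc_mann_whitney(pos, neg)
            ci = auc_ci_delong(pos, neg)
            yr = youden_cutoff(pos, neg, direction=direction)
            results.append(
                RocResult(
                    positive_class=a,
                    negative_class=b,
                    element=element,
                    auc=auc,
                    ci95=ci,
                    p=mann_whitney_p(pos, neg),
                    direction=direction,
                    cutoff=yr.cutoff,
                    sensitivity=yr.sensitivity,
                    specificity=yr.specificity,
                )
            )
    return results


@dataclass(frozen=True)
class MetricScale:
    """Four ordered tissue classes partitioning [0, inf) at three cutoffs."""

    element: str
    ordered_classes: tuple[TissueClass, TissueClass, TissueClass, TissueClass]
    cutoffs: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.cutoffs[0] < self.cutoffs[1] < self.cutoffs[2]):
            raise ValidationError(f"cutoffs must be strictly ascending, got {self.cutoffs}")

    @property
    def intervals(self) -> list[tuple[float, float]]:
        edges = (0.0, *self.cutoffs, np.inf)
        return [(edges[i], edges[i + 1]) for i in range(4)]

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "ordered_classes": [c.value for c in self.ordered_classes],
            "cutoffs": list(self.cutoffs),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MetricScale":
        return cls(
            element=data["element"],
            ordered_classes=tuple(TissueClass(c) for c in data["ordered_classes"]),
            cutoffs=tuple(float(c) for c in data["cutoffs"]),
        )


def build_metric_scale(features: list[ElectrolyteFeatures], element: str) -> MetricScale:
    """Order the four study classes by median and cut between adjacent pairs.

    Each cutoff is the Youden-optimal threshold of the two median-adjacent
    classes only (forced higher-is-positive for the upper class), which is the
    only construction under which three cutoffs partition the axis.  If the
    cutoffs come out non-ascending the scale is undefined and an error names
    the violating pair.
    """
    values = _values_by_class(features, element)
    missing = [c.value for c in STUDY_CLASSES if c not in values]
    if missing:
        raise ValidationError(f"missing study class(es) {missing} for element {element}")
    ordered = tuple(sorted(STUDY_CLASSES, key=lambda c: np.median(values[c])))
    cutoffs = []
    for lo_cls, hi_cls in zip(ordered, ordered[1:]):
        yr = youden_cutoff(values[hi_cls], values[lo_cls], direction=HIGHER)
        cutoffs.append(yr.cutoff)
    for i, (a, b) in enumerate(zip(cutoffs, cutoffs[1:])):
        if b <= a:
            raise ValidationError(
                f"non-monotone cutoffs for {element}: boundary "
                f"{ordered[i + 1].value}/{ordered[i + 2].value} ({b:.4g}) does not exceed "
                f"{ordered[i].value}/{ordered[i + 1].value} ({a:.4g})"
            )
    return MetricScale(element=element, ordered_classes=ordered, cutoffs=tuple(cutoffs))


def classify(value: float, scale: MetricScale) -> TissueClass:
    """Class of the half-open interval containing ``value`` (boundary -> upper)."""
    if value < 0:
        raise ValidationError(f"peak areas are nonnegative, got {value}")
    idx = int(np.searchsorted(np.asarray(scale.cutoffs), value, side="right"))
    return scale.ordered_classes[idx]
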