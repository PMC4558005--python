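"""Speed-stratum restructuring and ROC-based cut-point derivation.

The calibration question: which count thresholds best separate slow,
intermediate, and brisk walking?  The reference strata are defined from
the measured bout speeds themselves — the 75th percentile of
self-selected slow walking and the 25th percentile of self-selected
brisk walking form the LOW/HIGH speed boundaries, and every bout is
re-labelled by its measured speed regardless of the instructed
condition.  ROC analysis of bout mean counts against those strata then
yields the two cut points:

* low cut (LOW iff counts <= cut): selected to maximize sensitivity,
  so that slowly walking individuals are rarely missed;
* high cut (HIGH iff counts >= cut): selected to maximize specificity,
  preferring false negatives over false positives for brisk walking.

Both selections respect a floor (default 0.60) on the non-prioritized
metric so that neither rate collapses.  AUC is the Mann-Whitney win
probability with a Hanley-McNeil 95% confidence interval.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .epochs import Bout, Condition, Signal

__all__ = [
    "Stratum",
    "Direction",
    "Priority",
    "SpeedThresholds",
    "RocPoint",
    "RocSummary",
    "CutPointSet",
    "LabeledBout",
    "percentile",
    "restructure",
    "roc_points",
    "auc",
    "grade_auc",
    "AucGrade",
    "select_cut_point",
    "derive_cut_points",
]


class Stratum(enum.Enum):
    """Walking-speed stratum after percentile restructuring."""

    LOW = "low"
    MID = "mid"
    HIGH = "high"


class Direction(enum.Enum):
    """Positive-classification direction of a count threshold."""

    LE = "le"  # predicted positive iff score <= threshold
    GE = "ge"  # predicted positive iff score >= threshold


class Priority(enum.Enum):
    SENSITIVITY = "sensitivity"
    SPECIFICITY = "specificity"


class AucGrade(enum.Enum):
    EXCELLENT = "excellent"  # >= 0.90
    GOOD = "good"            # 0.80-0.89
    FAIR = "fair"            # 0.70-0.79
    POOR = "poor"            # < 0.70


@dataclass(frozen=True)
class SpeedThresholds:
    """Percentile-derived speed boundaries (m/s) defining the strata."""

    t_low_ms: float   # 75th percentile of slow-condition bout speeds
    t_high_ms: float  # 25th percentile of brisk-condition bout speeds

    def __post_init__(self) -> None:
        if not self.t_low_ms < self.t_high_ms:
            raise ValueError("strata collapse: t_low_ms >= t_high_ms")

    def classify_speed(self, speed_ms: float) -> Stratum:
        if speed_ms <= self.t_low_ms:
            return Stratum.LOW
        if speed_ms >= self.t_high_ms:
            return Stratum.HIGH
        return Stratum.MID


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")


@dataclass(frozen=True)
class RocSummary:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    points: tuple[RocPoint, ...]
    positive_direction: Direction

    def __post_init__(self) -> None:
        if not self.auc_ci_low <= self.auc <= self.auc_ci_high:
            raise ValueError("AUC must lie within its confidence interval")


@dataclass(frozen=True)
class CutPointSet:
    """Calibrated integer count thresholds for one signal.

    LOW iff counts <= low_cut; HIGH iff counts >= high_cut; the MID
    interval is [low_cut + 1, high_cut - 1].
    """

    signal: Signal
    low_cut: int
    high_cut: int
    low_roc: RocSummary
    high_roc: RocSummary
    low_point: RocPoint
    high_point: RocPoint

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise ValueError("degenerate calibration: low_cut >= high_cut")


@dataclass(frozen=True)
class LabeledBout:
    bout: Bout
    stratum: Stratum


def percentile(values: Sequence[float], p: float) -> float:
    """Weighted-average empirical percentile (the (n+1)p definition).

    With sorted x(1..n) and h = (n+1)p/100 the result interpolates
    between x(floor(h)) and the next order statistic, clamped to the
    observed range.  This is numpy's "weibull" method and the default of
    common menu-driven statistics software.
    """
    if len(values) == 0:
        raise ValueError("percentile of empty list")
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    return float(np.percentile(np.asarray(values, dtype=float), p, method="weibull"))


def restructure(bouts: Iterable[Bout]) -> tuple[SpeedThresholds, list[LabeledBout]]:
    """Label every bout LOW/MID/HIGH by its measured speed.

    Thresholds are the 75th percentile of slow-condition speeds and the
    25th percentile of brisk-condition speeds.  Labelling is by measured
    speed, not instructed condition: a normal-condition bout walked
    below the low threshold is LOW.
    """
    bouts = list(bouts)
    slow = [b.speed_ms for b in bouts if b.condition is Condition.SLOW]
    brisk = [b.speed_ms for b in bouts if b.condition is Condition.BRISK]
    if not slow or not brisk:
        raise ValueError("restructure requires at least one slow and one brisk bout")
    t_low = percentile(slow, 75)
    t_high = percentile(brisk, 25)
    if not t_low < t_high:
        raise ValueError("strata collapse: slow 75th percentile >= brisk 25th percentile")
    thresholds = SpeedThresholds(t_low_ms=t_low, t_high_ms=t_high)
    labeled = [LabeledBout(b, thresholds.classify_speed(b.speed_ms)) for b in bouts]
    return thresholds, labeled


def _confusion_rates(
    pos: np.ndarray, neg: np.ndarray, threshold: float, direction: Direction
) -> tuple[float, float]:
    if direction is Direction.LE:
        tp = int(np.sum(pos <= threshold))
        fp = int(np.sum(neg <= threshold))
    else:
        tp = int(np.sum(pos >= threshold))
        fp = int(np.sum(neg >= threshold))
    sens = tp / len(pos)
    spec = (len(neg) - fp) / len(neg)
    return sens, spec


def _split_classes(scores: Iterable[tuple[float, bool]]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s for s, is_pos in scores if is_pos], dtype=float)
    neg = np.array([s for s, is_pos in scores if not is_pos], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires both a positive and a negative class")
    return pos, neg


def roc_points(
    scores: Sequence[tuple[float, bool]], positive_direction: Direction
) -> list[RocPoint]:
    """One operating point per candidate threshold.

    Candidate thresholds are the midpoints between consecutive distinct
    observed scores, plus -inf and +inf sentinels, following the
    coordinates-of-the-curve convention of menu-driven ROC software:
    every achievable confusion table appears exactly once and the
    reported threshold sits mid-gap rather than on an observed score.
    """
    pos, neg = _split_classes(scores)
    distinct = sorted(set(np.concatenate([pos, neg]).tolist()))
    mids = [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
    thresholds = [-math.inf, *mids, math.inf]
    return [
        RocPoint(t, *_confusion_rates(pos, neg, t, positive_direction))
        for t in thresholds
    ]


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray, direction: Direction) -> float:
    # P(positive score beats negative score), ties counted 1/2.  For LE
    # a *smaller* score is the positive signal.
    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined)  # average ranks handle ties
    r_pos = float(np.sum(ranks[: len(pos)]))
    n1, n2 = len(pos), len(neg)
    a = (r_pos - n1 * (n1 + 1) / 2) / (n1 * n2)  # P(pos > neg) + ties/2
    return 1.0 - a if direction is Direction.LE else a


def _hanley_mcneil_ci(a: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return lo, hi


def auc(
    scores: Sequence[tuple[float, bool]], positive_direction: Direction
) -> RocSummary:
    """Mann-Whitney AUC with a Hanley-McNeil 95% CI, plus the full curve."""
    pos, neg = _split_classes(scores)
    a = _mann_whitney_auc(pos, neg, positive_direction)
    lo, hi = _hanley_mcneil_ci(a, len(pos), len(neg))
    return RocSummary(
        auc=a,
        auc_ci_low=min(lo, a),
        auc_ci_high=max(hi, a),
        points=tuple(roc_points(scores, positive_direction)),
        positive_direction=positive_direction,
    )


def grade_auc(value: float) -> AucGrade:
    """Conventional verbal AUC bands (excellent/good/fair/poor)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if value >= 0.90:
        return AucGrade.EXCELLENT
    if value >= 0.80:
        return AucGrade.GOOD
    if value >= 0.70:
        return AucGrade.FAIR
    return AucGrade.POOR


def select_cut_point(
    points: Sequence[RocPoint],
    priority: Priority,
    floor_other: float = 0.60,
    *,
    midpoint: float | None = None,
) -> RocPoint:
    """Deterministic stand-in for by-eye coordinate inspection.

    Among points whose non-priority metric is at least ``floor_other``,
    pick the one maximizing the priority metric; break ties by the
    non-priority metric, then by the threshold closest to ``midpoint``
    (the midpoint of the two class medians, when known), then by the
    smaller threshold.
    """
    if not points:
        raise ValueError("no ROC points")

    def prio(p: RocPoint) -> float:
        return p.sensitivity if priority is Priority.SENSITIVITY else p.specificity

    def other(p: RocPoint) -> float:
        return p.specificity if priority is Priority.SENSITIVITY else p.sensitivity

    admissible = [p for p in points if other(p) >= floor_other]
    if not admissible:
        best = max(points, key=other)
        raise ValueError(
            "no admissible threshold: no point reaches "
            f"{priority.value}-floor {floor_other}; best attainable pair is "
            f"sensitivity={best.sensitivity:.3f}, specificity={best.specificity:.3f} "
            f"at threshold {best.threshold}"
        )
    best_prio = max(prio(p) for p in admissible)
    tied = [p for p in admissible if prio(p) == best_prio]
    best_other = max(other(p) for p in tied)
    tied = [p for p in tied if other(p) == best_other]
    if midpoint is not None:
        dmin = min(abs(p.threshold - midpoint) for p in tied)
        tied = [p for p in tied if abs(p.threshold - midpoint) == dmin]
    return min(tied, key=lambda p: p.threshold)


def _class_midpoint(pos: Sequence[float], neg: Sequence[float]) -> float:
    return (median(pos) + median(neg)) / 2.0


def derive_cut_points(
    labeled: Sequence[LabeledBout],
    signal: Signal,
    *,
    floor_other: float = 0.60,
) -> CutPointSet:
    """ROC-calibrate the low and high count cuts on bout mean counts.

    The unit of analysis is the bout, scored by its mean counts/15 s on
    the chosen signal.  Low cut: LOW vs (MID u HIGH), direction LE,
    sensitivity prioritized.  High cut: HIGH vs (LOW u MID), direction
    GE, specificity prioritized.  Cuts are reported as integers — floor
    of the selected LE threshold, ceiling of the GE threshold — so the
    MID interval is the complementary [low_cut+1, high_cut-1].
    """
    by_stratum: dict[Stratum, list[float]] = {s: [] for s in Stratum}
    for lb in labeled:
        by_stratum[lb.stratum].append(lb.bout.mean_counts(signal))
    if any(len(v) == 0 for v in by_stratum.values()):
        raise ValueError("derive_cut_points requires all three strata non-empty")

    low_scores = [(c, True) for c in by_stratum[Stratum.LOW]] + [
        (c, False) for c in by_stratum[Stratum.MID] + by_stratum[Stratum.HIGH]
    ]
    high_scores = [(c, True) for c in by_stratum[Stratum.HIGH]] + [
        (c, False) for c in by_stratum[Stratum.LOW] + by_stratum[Stratum.MID]
    ]

    low_roc = auc(low_scores, Direction.LE)
    high_roc = auc(high_scores, Direction.GE)

    low_point = select_cut_point(
        low_roc.points,
        Priority.SENSITIVITY,
        floor_other,
        midpoint=_class_midpoint(
            by_stratum[Stratum.LOW], by_stratum[Stratum.MID] + by_stratum[Stratum.HIGH]
        ),
    )
    high_point = select_cut_point(
        high_roc.points,
        Priority.SPECIFICITY,
        floor_other,
        midpoint=_class_midpoint(
            by_stratum[Stratum.HIGH], by_stratum[Stratum.LOW] + by_stratum[Stratum.MID]
        ),
    )
    if not (math.isfinite(low_point.threshold) and math.isfinite(high_point.threshold)):
        raise ValueError("degenerate calibration: selected threshold is not finite")

    low_cut = math.floor(low_point.threshold)
    high_cut = math.ceil(high_point.threshold)
    if not low_cut < high_cut:
        raise ValueError("degenerate calibration: low_cut >= high_cut")
    return CutPointSet(
        signal=signal,
        low_cut=low_cut,
        high_cut=high_cut,
        low_roc=low_roc,
        high_roc=high_roc,
        low_point=low_point,
        high_point=high_point,
    )
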