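"""Leave-one-out cross-validation and chance-corrected agreement.

Each participant in turn is held out; cut points are re-derived on
everyone else's bouts and then applied to the held-out participant's
bout mean counts.  True (speed-defined) versus predicted (count-defined)
strata accumulate into a pooled 3x3 confusion matrix, summarized by
absolute agreement and quadratic weighted Cohen's kappa.  The quadratic
weighting discounts disagreement less when the categories are adjacent
(LOW vs MID) than when they are two apart (LOW vs HIGH), which suits
ordered speed strata.

The speed-stratum boundaries are computed once on the full sample and
held fixed across folds — the restructuring happens once, then the cut
points are cross-validated.  A strict mode recomputing the percentiles
per fold is available for sensitivity analysis.

The kappa confidence interval is a participant-level nonparametric
bootstrap (percentile method): bouts within a participant are dependent,
and resampling whole participants respects that clustering.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np

from .calibration import CutPointSet, Stratum, derive_cut_points, restructure
from .epochs import Bout, EpochRecord, Signal, attach_mean_counts

__all__ = [
    "KappaInterpretation",
    "AgreementResult",
    "LoocvResult",
    "classify_counts",
    "loocv",
    "absolute_agreement",
    "quadratic_weighted_kappa",
    "kappa_bootstrap_ci",
    "interpret_kappa",
    "evaluate_agreement",
]

logger = logging.getLogger(__name__)

_STRATA = (Stratum.LOW, Stratum.MID, Stratum.HIGH)
_INDEX = {s: i for i, s in enumerate(_STRATA)}


class KappaInterpretation(enum.Enum):
    """Landis-Koch verbal bands for kappa magnitude."""

    POOR = "poor"                    # < 0
    SLIGHT = "slight"                # 0.00-0.20
    FAIR = "fair"                    # 0.21-0.40
    MODERATE = "moderate"            # 0.41-0.60
    SUBSTANTIAL = "substantial"      # 0.61-0.80
    ALMOST_PERFECT = "almost perfect"  # 0.81-1.00


@dataclass(frozen=True)
class AgreementResult:
    """Pooled confusion matrix with agreement and kappa +- CI."""

    matrix: np.ndarray  # 3x3, rows true stratum, columns predicted
    absolute_agreement: float
    kappa: float
    kappa_ci_low: float
    kappa_ci_high: float
    interpretation: KappaInterpretation

    def __post_init__(self) -> None:
        if not self.kappa_ci_low <= self.kappa <= self.kappa_ci_high:
            raise ValueError("kappa must lie within its confidence interval")


@dataclass(frozen=True)
class LoocvResult:
    fold_cuts: dict[str, CutPointSet | None]  # None where the fold degenerated
    matrix: np.ndarray
    # (participant_id, true stratum, predicted stratum), one per classified bout
    pairs: tuple[tuple[str, Stratum, Stratum], ...]
    n_folds: int
    n_degenerate: int


def classify_counts(mean_counts: float, cuts: CutPointSet) -> Stratum:
    """Map bout mean counts/15 s to a stratum via the calibrated cuts."""
    if mean_counts < 0:
        raise ValueError("mean_counts must be >= 0")
    if mean_counts <= cuts.low_cut:
        return Stratum.LOW
    if mean_counts >= cuts.high_cut:
        return Stratum.HIGH
    return Stratum.MID


def _matrix_from_pairs(pairs) -> np.ndarray:
    m = np.zeros((3, 3), dtype=int)
    for _, true, pred in pairs:
        m[_INDEX[true], _INDEX[pred]] += 1
    return m


def loocv(
    bouts: list[Bout],
    epochs: list[EpochRecord],
    signal: Signal,
    *,
    floor_other: float = 0.60,
    trim_epochs: int = 0,
    refit_thresholds: bool = False,
) -> LoocvResult:
    """Leave-one-participant-out cross-validation of the calibration.

    One fold per participant.  Folds whose training calibration
    degenerates (crossed or non-finite cuts, empty stratum) are skipped
    with a warning and recorded; their bouts contribute nothing to the
    pooled matrix.
    """
    with_means = attach_mean_counts(bouts, epochs, trim_epochs=trim_epochs)
    participants = sorted({b.participant_id for b in with_means})
    if len(participants) < 3:
        raise ValueError("loocv requires at least 3 participants")

    thresholds, labeled = restructure(with_means)
    stratum_of = {
        (lb.bout.participant_id, lb.bout.condition): lb.stratum for lb in labeled
    }

    fold_cuts: dict[str, CutPointSet | None] = {}
    pairs: list[tuple[str, Stratum, Stratum]] = []
    n_degenerate = 0
    for pid in participants:
        train = [lb for lb in labeled if lb.bout.participant_id != pid]
        if refit_thresholds:
            try:
                _, train = restructure([lb.bout for lb in train])
            except ValueError as err:
                logger.warning("fold %s: threshold refit degenerated (%s); skipped", pid, err)
                fold_cuts[pid] = None
                n_degenerate += 1
                continue
        try:
            cuts = derive_cut_points(train, signal, floor_other=floor_other)
        except ValueError as err:
            logger.warning("fold %s: calibration degenerated (%s); skipped", pid, err)
            fold_cuts[pid] = None
            n_degenerate += 1
            continue
        fold_cuts[pid] = cuts
        for lb in labeled:
            if lb.bout.participant_id != pid:
                continue
            pred = classify_counts(lb.bout.mean_counts(signal), cuts)
            pairs.append((pid, lb.stratum, pred))

    return LoocvResult(
        fold_cuts=fold_cuts,
        matrix=_matrix_from_pairs(pairs),
        pairs=tuple(pairs),
        n_folds=len(participants),
        n_degenerate=n_degenerate,
    )


def absolute_agreement(matrix: np.ndarray) -> float:
    """Proportion of exact stratum matches: trace / total."""
    m = np.asarray(matrix)
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m) / total)


def _quadratic_weights(k: int) -> np.ndarray:
    i, j = np.indices((k, k))
    return 1.0 - (i - j) ** 2 / (k - 1) ** 2


def quadratic_weighted_kappa(matrix: np.ndarray) -> float:
    """Quadratic weighted Cohen's kappa for ordered categories.

    Weights w_ij = 1 - (i-j)^2/(k-1)^2; kappa = (p_o - p_e)/(1 - p_e)
    with p_o the observed weighted proportion and p_e its expectation
    under independent marginals.  Degenerate marginals (all mass in one
    cell) give kappa = 1 when observed agreement is perfect, else raise.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValueError("matrix must be square, k >= 2")
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p = m / total
    w = _quadratic_weights(m.shape[0])
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(p.sum(axis=1), p.sum(axis=0))).sum())
    if math.isclose(p_e, 1.0, abs_tol=1e-15):
        if math.isclose(p_o, 1.0, abs_tol=1e-15):
            return 1.0
        raise ValueError("degenerate marginals: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_bootstrap_ci(
    pairs,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Participant-level bootstrap percentile CI for the weighted kappa.

    Whole participants are resampled with replacement and their pooled
    (true, predicted) pairs re-scored; resamples with degenerate
    marginals and imperfect agreement are discarded.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    by_pid: dict[str, list] = {}
    for pid, true, pred in pairs:
        by_pid.setdefault(pid, []).append((pid, true, pred))
    pids = sorted(by_pid)
    if not pids:
        raise ValueError("no classified bouts")
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        sample = rng.choice(len(pids), size=len(pids), replace=True)
        resampled = [pair for idx in sample for pair in by_pid[pids[idx]]]
        try:
            stats.append(quadratic_weighted_kappa(_matrix_from_pairs(resampled)))
        except ValueError:
            continue
    if not stats:
        raise ValueError("all bootstrap resamples degenerated")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def interpret_kappa(kappa: float) -> KappaInterpretation:
    """Landis-Koch verbal interpretation of a kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0:
        return KappaInterpretation.POOR
    if kappa <= 0.20:
        return KappaInterpretation.SLIGHT
    if kappa <= 0.40:
        return KappaInterpretation.FAIR
    if kappa <= 0.60:
        return KappaInterpretation.MODERATE
    if kappa <= 0.80:
        return KappaInterpretation.SUBSTANTIAL
    return KappaInterpretation.ALMOST_PERFECT


def evaluate_agreement(
    result: LoocvResult,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Summarize a LOOCV run: agreement, kappa and its bootstrap CI.

    ``n_boot=0`` skips the bootstrap and reports a point-mass interval.
    The percentile interval is widened to contain the point estimate
    when an extreme bootstrap distribution would otherwise exclude it.
    """
    kappa = quadratic_weighted_kappa(result.matrix)
    if n_boot > 0:
        lo, hi = kappa_bootstrap_ci(result.pairs, n_boot=n_boot, seed=seed)
        lo, hi = min(lo, kappa), max(hi, kappa)
    else:
        lo = hi = kappa
    return AgreementResult(
        matrix=result.matrix.copy(),
        absolute_agreement=absolute_agreement(result.matrix),
        kappa=kappa,
        kappa_ci_low=lo,
        kappa_ci_high=hi,
        interpretation=interpret_kappa(kappa),
    )
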