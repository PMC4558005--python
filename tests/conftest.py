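"""Shared fixtures: synthetic cohorts and hand-built degenerate cohorts."""

from __future__ import annotations

import math

import pytest

from accelcal.calibration import CutPointSet, Direction, RocPoint, RocSummary
from accelcal.epochs import Bout, Condition, EpochRecord, Signal
from accelcal.synthetic import CohortConfig, generate_cohort

# Exact per-condition count levels for the degenerate noiseless cohort,
# chosen on the default linear model at the three condition mean speeds.
LEVELS_V = {Condition.SLOW: 272, Condition.NORMAL: 543, Condition.BRISK: 834}
LEVELS_VM = {Condition.SLOW: 433, Condition.NORMAL: 667, Condition.BRISK: 917}
SPEEDS = {Condition.SLOW: 0.89, Condition.NORMAL: 1.17, Condition.BRISK: 1.47}


def build_exact_level_cohort(
    n_participants: int = 10, n_epochs: int = 12
) -> tuple[list[Bout], list[EpochRecord]]:
    """Noiseless three-level cohort: within each condition every bout has
    the same exact speed and the same integer count level.

    Strata then coincide with conditions and all scores within a stratum
    tie exactly, so a correct calibration must recover them perfectly.
    """
    bouts, epochs = [], []
    for i in range(n_participants):
        pid = f"S{i + 1:02d}"
        for cond in Condition:
            speed = SPEEDS[cond]
            bouts.append(
                Bout(
                    participant_id=pid,
                    condition=cond,
                    distance_m=speed * 180.0,
                    duration_s=180.0,
                )
            )
            v = float(LEVELS_V[cond])
            vm = float(LEVELS_VM[cond])
            ap = ml = math.sqrt((vm * vm - v * v) / 2.0)
            for k in range(n_epochs):
                epochs.append(
                    EpochRecord(
                        participant_id=pid,
                        condition=cond,
                        epoch_index=k,
                        axis_v=v,
                        axis_ap=ap,
                        axis_ml=ml,
                    )
                )
    return bouts, epochs


def make_cuts(low: int, high: int, signal: Signal = Signal.V) -> CutPointSet:
    """CutPointSet with the given integer cuts and placeholder ROC summaries."""
    point = RocPoint(threshold=float(low), sensitivity=1.0, specificity=1.0)
    roc = lambda d: RocSummary(  # noqa: E731
        auc=1.0, auc_ci_low=1.0, auc_ci_high=1.0, points=(), positive_direction=d
    )
    return CutPointSet(
        signal=signal,
        low_cut=low,
        high_cut=high,
        low_roc=roc(Direction.LE),
        high_roc=roc(Direction.GE),
        low_point=point,
        high_point=point,
    )


@pytest.fixture(scope="session")
def exact_cohort():
    return build_exact_level_cohort(10)


@pytest.fixture(scope="session")
def cohort30():
    """Default-parameter cohort of 30 participants, fixed seed."""
    return generate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def cohort5():
    return generate_cohort(CohortConfig(n_participants=5, missing_bout_prob=0.0, seed=7))
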