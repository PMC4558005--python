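"""Percentile restructuring, ROC analysis, and cut-point selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accelcal.calibration import (
    AucGrade,
    CutPointSet,
    Direction,
    Priority,
    RocPoint,
    auc,
    derive_cut_points,
    grade_auc,
    percentile,
    restructure,
    roc_points,
    select_cut_point,
)
from accelcal.epochs import Bout, Condition, Signal, attach_mean_counts
from accelcal.synthetic import CohortConfig, default_count_params, generate_cohort
from accelcal.validation import classify_counts

from conftest import make_cuts


def select_oracle(points, priority, floor_other, midpoint=None):
    """Exhaustive-search restatement of the selection rule."""
    prio = (lambda p: p.sensitivity) if priority is Priority.SENSITIVITY else (
        lambda p: p.specificity
    )
    other = (lambda p: p.specificity) if priority is Priority.SENSITIVITY else (
        lambda p: p.sensitivity
    )
    admissible = [p for p in points if other(p) >= floor_other]
    if not admissible:
        raise ValueError("no admissible threshold")
    best = None
    for p in admissible:
        if best is None:
            best = p
            continue
        key_p = (prio(p), other(p))
        key_b = (prio(best), other(best))
        if key_p > key_b:
            best = p
        elif key_p == key_b:
            if midpoint is not None:
                dp, db = abs(p.threshold - midpoint), abs(best.threshold - midpoint)
                if dp < db or (dp == db and p.threshold < best.threshold):
                    best = p
            elif p.threshold < best.threshold:
                best = p
    return best


class TestPercentile:
    @pytest.mark.parametrize(
        "values, p, expected",
        [([1, 2, 3, 4], 50, 2.5), ([1, 2, 3, 4], 75, 3.75), ([5], 25, 5.0)],
    )
    def test_examples(self, values, p, expected):
        assert percentile(values, p) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile([], 50)

    @settings(derandomize=True, max_examples=100)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        p=st.floats(min_value=1, max_value=99),
    )
    def test_matches_hand_formula(self, values, p):
        # Weighted-average definition: h = (n+1)p/100, linear between
        # order statistics, clamped to the observed range.
        x = sorted(values)
        n = len(x)
        h = (n + 1) * p / 100
        if h <= 1:
            expected = x[0]
        elif h >= n:
            expected = x[-1]
        else:
            k = int(math.floor(h))
            expected = x[k - 1] + (h - k) * (x[k] - x[k - 1])
        assert percentile(values, p) == pytest.approx(expected, rel=1e-9, abs=1e-9)


def _bout(pid, cond, speed):
    return Bout(pid, cond, distance_m=speed * 180.0, duration_s=180.0)


class TestRestructure:
    def test_labels_follow_speed_not_condition(self):
        bouts = [
            _bout("a", Condition.SLOW, 0.8),
            _bout("a", Condition.NORMAL, 0.9),  # slower than the low threshold
            _bout("a", Condition.BRISK, 1.5),
            _bout("b", Condition.SLOW, 1.0),
            _bout("b", Condition.NORMAL, 1.2),
            _bout("b", Condition.BRISK, 1.4),
        ]
        thresholds, labeled = restructure(bouts)
        # slow speeds {0.8, 1.0}: 75th pct clamps to 1.0; brisk {1.4, 1.5}:
        # 25th pct clamps to 1.4
        assert thresholds.t_low_ms == pytest.approx(1.0)
        assert thresholds.t_high_ms == pytest.approx(1.4)
        by_key = {
            (lb.bout.participant_id, lb.bout.condition): lb.stratum for lb in labeled
        }
        assert by_key[("a", Condition.NORMAL)].value == "low"
        assert by_key[("b", Condition.NORMAL)].value == "mid"
        assert by_key[("b", Condition.BRISK)].value == "high"

    def test_boundary_speeds_inclusive(self):
        bouts = [
            _bout("a", Condition.SLOW, 1.0),
            _bout("b", Condition.SLOW, 1.0),
            _bout("a", Condition.NORMAL, 1.2),
            _bout("a", Condition.BRISK, 1.4),
            _bout("b", Condition.BRISK, 1.4),
        ]
        thresholds, labeled = restructure(bouts)
        strata = [lb.stratum.value for lb in labeled]
        assert strata == ["low", "low", "mid", "high", "high"]

    def test_order_invariance(self):
        triples = [(0.7, 1.1, 1.5), (0.95, 1.2, 1.35), (0.85, 1.0, 1.6)]
        bouts = [
            _bout(f"p{i}", cond, speed)
            for i, trio in enumerate(triples)
            for cond, speed in zip(Condition, trio)
        ]
        _, labeled_fwd = restructure(bouts)
        _, labeled_rev = restructure(list(reversed(bouts)))
        fwd = {(lb.bout.participant_id, lb.bout.condition): lb.stratum for lb in labeled_fwd}
        rev = {(lb.bout.participant_id, lb.bout.condition): lb.stratum for lb in labeled_rev}
        assert fwd == rev

    def test_strata_collapse_rejected(self):
        bouts = [
            _bout("a", Condition.SLOW, 1.5),
            _bout("a", Condition.BRISK, 1.0),
        ]
        with pytest.raises(ValueError, match="strata collapse"):
            restructure(bouts)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="slow and .* brisk"):
            restructure([_bout("a", Condition.SLOW, 0.9)])


class TestRocPoints:
    def test_separable_classes_reach_perfect_point(self):
        scores = [(1, True), (2, True), (5, False), (6, False)]
        points = roc_points(scores, Direction.LE)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in points)

    def test_interleaved_classes(self):
        # positives {1,5}, negatives {2,6}: the threshold just above 1
        # catches half the positives and no negatives
        points = roc_points([(1, True), (5, True), (2, False), (6, False)], Direction.LE)
        assert (0.5, 1.0) in {(p.sensitivity, p.specificity) for p in points}

    def test_sentinels_present(self):
        points = roc_points([(1, True), (2, False)], Direction.LE)
        assert points[0].threshold == -math.inf
        assert points[-1].threshold == math.inf
        assert (points[0].sensitivity, points[0].specificity) == (0.0, 1.0)
        assert (points[-1].sensitivity, points[-1].specificity) == (1.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([(1, True), (2, True)], Direction.LE)

    @settings(derandomize=True, max_examples=50)
    @given(
        pos=st.lists(st.integers(0, 100), min_size=1, max_size=15),
        neg=st.lists(st.integers(0, 100), min_size=1, max_size=15),
    )
    def test_le_curve_monotone_in_threshold(self, pos, neg):
        scores = [(s, True) for s in pos] + [(s, False) for s in neg]
        points = roc_points(scores, Direction.LE)  # sorted by threshold
        sens = [p.sensitivity for p in points]
        spec = [p.specificity for p in points]
        assert all(a <= b for a, b in zip(sens, sens[1:]))
        assert all(a >= b for a, b in zip(spec, spec[1:]))


class TestAuc:
    def test_separable(self):
        summary = auc([(1, True), (2, True), (5, False)], Direction.LE)
        assert summary.auc == 1.0

    def test_identical_distributions(self):
        scores = [(v, True) for v in (1, 2, 3)] + [(v, False) for v in (1, 2, 3)]
        assert auc(scores, Direction.LE).auc == pytest.approx(0.5)

    def test_pairwise_example(self):
        # positives {1,2,4}, negatives {3,5}, LE: 5 of 6 pairs won, no ties
        summary = auc(
            [(1, True), (2, True), (4, True), (3, False), (5, False)], Direction.LE
        )
        assert summary.auc == pytest.approx(5 / 6, abs=1e-12)

    def test_ci_brackets_estimate(self):
        summary = auc(
            [(1, True), (2, True), (4, True), (3, False), (5, False)], Direction.LE
        )
        assert summary.auc_ci_low <= summary.auc <= summary.auc_ci_high
        assert 0.0 <= summary.auc_ci_low and summary.auc_ci_high <= 1.0

    @settings(derandomize=True, max_examples=60)
    @given(
        pos=st.lists(st.integers(0, 30), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 30), min_size=1, max_size=12),
        direction=st.sampled_from([Direction.LE, Direction.GE]),
    )
    def test_matches_brute_force_pair_count(self, pos, neg, direction):
        scores = [(s, True) for s in pos] + [(s, False) for s in neg]
        wins = ties = 0
        for p, n in itertools.product(pos, neg):
            beats = p < n if direction is Direction.LE else p > n
            wins += beats
            ties += p == n
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auc(scores, direction).auc == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self):
        # independent library cross-check, GE direction = standard ROC AUC
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.integers(0, 50, size=rng.integers(2, 15))
            neg = rng.integers(0, 50, size=rng.integers(2, 15))
            scores = [(int(s), True) for s in pos] + [(int(s), False) for s in neg]
            y = [1] * len(pos) + [0] * len(neg)
            x = list(pos) + list(neg)
            assert auc(scores, Direction.GE).auc == pytest.approx(
                roc_auc_score(y, x), abs=1e-12
            )


class TestGradeAuc:
    @pytest.mark.parametrize(
        "value, grade",
        [
            (0.940, AucGrade.EXCELLENT),
            (0.90, AucGrade.EXCELLENT),
            (0.89, AucGrade.GOOD),
            (0.826, AucGrade.GOOD),
            (0.80, AucGrade.GOOD),
            (0.784, AucGrade.FAIR),
            (0.70, AucGrade.FAIR),
            (0.699, AucGrade.POOR),
            (0.5, AucGrade.POOR),
        ],
    )
    def test_bands(self, value, grade):
        assert grade_auc(value) is grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade_auc(1.2)


class TestSelectCutPoint:
    POINTS = [
        RocPoint(threshold=10, sensitivity=1.0, specificity=0.75),
        RocPoint(threshold=8, sensitivity=0.9, specificity=0.9),
    ]

    def test_sensitivity_priority(self):
        assert select_cut_point(self.POINTS, Priority.SENSITIVITY, 0.6).threshold == 10

    def test_specificity_priority(self):
        assert select_cut_point(self.POINTS, Priority.SPECIFICITY, 0.6).threshold == 8

    def test_floor_violation_reports_best_pair(self):
        points = [RocPoint(threshold=5, sensitivity=0.9, specificity=0.5)]
        with pytest.raises(ValueError, match="no admissible threshold"):
            select_cut_point(points, Priority.SENSITIVITY, 0.6)

    def test_invariant_to_data_duplication(self):
        scores = [(s, True) for s in (1, 4, 6)] + [(s, False) for s in (5, 8, 9)]
        for priority in Priority:
            chosen1 = select_cut_point(
                roc_points(scores, Direction.LE), priority, 0.5
            )
            chosen3 = select_cut_point(
                roc_points(scores * 3, Direction.LE), priority, 0.5
            )
            assert chosen1 == chosen3

    @settings(derandomize=True, max_examples=100)
    @given(
        pos=st.lists(st.integers(0, 40), min_size=2, max_size=12),
        neg=st.lists(st.integers(0, 40), min_size=2, max_size=12),
        priority=st.sampled_from(list(Priority)),
        use_midpoint=st.booleans(),
    )
    def test_matches_exhaustive_oracle(self, pos, neg, priority, use_midpoint):
        scores = [(s, True) for s in pos] + [(s, False) for s in neg]
        points = roc_points(scores, Direction.LE)
        midpoint = (np.median(pos) + np.median(neg)) / 2 if use_midpoint else None
        try:
            expected = select_oracle(points, priority, 0.6, midpoint)
        except ValueError:
            with pytest.raises(ValueError):
                select_cut_point(points, priority, 0.6, midpoint=midpoint)
            return
        assert select_cut_point(points, priority, 0.6, midpoint=midpoint) == expected


@pytest.fixture(scope="module")
def noiseless_cohort():
    cfg = CohortConfig(
        n_participants=12,
        count_model={s: default_count_params(s).scaled_noise(0.0) for s in Signal},
        missing_bout_prob=0.0,
        seed=21,
    )
    bouts, epochs = generate_cohort(cfg)
    return attach_mean_counts(bouts, epochs)


class TestDeriveCutPoints:
    @pytest.mark.parametrize("signal", [Signal.V, Signal.VM])
    def test_noiseless_cohort_separates_perfectly(self, noiseless_cohort, signal):
        # Zero count noise leaves counts monotone in speed, so the
        # speed-defined strata are perfectly separable in counts.
        _, labeled = restructure(noiseless_cohort)
        cuts = derive_cut_points(labeled, signal)
        assert cuts.low_point.sensitivity == 1.0
        assert cuts.low_point.specificity == 1.0
        assert cuts.high_point.sensitivity == 1.0
        assert cuts.high_point.specificity == 1.0
        # integer cuts reproduce the separating boundaries within one count
        low = sorted(
            lb.bout.mean_counts(signal) for lb in labeled if lb.stratum.value == "low"
        )
        rest = sorted(
            lb.bout.mean_counts(signal) for lb in labeled if lb.stratum.value != "low"
        )
        gap_mid = (low[-1] + rest[0]) / 2
        assert abs(cuts.low_cut - gap_mid) <= 1.0
        high = sorted(
            lb.bout.mean_counts(signal) for lb in labeled if lb.stratum.value == "high"
        )
        rest_h = sorted(
            lb.bout.mean_counts(signal) for lb in labeled if lb.stratum.value != "high"
        )
        assert abs(cuts.high_cut - (high[0] + rest_h[-1]) / 2) <= 1.0

    def test_cut_partition_is_exhaustive(self, noiseless_cohort):
        _, labeled = restructure(noiseless_cohort)
        cuts = derive_cut_points(labeled, Signal.V)
        for c in range(0, 2001):
            strata = [
                c <= cuts.low_cut,
                cuts.low_cut < c < cuts.high_cut,
                c >= cuts.high_cut,
            ]
            assert sum(strata) == 1
            assert classify_counts(c, cuts).value == ["low", "mid", "high"][
                strata.index(True)
            ]

    def test_crossed_cuts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_cuts(700, 300)

    def test_empty_stratum_rejected(self, noiseless_cohort):
        _, labeled = restructure(noiseless_cohort)
        no_low = [lb for lb in labeled if lb.stratum.value != "low"]
        with pytest.raises(ValueError, match="strata non-empty"):
            derive_cut_points(no_low, Signal.V)
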