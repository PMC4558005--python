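# Methods

## The calibration problem

Waist-worn activity monitors summarize movement as *counts*, an
arbitrary per-axis accumulation reported per epoch (15 s throughout this
package), either per axis or as the composite vector magnitude
VM = √(v² + ap² + ml²). Counts are device- and population-specific: a
shortened, shuffling gait produces a different count–speed relationship
than a healthy gait at the same speed, so thresholds calibrated on
healthy adults do not transfer to populations with altered gait. The
pipeline here calibrates count thresholds against *measured walking
speed* — a reference that is itself clinically meaningful (speeds below
≈1.0 m/s predict adverse outcomes in older adults) — using instructed
hallway bouts at self-selected slow, normal, and brisk paces.

## Procedure

1. **Bout speeds.** Each bout's speed is distance/duration (m/s), with
   km/h = 3.6 × m/s. Counts are aggregated to 15-s epochs (trailing
   partial epochs dropped; zero-padding would bias means downward), and
   each bout is scored by its mean counts per 15-s epoch. The bout, not
   the epoch, is the unit of analysis: bouts are the independent
   observations of the protocol, and per-epoch analysis would give
   within-bout replicates ~12× the weight of the design size.
2. **Restructuring.** Self-selected paces overlap between people, so
   instructed condition is not the reference. Strata are defined from
   the pooled bout speeds: t_low = 75th percentile of slow-condition
   speeds, t_high = 25th percentile of brisk-condition speeds; every
   bout is labelled LOW (speed ≤ t_low), HIGH (speed ≥ t_high), or MID
   by its *measured* speed, whatever the instruction was. Percentiles
   use the weighted-average (n+1)p definition (numpy's "weibull"
   method), the default of common menu-driven statistics software;
   alternative definitions change thresholds by at most one
   inter-observation gap at these sample sizes.
3. **ROC calibration.** Two binary problems per signal: LOW vs
   (MID ∪ HIGH) with "positive iff counts ≤ t", and HIGH vs (LOW ∪ MID)
   with "positive iff counts ≥ t". Candidate thresholds are the
   midpoints between consecutive distinct observed scores plus ±∞
   sentinels, so each achievable confusion table appears once and the
   reported threshold sits mid-gap. AUC is the Mann–Whitney win
   probability P(score_pos beats score_neg) with ties counted ½, which
   equals the trapezoidal area under the empirical curve; its 95% CI
   uses the closed-form Hanley–McNeil standard error, adequate at n ≈ 90
   bouts (DeLong would differ in the third decimal here and is not
   implemented). AUC is graded excellent (≥ 0.90), good (0.80–0.89),
   fair (0.70–0.79), poor (< 0.70).
4. **Cut-point selection.** By-eye inspection of curve coordinates is
   not reproducible, so selection is a deterministic rule with the same
   intent: among operating points whose *non*-prioritized metric is at
   least a floor (default 0.60), take the point maximizing the
   prioritized metric — sensitivity for the low cut (a slow walker
   should rarely be missed), specificity for the high cut (false
   negatives preferred over false positives for brisk walking). Ties
   are broken by the other metric, then by the threshold closest to the
   midpoint of the two class medians, then by the smaller threshold.
   Cuts are reported as integers — floor of the selected low threshold,
   ceiling of the high one — so the three intervals are complementary
   on integer counts: LOW ≤ low_cut, MID = [low_cut+1, high_cut−1],
   HIGH ≥ high_cut.
5. **Cross-validation.** Leave-one-participant-out: cut points are
   re-derived on the other participants' bouts and applied to the
   held-out participant's bout mean counts. Speed-stratum thresholds
   are computed once on the full sample and held fixed across folds
   (the restructuring is part of the reference definition, not of the
   classifier); `refit_thresholds=True` recomputes them per fold for
   sensitivity analysis. Folds whose training calibration degenerates
   (crossed cuts, empty stratum, no admissible threshold) are skipped
   with a warning and counted. True-vs-predicted strata pool into a 3×3
   matrix summarized by absolute agreement (trace/total) and quadratic
   weighted Cohen's κ: weights w_ij = 1 − (i−j)²/(k−1)²,
   κ = (p_o − p_e)/(1 − p_e), so a LOW↔MID confusion costs a quarter of
   a LOW↔HIGH confusion — appropriate for ordered strata. κ is read on
   the Landis–Koch bands (0.61–0.80 "substantial", etc.).
6. **Kappa CI.** Bouts within a participant share a random intercept
   and are not independent, so the κ interval is a participant-level
   nonparametric bootstrap (resample whole participants with
   replacement, default B = 2000, seeded; percentile interval).
   Degenerate resamples (expected agreement 1 without perfect observed
   agreement) are discarded; the percentile interval is widened, if
   necessary, to contain the point estimate so the reported triple is
   always internally consistent.

## Synthetic cohorts

No raw monitor data ships with the package; `accelcal.synthetic`
generates cohorts with the statistical structure the analysis assumes,
parameterized from published stratum summaries:

* **Speeds.** One bout per condition per participant; speeds are normal
  with means 0.89 / 1.17 / 1.47 m/s and SDs 0.11 / 0.08 / 0.14
  (slow/normal/brisk), floored at 0.3 m/s. Half the speed variance is a
  shared per-participant "pace" shift, so slow < normal < brisk is
  violated only occasionally — and violations are kept, because the
  restructuring step exists precisely to relabel them.
* **Geometry.** Each bout covers the smallest whole number of 210-m
  hallway laps lasting ≥ 180 s at its speed, yielding ≥ 12 complete
  15-s epochs.
* **Counts.** E[counts] = intercept + slope·speed per signal, the
  least-squares line through the three published stratum (mean speed,
  mean count) points: vertical axis slope 968.86 counts/15 s per m/s,
  intercept −590.36; VM slope 833.76, intercept −308.72. Stratum count
  variance is split 50/50 between a participant random intercept and
  within-bout epoch noise (participant_sd = epoch_sd = pooled stratum
  SD/√2: 122.7 for the vertical axis, 151.5 for VM; the 50/50 split is
  arbitrary, undocumented in the source summaries, and configurable).
  Counts are rectified at zero after noise, as count registers are.
  The horizontal axes carry the residual √((VM² − V²)/2) each, so epoch
  records satisfy the VM identity by construction.
* **Missingness.** Each bout is independently dropped with probability
  0.02 (one or two bouts per 90-bout cohort, matching a protocol in
  which an occasional bout is not completed).

What the generator does **not** emulate: integer count registers (it
emits real-valued counts), tremor/freezing/dyskinesia artifacts,
within-bout pace drift or gait initiation/termination transients,
heteroscedastic noise, device filtering, or non-wear. Passing tests
therefore show that the *statistical pipeline* behaves correctly on
data with the assumed count–speed structure — not that any particular
cut points transfer to real recordings.

## Numerical and degenerate-input choices

* Rounding for display is half-up at the printed precision (2 decimals
  for speeds, integers for cuts); JSON outputs keep full precision, and
  every output embeds the config hash, seed, and package version, so
  reruns are byte-identical.
* Speed thresholds must satisfy t_low < t_high, else "strata collapse";
  crossed integer cuts raise "degenerate calibration"; selection with
  no point above the floor raises "no admissible threshold" and reports
  the best attainable sensitivity/specificity pair.
* κ with all mass in one diagonal cell is 1 by continuity; all mass in
  one off-diagonal cell gives p_o = p_e = w_ij and hence κ = 0.
* CSV reading uses round-trip float parsing so written cohorts reload
  bit-identically.

## Problem sizes used by the test suite

The suite exercises the pipeline at the design's own scale: cohorts of
5–30 participants (plus one 200-participant cohort for checking the
generator's stratified moments at 10% tolerance), 200-instance oracle
sweeps for the AUC and selection rules, and a recovery experiment of 50
seeded replicates × three noise scales (0.25/0.5/1.0 × the default
noise SDs) of full leave-one-out runs at n = 30 with the bootstrap
disabled (the CI is irrelevant to the recovery claim). The noiseless
recovery case uses a hand-built cohort with exact per-condition speeds
and integer count levels: the generator's config requires positive
speed SDs, and any within-condition speed variation lets the held-out
boundary bout fall beyond the training fold's mid-gap cut with
probability ≈ ½ per boundary — an order-statistics fact about the
method, not an implementation artifact — so exact LOOCV perfection is
only guaranteed when within-stratum scores tie exactly.

## Known limitations

* The noise-recovery experiment shows κ ≥ 0.9 in most but not all
  quarter-noise replicates (median ≈ 0.92): the percentile-defined
  stratum boundaries sit in the dense body of the speed distribution,
  so a handful of boundary bouts per cohort are one noise-SD from the
  count boundary, and the deliberately asymmetric selection rules
  (maximal sensitivity low, maximal specificity high) place cuts at
  corners rather than balanced-error points.
* The Hanley–McNeil CI assumes a smooth underlying score distribution;
  with heavy ties it is conservative.
* Calibration quality is reported for the simulated design only; real
  deployments must recalibrate or validate against their own device,
  epoch length, and population.
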