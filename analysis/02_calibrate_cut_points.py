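#!/usr/bin/env python
"""Restructure the cohort into speed strata and calibrate count cut points.

Reads the simulated cohort, labels every bout LOW/MID/HIGH by measured
speed (75th percentile of slow-condition speeds, 25th percentile of
brisk-condition speeds), summarizes the strata, and derives the
vertical-axis and vector-magnitude cut points by ROC analysis.
"""

import json
from pathlib import Path

from accelcal.calibration import derive_cut_points, grade_auc, restructure
from accelcal.epochs import Signal, attach_mean_counts, read_bout_csv, read_epoch_csv
from accelcal.report import cuts_to_dict, summarize_strata

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    bouts = read_bout_csv(COHORT / "bouts.csv")
    epochs = read_epoch_csv(COHORT / "epochs.csv")
    with_means = attach_mean_counts(bouts, epochs)
    thresholds, labeled = restructure(with_means)
    print(f"speed thresholds: low <= {thresholds.t_low_ms:.2f} m/s, "
          f"high >= {thresholds.t_high_ms:.2f} m/s")

    strata = summarize_strata(labeled)
    strata.to_csv(ROOT / "stratum_summary.csv", index=False)
    for row in strata.itertuples(index=False):
        print(f"  {row.stratum:>4}: n={row.n:3d}  V {row.counts_v_mean:6.0f} ± "
              f"{row.counts_v_sd:5.0f}  speed {row.speed_ms_mean:.2f} ± "
              f"{row.speed_ms_sd:.2f} m/s")

    for signal, tag in ((Signal.V, "vertical axis"), (Signal.VM, "vector magnitude")):
        cuts = derive_cut_points(labeled, signal)
        payload = {
            "speed_thresholds": {
                "t_low_ms": thresholds.t_low_ms, "t_high_ms": thresholds.t_high_ms,
            },
            "cut_points": cuts_to_dict(cuts),
        }
        path = ROOT / f"calibration_{signal.value}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        print(f"{tag}: LOW <= {cuts.low_cut}, HIGH >= {cuts.high_cut} counts/15 s "
              f"(low AUC {cuts.low_roc.auc:.3f} {grade_auc(cuts.low_roc.auc).value}, "
              f"high AUC {cuts.high_roc.auc:.3f} {grade_auc(cuts.high_roc.auc).value})")


if __name__ == "__main__":
    main()
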