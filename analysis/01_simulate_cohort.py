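#!/usr/bin/env python
"""Simulate the calibration cohort.

Draws the default synthetic cohort — 30 participants, one slow, one
normal, and one brisk hallway bout each, triaxial counts per 15-s epoch
with the published count-speed structure — and writes the epoch and bout
CSVs that the rest of the analysis consumes.
"""

from pathlib import Path

from accelcal.epochs import write_bout_csv, write_epoch_csv
from accelcal.synthetic import CohortConfig, config_to_json, generate_cohort

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED)
    bouts, epochs = generate_cohort(config)
    write_epoch_csv(epochs, OUT / "epochs.csv")
    write_bout_csv(bouts, OUT / "bouts.csv")
    (OUT / "config.json").write_text(config_to_json(config) + "\n")

    n_participants = len({b.participant_id for b in bouts})
    print(f"simulated cohort (seed {SEED}): {n_participants} participants, "
          f"{len(bouts)} bouts ({3 * n_participants - len(bouts)} missing), "
          f"{len(epochs)} epochs of 15 s")
    print(f"wrote {OUT / 'epochs.csv'} and {OUT / 'bouts.csv'}")


if __name__ == "__main__":
    main()
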