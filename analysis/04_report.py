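#!/usr/bin/env python
"""Assemble the full report bundle for the simulated cohort.

Runs the end-to-end pipeline (same seed as the upstream scripts) and
writes report.md plus the per-signal calibration and validation JSONs
under results/report/.
"""

from pathlib import Path

from accelcal.report import RunConfig, run_pipeline
from accelcal.synthetic import CohortConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "report"
    run_pipeline(
        RunConfig(out_dir=out, sim_config=CohortConfig(seed=SEED), n_boot=2000, seed=SEED)
    )
    print(f"report bundle written to {out}")
    print((out / "report.md").read_text())


if __name__ == "__main__":
    main()
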