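"""End-to-end pipeline orchestration and report generation.

``run_pipeline`` glues the stages together — simulate (or load) a
cohort, restructure by speed percentiles, calibrate cut points per
signal, cross-validate — and writes machine-readable JSON plus a
human-readable markdown report.  Every output embeds the config hash,
the seed, and the package version so reruns are attributable and
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CutPointSet,
    LabeledBout,
    RocSummary,
    SpeedThresholds,
    Stratum,
    derive_cut_points,
    grade_auc,
    restructure,
)
from .epochs import (
    Bout,
    EpochRecord,
    Signal,
    attach_mean_counts,
    read_bout_csv,
    read_epoch_csv,
    round_half_up,
)
from .synthetic import CohortConfig, config_from_json, config_to_json, generate_cohort
from .validation import AgreementResult, evaluate_agreement, loocv

__all__ = ["RunConfig", "run_pipeline", "summarize_strata"]

logger = logging.getLogger(__name__)

_STRATA = (Stratum.LOW, Stratum.MID, Stratum.HIGH)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input source, one output directory."""

    out_dir: Path
    epochs_csv: Path | None = None
    bouts_csv: Path | None = None
    sim_config: CohortConfig | None = None
    signals: tuple[Signal, ...] = (Signal.V, Signal.VM)
    floor_other: float = 0.60
    trim_epochs: int = 0
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.epochs_csv is not None and self.bouts_csv is not None
        have_sim = self.sim_config is not None
        if have_files == have_sim:
            raise ValueError(
                "exactly one of (epochs_csv + bouts_csv) or sim_config must be given"
            )
        if (self.epochs_csv is None) != (self.bouts_csv is None):
            raise ValueError("epochs_csv and bouts_csv must be given together")
        if not self.signals:
            raise ValueError("at least one signal required")
        if not 0.0 <= self.floor_other <= 1.0:
            raise ValueError("floor_other must be in [0, 1]")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")

    def canonical(self) -> str:
        payload = {
            "epochs_csv": str(self.epochs_csv) if self.epochs_csv else None,
            "bouts_csv": str(self.bouts_csv) if self.bouts_csv else None,
            "sim_config": json.loads(config_to_json(self.sim_config))
            if self.sim_config
            else None,
            "signals": [s.value for s in self.signals],
            "floor_other": self.floor_other,
            "trim_epochs": self.trim_epochs,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def summarize_strata(labeled: list[LabeledBout]) -> pd.DataFrame:
    """Per-stratum descriptive table: n, counts and speed as mean +- SD.

    SDs use the n-1 denominator and are NaN for strata with fewer than
    two bouts; an empty stratum still gets a row with n=0.
    """
    if not labeled:
        raise ValueError("no labeled bouts")
    rows = []
    for stratum in _STRATA:
        sub = [lb.bout for lb in labeled if lb.stratum is stratum]
        row: dict = {"stratum": stratum.value, "n": len(sub)}
        series = {
            "counts_v": [b.mean_counts(Signal.V) for b in sub],
            "counts_vm": [b.mean_counts(Signal.VM) for b in sub],
            "speed_kmh": [b.speed_kmh for b in sub],
            "speed_ms": [b.speed_ms for b in sub],
        }
        for name, vals in series.items():
            arr = np.asarray(vals, dtype=float)
            row[f"{name}_mean"] = float(arr.mean()) if len(arr) else float("nan")
            row[f"{name}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# --- JSON serialization -----------------------------------------------------

def _roc_to_dict(roc: RocSummary) -> dict:
    return {
        "auc": roc.auc,
        "auc_ci_low": roc.auc_ci_low,
        "auc_ci_high": roc.auc_ci_high,
        "auc_grade": grade_auc(roc.auc).value,
        "positive_direction": roc.positive_direction.value,
        "points": [
            {"threshold": p.threshold, "sensitivity": p.sensitivity, "specificity": p.specificity}
            for p in roc.points
        ],
    }


def cuts_to_dict(cuts: CutPointSet) -> dict:
    return {
        "signal": cuts.signal.value,
        "low_cut": cuts.low_cut,
        "high_cut": cuts.high_cut,
        "low": {
            "sensitivity": cuts.low_point.sensitivity,
            "specificity": cuts.low_point.specificity,
            "roc": _roc_to_dict(cuts.low_roc),
        },
        "high": {
            "sensitivity": cuts.high_point.sensitivity,
            "specificity": cuts.high_point.specificity,
            "roc": _roc_to_dict(cuts.high_roc),
        },
    }


def _agreement_to_dict(ag: AgreementResult) -> dict:
    return {
        "matrix": ag.matrix.tolist(),
        "matrix_order": [s.value for s in _STRATA],
        "absolute_agreement": ag.absolute_agreement,
        "kappa": ag.kappa,
        "kappa_ci_low": ag.kappa_ci_low,
        "kappa_ci_high": ag.kappa_ci_high,
        "interpretation": ag.interpretation.value,
    }


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _fmt2(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"


def _report_md(
    config: RunConfig,
    thresholds: SpeedThresholds,
    strata_df: pd.DataFrame,
    results: dict[Signal, tuple[CutPointSet, AgreementResult, "object"]],
) -> str:
    lines = [
        "# Walking-speed cut-point calibration report",
        "",
        f"- version: {__version__}",
        f"- config hash: {config.config_hash()}",
        f"- seed: {config.seed}",
        "",
        "## Speed thresholds",
        "",
        f"- low (75th pct of slow bouts): {_fmt2(thresholds.t_low_ms)} m/s"
        f" ({_fmt2(thresholds.t_low_ms * 3.6)} km/h)",
        f"- high (25th pct of brisk bouts): {_fmt2(thresholds.t_high_ms)} m/s"
        f" ({_fmt2(thresholds.t_high_ms * 3.6)} km/h)",
        "",
        "## Stratum summary",
        "",
        "| stratum | n | V counts/15 s | VM counts/15 s | speed (km/h) | speed (m/s) |",
        "|---|---|---|---|---|---|",
    ]
    for row in strata_df.itertuples(index=False):
        def ms(mean, sd):
            if row.n == 0 or np.isnan(mean):
                return "-"
            if np.isnan(sd):
                return f"{_fmt2(mean)} (SD undefined, n<2)"
            return f"{_fmt2(mean)} ± {_fmt2(sd)}"

        lines.append(
            f"| {row.stratum} | {row.n} "
            f"| {ms(row.counts_v_mean, row.counts_v_sd)} "
            f"| {ms(row.counts_vm_mean, row.counts_vm_sd)} "
            f"| {ms(row.speed_kmh_mean, row.speed_kmh_sd)} "
            f"| {ms(row.speed_ms_mean, row.speed_ms_sd)} |"
        )
    for signal, (cuts, agreement, lres) in results.items():
        name = "vertical axis" if signal is Signal.V else "vector magnitude"
        lines += [
            "",
            f"## Cut points — {name}",
            "",
            "| stratum | cut (counts/15 s) | sensitivity (%) | specificity (%) | AUC (95% CI) | grade |",
            "|---|---|---|---|---|---|",
        ]
        for label, cut_str, point, roc in (
            ("LOW", f"≤ {cuts.low_cut}", cuts.low_point, cuts.low_roc),
            ("HIGH", f"≥ {cuts.high_cut}", cuts.high_point, cuts.high_roc),
        ):
            lines.append(
                f"| {label} | {cut_str} "
                f"| {round_half_up(point.sensitivity * 100, 0):.0f} "
                f"| {round_half_up(point.specificity * 100, 0):.0f} "
                f"| {round_half_up(roc.auc, 3):.3f} "
                f"({round_half_up(roc.auc_ci_low, 3):.3f}–{round_half_up(roc.auc_ci_high, 3):.3f}) "
                f"| {grade_auc(roc.auc).value} |"
            )
        lines += [
            f"| MID | {cuts.low_cut + 1}–{cuts.high_cut - 1} | | | | |",
            "",
            f"## Cross-validation — {name}",
            "",
            f"- folds: {lres.n_folds} attempted, {lres.n_degenerate} degenerate/skipped",
            f"- absolute agreement: {round_half_up(agreement.absolute_agreement * 100, 0):.0f}%",
            f"- quadratic weighted κ: {round_half_up(agreement.kappa, 2):.2f} "
            f"(95% CI {round_half_up(agreement.kappa_ci_low, 2):.2f}–"
            f"{round_half_up(agreement.kappa_ci_high, 2):.2f}), "
            f"{agreement.interpretation.value} agreement",
        ]
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> calibrate -> validate and write the bundle.

    Writes ``calib_<signal>.json``, ``validation_<signal>.json`` and
    ``report.md`` into ``config.out_dir`` and returns the in-memory
    results keyed by signal.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim_config is not None:
        bouts, epochs = generate_cohort(config.sim_config)
        (out / "cohort_config.json").write_text(config_to_json(config.sim_config) + "\n")
    else:
        bouts = read_bout_csv(config.bouts_csv)
        epochs = read_epoch_csv(config.epochs_csv)
    logger.info("cohort: %d bouts, %d epochs", len(bouts), len(epochs))

    with_means = attach_mean_counts(bouts, epochs, trim_epochs=config.trim_epochs)
    thresholds, labeled = restructure(with_means)
    strata_df = summarize_strata(labeled)

    results: dict[Signal, tuple] = {}
    for signal in config.signals:
        cuts = derive_cut_points(labeled, signal, floor_other=config.floor_other)
        lres = loocv(
            bouts,
            epochs,
            signal,
            floor_other=config.floor_other,
            trim_epochs=config.trim_epochs,
        )
        agreement = evaluate_agreement(lres, n_boot=config.n_boot, seed=config.seed)
        results[signal] = (cuts, agreement, lres)

        prov = _provenance(config)
        _write_json(
            out / f"calib_{signal.value}.json",
            {
                **prov,
                "speed_thresholds": {
                    "t_low_ms": thresholds.t_low_ms,
                    "t_high_ms": thresholds.t_high_ms,
                },
                "cut_points": cuts_to_dict(cuts),
            },
        )
        _write_json(
            out / f"validation_{signal.value}.json",
            {
                **prov,
                "n_folds": lres.n_folds,
                "n_degenerate": lres.n_degenerate,
                "fold_cuts": {
                    pid: None if c is None else {"low_cut": c.low_cut, "high_cut": c.high_cut}
                    for pid, c in lres.fold_cuts.items()
                },
                "agreement": _agreement_to_dict(agreement),
            },
        )

    (out / "report.md").write_text(_report_md(config, thresholds, strata_df, results))
    return {
        "thresholds": thresholds,
        "strata": strata_df,
        "results": results,
    }
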