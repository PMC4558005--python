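"""Synthetic walking-bout cohorts with the count-speed structure the
calibration assumes.

The generator emulates a hallway calibration protocol: each of
``n_participants`` walks one bout per instructed condition (slow,
normal, brisk) around a 210-m circuit for at least three minutes, and a
waist-worn monitor accumulates triaxial counts per 15-s epoch.  The
emulated structure, not a claim about device physics:

* per-condition walking speeds are normal with the observed stratum
  means/SDs (defaults 0.89/1.17/1.47 +- 0.11/0.08/0.14 m/s), sharing a
  participant "pace" shift so slow < normal < brisk is only rarely
  violated — and violations are kept, because the percentile
  restructuring step exists precisely to relabel them;
* expected counts rise linearly with speed.  Default intercept/slope
  come from the least-squares line through the three published stratum
  (speed, count) means; the stratum count variance is split 50/50
  between a participant random intercept and within-bout epoch noise;
* counts are rectified at zero after noise, as count registers are.

All randomness flows from the config seed; a config maps to exactly one
cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import Bout, Condition, EpochRecord, Signal

__all__ = [
    "CountModelParams",
    "CohortConfig",
    "fit_count_line",
    "default_count_params",
    "generate_cohort",
    "config_from_json",
    "config_to_json",
]


def fit_count_line(
    speeds_ms: "list[float] | np.ndarray", mean_counts: "list[float] | np.ndarray"
) -> tuple[float, float]:
    """Least-squares line through (speed, mean counts) points.

    Returns (intercept, slope).  This is how the default count models
    are derived from published stratum means; a signal with equal means
    at all speeds fits slope 0.
    """
    x = np.asarray(speeds_ms, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two (speed, counts) points")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)

_HALLWAY_M = 210.0
_BOUT_MIN_S = 180.0
_EPOCH_S = 15.0
_SPEED_FLOOR_MS = 0.3
# Share of speed variance carried by the shared participant pace shift.
_PACE_SHARE = 0.5

# Least-squares line through the three published stratum (mean speed,
# mean counts) points, and the pooled stratum SD split 50/50 by variance
# between participant and epoch noise.  Frozen; recomputed in tests.
_DEFAULTS = {
    Signal.V: dict(intercept=-590.357369, slope=968.858954, sd=122.695422),
    Signal.VM: dict(intercept=-308.719493, slope=833.755943, sd=151.492574),
}


@dataclass(frozen=True)
class CountModelParams:
    """Linear mean model for one count signal: E[counts] = a + b*speed."""

    intercept: float  # counts/15 s at zero speed (extrapolated; may be < 0)
    slope: float      # counts/15 s per m/s
    participant_sd: float  # between-participant random-intercept SD
    epoch_sd: float        # within-bout epoch noise SD

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.participant_sd < 0 or self.epoch_sd < 0:
            raise ValueError("SDs must be >= 0")

    def scaled_noise(self, factor: float) -> "CountModelParams":
        """Same mean model with both noise SDs scaled by ``factor``."""
        return replace(
            self,
            participant_sd=self.participant_sd * factor,
            epoch_sd=self.epoch_sd * factor,
        )


def default_count_params(signal: Signal) -> CountModelParams:
    """Default count model for the vertical axis or vector magnitude."""
    d = _DEFAULTS[signal]
    return CountModelParams(
        intercept=d["intercept"],
        slope=d["slope"],
        participant_sd=d["sd"],
        epoch_sd=d["sd"],
    )


def _default_count_model() -> dict[Signal, CountModelParams]:
    return {s: default_count_params(s) for s in (Signal.V, Signal.VM)}


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 30
    speed_means_ms: tuple[float, float, float] = (0.89, 1.17, 1.47)  # slow/normal/brisk
    speed_sds_ms: tuple[float, float, float] = (0.11, 0.08, 0.14)
    count_model: dict[Signal, CountModelParams] = field(default_factory=_default_count_model)
    missing_bout_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(sd <= 0 for sd in self.speed_sds_ms):
            raise ValueError("speed SDs must be > 0")
        if not 0.0 <= self.missing_bout_prob <= 1.0:
            raise ValueError("missing_bout_prob must be in [0, 1]")
        if set(self.count_model) != {Signal.V, Signal.VM}:
            raise ValueError("count_model must provide params for both V and VM")

    def scaled_noise(self, factor: float) -> "CohortConfig":
        return replace(
            self,
            count_model={s: p.scaled_noise(factor) for s, p in self.count_model.items()},
        )


def generate_cohort(config: CohortConfig) -> tuple[list[Bout], list[EpochRecord]]:
    """Draw one synthetic cohort of bouts and their 15-s epochs.

    Per participant and condition: a speed is drawn from the condition's
    normal distribution (floored at 0.3 m/s), the bout covers the
    smallest whole number of 210-m laps lasting >= 180 s at that speed
    (hence >= 12 complete epochs), and each epoch's counts are
    ``max(0, intercept + slope*speed + participant_effect + noise)`` per
    signal.  Each bout is independently dropped with
    ``missing_bout_prob``.  Fully reproducible from the config seed.
    """
    rng = np.random.default_rng(config.seed)
    conditions = (Condition.SLOW, Condition.NORMAL, Condition.BRISK)
    pv = config.count_model[Signal.V]
    pvm = config.count_model[Signal.VM]
    a = math.sqrt(_PACE_SHARE)
    b = math.sqrt(1.0 - _PACE_SHARE)

    bouts: list[Bout] = []
    epochs: list[EpochRecord] = []
    width = max(2, len(str(config.n_participants)))
    for i in range(config.n_participants):
        pid = f"P{i + 1:0{width}d}"
        pace_z = rng.standard_normal()
        effect_z = rng.standard_normal()  # shared mover-level count effect
        u_v = effect_z * pv.participant_sd
        u_vm = effect_z * pvm.participant_sd
        for ci, cond in enumerate(conditions):
            z = rng.standard_normal()
            speed = config.speed_means_ms[ci] + config.speed_sds_ms[ci] * (
                a * pace_z + b * z
            )
            speed = max(speed, _SPEED_FLOOR_MS)
            dropped = rng.random() < config.missing_bout_prob
            n_laps = max(1, math.ceil(speed * _BOUT_MIN_S / _HALLWAY_M))
            distance = n_laps * _HALLWAY_M
            duration = distance / speed
            n_epochs = int(duration // _EPOCH_S)
            ev = rng.standard_normal(n_epochs) * pv.epoch_sd
            evm = rng.standard_normal(n_epochs) * pvm.epoch_sd
            if dropped:
                continue
            bouts.append(
                Bout(
                    participant_id=pid,
                    condition=cond,
                    distance_m=distance,
                    duration_s=duration,
                )
            )
            for k in range(n_epochs):
                v = max(0.0, pv.intercept + pv.slope * speed + u_v + ev[k])
                vm_target = max(0.0, pvm.intercept + pvm.slope * speed + u_vm + evm[k])
                # Split the VM residual evenly over the horizontal axes;
                # if noise drives VM below the vertical axis, the
                # horizontal axes are zero and VM equals the vertical.
                residual = max(vm_target * vm_target - v * v, 0.0)
                ap = ml = math.sqrt(residual / 2.0)
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


# --- JSON config ------------------------------------------------------------

def config_to_json(config: CohortConfig) -> str:
    payload = {
        "n_participants": config.n_participants,
        "speed_means_ms": list(config.speed_means_ms),
        "speed_sds_ms": list(config.speed_sds_ms),
        "count_model": {
            s.value: {
                "intercept": p.intercept,
                "slope": p.slope,
                "participant_sd": p.participant_sd,
                "epoch_sd": p.epoch_sd,
            }
            for s, p in sorted(config.count_model.items(), key=lambda kv: kv[0].value)
        },
        "missing_bout_prob": config.missing_bout_prob,
        "seed": config.seed,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def config_from_json(text: str) -> CohortConfig:
    raw = json.loads(text)
    kwargs = {}
    for key in ("n_participants", "missing_bout_prob", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("speed_means_ms", "speed_sds_ms"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "count_model" in raw:
        kwargs["count_model"] = {
            Signal(sig): CountModelParams(**params)
            for sig, params in raw["count_model"].items()
        }
    return CohortConfig(**kwargs)
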