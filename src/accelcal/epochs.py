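"""Epoch-level count handling and bout walking speeds.

Waist-worn activity monitors report movement as *counts*, an arbitrary
per-axis accumulation, which analysis software summarizes over fixed
epochs (15 s here).  This module holds the two core records of the
calibration pipeline — a 15-s triaxial epoch and an instructed walking
bout — together with the arithmetic that connects them: epoch
aggregation from per-second counts, the composite vector magnitude, and
walking-speed unit conversions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Condition",
    "Signal",
    "EpochRecord",
    "Bout",
    "aggregate_epochs",
    "vector_magnitude",
    "compute_speed",
    "kmh_to_ms",
    "round_half_up",
    "attach_mean_counts",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_bout_csv",
    "write_bout_csv",
]

DEFAULT_EPOCH_LENGTH_S = 15


class Condition(enum.Enum):
    """Instructed walking condition (self-selected pace)."""

    SLOW = "slow"
    NORMAL = "normal"
    BRISK = "brisk"


class Signal(enum.Enum):
    """Count channel used for calibration: vertical axis or vector magnitude."""

    V = "v"
    VM = "vm"


def vector_magnitude(x: float, y: float, z: float) -> float:
    """Euclidean norm of the three axis counts.

    Raises ValueError on negative input; counts are non-negative by
    definition.
    """
    if x < 0 or y < 0 or z < 0:
        raise ValueError("invalid counts: axis counts must be non-negative")
    return math.sqrt(x * x + y * y + z * z)


@dataclass(frozen=True)
class EpochRecord:
    """One 15-s epoch of triaxial counts for one participant/bout.

    ``vm`` is derived from the axis counts when not supplied.
    """

    participant_id: str
    condition: Condition
    epoch_index: int
    axis_v: float
    axis_ap: float
    axis_ml: float
    vm: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.epoch_index < 0:
            raise ValueError("epoch_index must be non-negative")
        for v in (self.axis_v, self.axis_ap, self.axis_ml):
            if v < 0:
                raise ValueError("invalid counts: axis counts must be non-negative")
        expected = vector_magnitude(self.axis_v, self.axis_ap, self.axis_ml)
        if self.vm is None:
            object.__setattr__(self, "vm", expected)
        elif not math.isclose(self.vm, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"vm={self.vm} inconsistent with axis counts (expected {expected})"
            )


@dataclass(frozen=True)
class Bout:
    """One instructed walking bout with measured distance and duration.

    Speeds are derived; mean counts per 15-s epoch are attached once the
    bout's epochs are known (see :func:`attach_mean_counts`).
    """

    participant_id: str
    condition: Condition
    distance_m: float
    duration_s: float
    mean_counts_v: float | None = None
    mean_counts_vm: float | None = None

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValueError("distance_m must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def speed_ms(self) -> float:
        return self.distance_m / self.duration_s

    @property
    def speed_kmh(self) -> float:
        return self.speed_ms * 3.6

    def mean_counts(self, signal: Signal) -> float:
        value = self.mean_counts_v if signal is Signal.V else self.mean_counts_vm
        if value is None:
            raise ValueError(
                f"bout {self.participant_id}/{self.condition.value} has no "
                f"attached mean counts; call attach_mean_counts first"
            )
        return value


def aggregate_epochs(
    per_second_counts: Sequence[tuple[float, float, float]],
    epoch_length_s: int = DEFAULT_EPOCH_LENGTH_S,
    *,
    participant_id: str = "",
    condition: Condition = Condition.NORMAL,
    keep_partial: bool = False,
) -> list[EpochRecord]:
    """Sum per-second triaxial counts into fixed-length epochs.

    Epoch ``k`` holds the sum of seconds ``[k*L, (k+1)*L)``.  A trailing
    partial epoch is dropped by default: bouts are analysed as complete
    epochs and zero-padding would bias count means downward.  VM is
    computed on the epoch-summed axis values, matching how monitor
    software reports epoch VM.
    """
    if len(per_second_counts) == 0:
        raise ValueError("no samples")
    if epoch_length_s < 1:
        raise ValueError("epoch_length_s must be >= 1")
    for triple in per_second_counts:
        if any(v < 0 for v in triple):
            raise ValueError("invalid counts: negative per-second counts")

    n = len(per_second_counts)
    n_epochs = n // epoch_length_s
    if keep_partial and n % epoch_length_s:
        n_epochs += 1

    out: list[EpochRecord] = []
    for k in range(n_epochs):
        chunk = per_second_counts[k * epoch_length_s : (k + 1) * epoch_length_s]
        sv = sum(c[0] for c in chunk)
        sap = sum(c[1] for c in chunk)
        sml = sum(c[2] for c in chunk)
        out.append(
            EpochRecord(
                participant_id=participant_id,
                condition=condition,
                epoch_index=k,
                axis_v=sv,
                axis_ap=sap,
                axis_ml=sml,
            )
        )
    return out


def compute_speed(distance_m: float, duration_s: float) -> tuple[float, float]:
    """Walking speed from measured distance and duration, in (m/s, km/h)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if distance_m < 0:
        raise ValueError("distance_m must be >= 0")
    speed_ms = distance_m / duration_s
    return speed_ms, speed_ms * 3.6


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def kmh_to_ms(v_kmh: float, decimals: int | None = None) -> float:
    """Convert km/h to m/s, optionally half-up rounded for display."""
    if v_kmh < 0:
        raise ValueError("speed must be non-negative")
    v = v_kmh / 3.6
    if decimals is not None:
        v = round_half_up(v, decimals)
    return v


def attach_mean_counts(
    bouts: Iterable[Bout],
    epochs: Iterable[EpochRecord],
    *,
    trim_epochs: int = 0,
) -> list[Bout]:
    """Attach per-bout mean counts/15 s (vertical and VM) from the epochs.

    ``trim_epochs`` drops that many epochs from each end of every bout
    before averaging (gait initiation/termination); default 0 keeps all.
    Bouts with no remaining epochs raise.
    """
    if trim_epochs < 0:
        raise ValueError("trim_epochs must be >= 0")
    grouped: dict[tuple[str, Condition], list[EpochRecord]] = {}
    for e in epochs:
        grouped.setdefault((e.participant_id, e.condition), []).append(e)

    out = []
    for b in bouts:
        recs = sorted(
            grouped.get((b.participant_id, b.condition), []),
            key=lambda e: e.epoch_index,
        )
        if trim_epochs:
            recs = recs[trim_epochs : len(recs) - trim_epochs]
        if not recs:
            raise ValueError(
                f"bout {b.participant_id}/{b.condition.value} has no epochs "
                f"after trimming"
            )
        mv = sum(e.axis_v for e in recs) / len(recs)
        mvm = sum(e.vm for e in recs) / len(recs)
        out.append(replace(b, mean_counts_v=mv, mean_counts_vm=mvm))
    return out


# --- CSV dialects -----------------------------------------------------------
#
# Epoch CSV: participant_id,condition,epoch_index,axis_v,axis_ap,axis_ml[,vm]
# Bout CSV:  participant_id,condition,distance_m,duration_s
#
# Comma-separated, UTF-8, header required.  Integer counts survive a
# write/read round trip exactly; vm is recomputed when the column is absent.

_EPOCH_COLUMNS = ["participant_id", "condition", "epoch_index", "axis_v", "axis_ap", "axis_ml", "vm"]
_BOUT_COLUMNS = ["participant_id", "condition", "distance_m", "duration_s"]


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_epoch_csv(epochs: Sequence[EpochRecord], path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in epochs],
            "condition": [e.condition.value for e in epochs],
            "epoch_index": [e.epoch_index for e in epochs],
            "axis_v": [_fmt(e.axis_v) for e in epochs],
            "axis_ap": [_fmt(e.axis_ap) for e in epochs],
            "axis_ml": [_fmt(e.axis_ml) for e in epochs],
            "vm": [repr(float(e.vm)) for e in epochs],
        }
    )
    df.to_csv(path, index=False)


def read_epoch_csv(path) -> list[EpochRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    missing = set(_EPOCH_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    has_vm = "vm" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EpochRecord(
                participant_id=str(row.participant_id),
                condition=Condition(row.condition),
                epoch_index=int(row.epoch_index),
                axis_v=float(row.axis_v),
                axis_ap=float(row.axis_ap),
                axis_ml=float(row.axis_ml),
                vm=float(row.vm) if has_vm else None,
            )
        )
    return out


def write_bout_csv(bouts: Sequence[Bout], path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [b.participant_id for b in bouts],
            "condition": [b.condition.value for b in bouts],
            "distance_m": [_fmt(b.distance_m) for b in bouts],
            "duration_s": [_fmt(b.duration_s) for b in bouts],
        }
    )
    df.to_csv(path, index=False)


def read_bout_csv(path) -> list[Bout]:
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    missing = set(_BOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"bout CSV missing columns: {sorted(missing)}")
    return [
        Bout(
            participant_id=str(row.participant_id),
            condition=Condition(row.condition),
            distance_m=float(row.distance_m),
            duration_s=float(row.duration_s),
        )
        for row in df.itertuples(index=False)
    ]
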