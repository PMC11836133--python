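"""Visuo-haptic perturbation schedules.

A *schedule* is an ordered sequence of (seen size v, felt size h) pairs, one per
grasp trial.  The mismatch ``h - v`` is the perturbation.  Two schedule shapes
are supported:

* **abrupt** — a constant mismatch switched on after a short unperturbed
  baseline and switched off again before a closing baseline (the printed
  design: 24 trials with 4 baseline trials at each end, 16 perturbed trials
  in between);
* **sinusoidal** — the mismatch follows a sine over trials (printed design:
  36 trials, 3 cycles of period 12, the first trial unperturbed).

Felt sizes are realised by physical objects available in half-millimetre
steps between 28 and 60 mm, so mismatches are quantised to that grid by
default; pass ``quantum=None`` for the ideal (continuous) schedule.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleKind",
    "StartSign",
    "ScheduleSpec",
    "ScheduleTrial",
    "Schedule",
    "quantize",
    "make_abrupt_schedule",
    "make_sinusoidal_schedule",
    "enumerate_block_set",
    "PILOT_MAGNITUDES_MM",
    "MAIN_MAGNITUDES_MM",
    "PILOT_SEEN_SIZES_MM",
    "MAIN_SEEN_SIZES_MM",
    "FELT_SIZE_RANGE_MM",
]

PILOT_MAGNITUDES_MM = (4.0, 8.0, 12.0)
MAIN_MAGNITUDES_MM = (3.0, 6.0, 12.0)
PILOT_SEEN_SIZES_MM = (40.0, 45.0)
MAIN_SEEN_SIZES_MM = (40.0, 44.0, 48.0)
#: physical felt objects exist from 28 to 60 mm in 0.5 mm steps
FELT_SIZE_RANGE_MM = (28.0, 60.0)
DEFAULT_QUANTUM_MM = 0.5


class ScheduleKind(str, enum.Enum):
    ABRUPT = "abrupt"
    SINUSOIDAL = "sinusoidal"


class StartSign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class SeenAssignment(str, enum.Enum):
    FIXED_PER_BLOCK = "fixed_per_block"
    RANDOMIZED_PER_TRIAL = "randomized_per_trial"


def quantize(value: float, quantum: float | None) -> float:
    """Round ``value`` to the nearest multiple of ``quantum`` (ties away from zero).

    ``quantum=None`` disables quantisation.
    """
    if quantum is None:
        return float(value)
    if quantum <= 0:
        raise ValueError(f"quantum must be positive, got {quantum}")
    q = value / quantum
    # ties away from zero (numpy rounds half to even, python half away for -0.5?)
    return float(math.floor(abs(q) + 0.5) * math.copysign(1.0, q) * quantum)


@dataclass(frozen=True)
class ScheduleSpec:
    """Parameters defining one perturbation block."""

    schedule_kind: ScheduleKind
    magnitude: float  # signed peak mismatch, mm
    n_trials: int = 24
    n_cycles: int | None = None  # sinusoidal only
    baseline_len: int | None = None  # abrupt only
    seen_sizes: tuple[float, ...] = MAIN_SEEN_SIZES_MM
    seen_assignment: SeenAssignment = SeenAssignment.RANDOMIZED_PER_TRIAL
    quantum: float | None = DEFAULT_QUANTUM_MM
    start_sign: StartSign = StartSign.POSITIVE

    def __post_init__(self) -> None:
        kind = ScheduleKind(self.schedule_kind)
        object.__setattr__(self, "schedule_kind", kind)
        object.__setattr__(self, "seen_assignment", SeenAssignment(self.seen_assignment))
        object.__setattr__(self, "start_sign", StartSign(self.start_sign))
        if self.quantum is not None and self.quantum <= 0:
            raise ValueError("quantum must be positive or None")
        if kind is ScheduleKind.ABRUPT:
            bl = self.baseline_len if self.baseline_len is not None else 4
            object.__setattr__(self, "baseline_len", bl)
            if 2 * bl >= self.n_trials:
                raise ValueError(
                    f"abrupt block needs n_trials > 2*baseline_len ({self.n_trials} vs {bl})"
                )
        else:
            nc = self.n_cycles if self.n_cycles is not None else 3
            object.__setattr__(self, "n_cycles", nc)
            if self.n_trials % nc != 0:
                raise ValueError(
                    f"sinusoidal n_trials ({self.n_trials}) must be divisible by "
                    f"n_cycles ({nc})"
                )

    @property
    def period(self) -> int:
        if self.schedule_kind is not ScheduleKind.SINUSOIDAL:
            raise AttributeError("period is defined for sinusoidal schedules only")
        return self.n_trials // self.n_cycles


@dataclass(frozen=True)
class ScheduleTrial:
    trial: int  # 1-based
    v: float  # seen size, mm
    h: float  # felt size, mm

    @property
    def mismatch(self) -> float:
        return self.h - self.v


@dataclass(frozen=True)
class Schedule:
    """An ordered (seen, felt) size sequence for one block."""

    spec: ScheduleSpec
    trials: tuple[ScheduleTrial, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def seen(self) -> np.ndarray:
        return np.array([t.v for t in self.trials])

    @property
    def felt(self) -> np.ndarray:
        return np.array([t.h for t in self.trials])

    @property
    def mismatch(self) -> np.ndarray:
        return self.felt - self.seen

    def to_frame(self, block_id: str | int = 0) -> pd.DataFrame:
        """Tidy trial table with one row per trial."""
        return pd.DataFrame(
            {
                "block_id": block_id,
                "trial": [t.trial for t in self.trials],
                "schedule_kind": self.spec.schedule_kind.value,
                "magnitude": self.spec.magnitude,
                "v_mm": self.seen,
                "h_mm": self.felt,
                "mismatch_mm": self.mismatch,
            }
        )


def _check_seen(spec: ScheduleSpec, seen_sequence: Sequence[float]) -> np.ndarray:
    seen = np.asarray(seen_sequence, dtype=float)
    if seen.ndim != 1 or seen.size != spec.n_trials:
        raise ValueError(
            f"seen_sequence must have length n_trials={spec.n_trials}, got {seen.size}"
        )
    return seen


def _assemble(spec: ScheduleSpec, seen: np.ndarray, mismatch: np.ndarray) -> Schedule:
    felt = seen + np.array([quantize(m, spec.quantum) for m in mismatch])
    trials = tuple(
        ScheduleTrial(trial=i + 1, v=float(v), h=float(h))
        for i, (v, h) in enumerate(zip(seen, felt))
    )
    return Schedule(spec=spec, trials=trials)


def make_abrupt_schedule(spec: ScheduleSpec, seen_sequence: Sequence[float]) -> Schedule:
    """Baseline → constant mismatch → washout baseline.

    The mismatch is 0 on the first and last ``baseline_len`` trials and equals
    ``spec.magnitude`` on every trial in between.
    """
    if spec.schedule_kind is not ScheduleKind.ABRUPT:
        raise ValueError("spec.schedule_kind must be 'abrupt'")
    seen = _check_seen(spec, seen_sequence)
    mismatch = np.zeros(spec.n_trials)
    mismatch[spec.baseline_len : spec.n_trials - spec.baseline_len] = spec.magnitude
    return _assemble(spec, seen, mismatch)


def make_sinusoidal_schedule(
    spec: ScheduleSpec,
    seen_sequence: Sequence[float],
    start_sign: StartSign | str | None = None,
) -> Schedule:
    """Mismatch follows ``sign * M * sin(2*pi*(t-1)/P)`` over trials ``t = 1..n``.

    Trial 1 is exactly unperturbed; ``start_sign`` decides whether the first
    half-cycle pushes the felt size above (*positive*) or below (*negative*)
    the seen size.
    """
    if spec.schedule_kind is not ScheduleKind.SINUSOIDAL:
        raise ValueError("spec.schedule_kind must be 'sinusoidal'")
    seen = _check_seen(spec, seen_sequence)
    sign = {StartSign.POSITIVE: 1.0, StartSign.NEGATIVE: -1.0}[
        StartSign(start_sign if start_sign is not None else spec.start_sign)
    ]
    t = np.arange(spec.n_trials)
    mismatch = sign * spec.magnitude * np.sin(2.0 * np.pi * t / spec.period)
    mismatch[0] = 0.0  # exact, not merely sin(0)
    return _assemble(spec, seen, mismatch)


def make_schedule(
    spec: ScheduleSpec, seen_sequence: Sequence[float]
) -> Schedule:
    """Dispatch on ``spec.schedule_kind``."""
    if spec.schedule_kind is ScheduleKind.ABRUPT:
        return make_abrupt_schedule(spec, seen_sequence)
    return make_sinusoidal_schedule(spec, seen_sequence)


def enumerate_block_set(experiment: str) -> list[ScheduleSpec]:
    """The 12 experimental blocks of one session.

    Six abrupt blocks (one per signed magnitude) and six sinusoidal blocks.
    In the main experiment the seen size is re-drawn every trial from
    {40, 44, 48} mm and half of the sinusoidal blocks start with a negative
    half-cycle; in the pilot the seen size is fixed per block at 40 or 45 mm
    and every sinusoidal block starts positive.
    """
    if experiment == "main":
        magnitudes = MAIN_MAGNITUDES_MM
        seen_sizes: tuple[float, ...] = MAIN_SEEN_SIZES_MM
        assignment = SeenAssignment.RANDOMIZED_PER_TRIAL
        sin_signs = [StartSign.POSITIVE, StartSign.NEGATIVE]
    elif experiment == "pilot":
        magnitudes = PILOT_MAGNITUDES_MM
        seen_sizes = PILOT_SEEN_SIZES_MM
        assignment = SeenAssignment.FIXED_PER_BLOCK
        sin_signs = [StartSign.POSITIVE, StartSign.POSITIVE]
    else:
        raise ValueError(f"unknown experiment {experiment!r}; expected 'pilot' or 'main'")

    specs: list[ScheduleSpec] = []
    for m in magnitudes:
        for signed in (m, -m):
            specs.append(
                ScheduleSpec(
                    schedule_kind=ScheduleKind.ABRUPT,
                    magnitude=signed,
                    n_trials=24,
                    baseline_len=4,
                    seen_sizes=seen_sizes,
                    seen_assignment=assignment,
                )
            )
    # six sinusoidal blocks: each magnitude twice; start signs alternate in the
    # main experiment ("half of the sinusoidal blocks started with a negative
    # perturbation"), all positive in the pilot
    for m in magnitudes:
        for sign in sin_signs:
            specs.append(
                ScheduleSpec(
                    schedule_kind=ScheduleKind.SINUSOIDAL,
                    magnitude=m,
                    n_trials=36,
                    n_cycles=3,
                    seen_sizes=seen_sizes,
                    seen_assignment=assignment,
                    start_sign=sign,
                )
            )
    return specs


def draw_seen_sequence(
    spec: ScheduleSpec, rng: np.random.Generator, fixed_size: float | None = None
) -> np.ndarray:
    """Seen sizes for one block under the spec's assignment policy."""
    if spec.seen_assignment is SeenAssignment.RANDOMIZED_PER_TRIAL:
        return rng.choice(np.asarray(spec.seen_sizes), size=spec.n_trials)
    size = fixed_size if fixed_size is not None else spec.seen_sizes[0]
    if size not in spec.seen_sizes:
        raise ValueError(f"fixed seen size {size} not in {spec.seen_sizes}")
    return np.full(spec.n_trials, float(size))
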