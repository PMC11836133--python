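"""Synthetic visuo-haptic grasping experiments.

Generates everything downstream stages consume: per-trial maximum grip
apertures (MGAs) from the state-space adaptation model, 3-D marker
trajectories that realise those apertures, and binary 2AFC size judgments
from a noisy-comparison observer.

The observer model deserves a caveat.  The hypothesis under study is that
sensorimotor adaptation shrinks the error signal and thereby makes size
mismatches harder to detect.  We operationalise this with a coupling
parameter ``kappa``: the observer compares the felt size ``h`` against an
internal reference ``v + kappa * x`` that is shifted by the adaptation state
``x``, plus Gaussian decision noise.  ``kappa = 0`` is a stationary observer
(detection unaffected by adaptation); ``kappa = 1`` fully couples perception
to the adapted visuomotor mapping.  This is a simulation device for testing
the analysis chain, not an empirical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import schedules as sched
from .adaptation import ResponseFunction
from .kinematics import Trajectory

__all__ = [
    "SimParticipant",
    "TrajectorySpec",
    "simulate_mgas",
    "simulate_response",
    "simulate_responses",
    "simulate_trajectory",
    "simulate_experiment",
    "make_cohort",
    "SimulatedExperiment",
]


@dataclass(frozen=True)
class SimParticipant:
    """Generating parameters for one synthetic participant.

    Defaults follow the reference simulation point used throughout
    (retention A = 0.95, error-correction b = 0.2); response-function
    defaults put the baseline aperture roughly 20 mm above the object, with
    a slope near the strong size scaling seen in simple setups (0.93).
    """

    A_true: float = 0.95
    b_true: float = 0.2
    intercept_true: float = 23.0  # mm
    slope_true: float = 0.93
    motor_noise_sd: float = 2.0  # mm, additive on each MGA
    obs_sigma: float = 4.0  # mm, 2AFC decision noise
    obs_bias: float = 0.0  # mm, PSE offset
    kappa: float = 1.0  # adaptation–perception coupling
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("A_true", "b_true", "kappa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.motor_noise_sd < 0 or self.obs_sigma < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def response_function(self) -> ResponseFunction:
        return ResponseFunction(self.intercept_true, self.slope_true)


@dataclass(frozen=True)
class TrajectorySpec:
    """Geometry and noise of one simulated reach-to-grasp recording."""

    sampling_rate: float = 500.0  # Hz (main); pilot used 200
    duration: float = 3.0  # s (main); pilot used 5
    movement_time: float = 1.0  # s
    # the aperture peaks before the hand crosses the touch-detection radius
    # (half the reach, under the minimum-jerk transport), so the programmed
    # peak always falls inside the [onset, touch) extraction window
    mga_fraction: float = 0.45  # of movement time at which the aperture peaks
    start_delay: float = 0.3  # s of stillness before onset
    start_aperture: float = 20.0  # mm, thumb–index at rest
    reach_distance: float = 300.0  # mm from start to object; must exceed the
    # touch-proximity radius (150 mm main, 300 mm pilot)
    dropout_prob: float = 0.0  # per-frame, per-digit marker
    marker_noise_sd: float = 0.0  # mm per coordinate

    def __post_init__(self) -> None:
        if not 0.0 < self.mga_fraction < 1.0:
            raise ValueError("mga_fraction must lie strictly in (0, 1)")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")

    @classmethod
    def for_experiment(cls, experiment: str, **kw) -> "TrajectorySpec":
        if experiment == "pilot":
            kw.setdefault("reach_distance", 600.0)  # touch radius is 300 mm
            return cls(sampling_rate=200.0, duration=5.0, **kw)
        if experiment == "main":
            return cls(sampling_rate=500.0, duration=3.0, **kw)
        raise ValueError(f"unknown experiment {experiment!r}")


def simulate_mgas(
    participant: SimParticipant,
    schedule: sched.Schedule,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Closed-loop MGA sequence for one block.

    The state starts at zero; each trial's aperture is the model prediction
    plus motor noise, and the *noisy* aperture feeds the error signal (random
    errors propagate into correction, as when fitting observed data):

        MGA_t = int + slope*(v_t + x_t) + eps_t
        E_t   = MGA_t - (int + slope*h_t)
        x_t+1 = A*x_t - b*E_t

    Returns a frame with columns trial, v_mm, h_mm, mismatch_mm, state_x,
    mga_mm.
    """
    rng = np.random.default_rng(participant.seed) if rng is None else rng
    p = participant
    v, h = schedule.seen, schedule.felt
    n = v.size
    eps = rng.normal(0.0, p.motor_noise_sd, size=n) if p.motor_noise_sd > 0 else np.zeros(n)
    x = 0.0
    states = np.empty(n)
    mgas = np.empty(n)
    for t in range(n):
        states[t] = x
        mga = p.intercept_true + p.slope_true * (v[t] + x) + eps[t]
        mgas[t] = mga
        e = mga - (p.intercept_true + p.slope_true * h[t])
        x = p.A_true * x - p.b_true * e
    return pd.DataFrame(
        {"trial": np.arange(1, n + 1), "v_mm": v, "h_mm": h,
         "mismatch_mm": h - v, "state_x": states, "mga_mm": mgas}
    )


def response_probability(participant: SimParticipant, v, h, x) -> np.ndarray:
    """P(respond 'felt larger') for the noisy-comparison observer."""
    from scipy.stats import norm

    p = participant
    d = np.asarray(h) - (np.asarray(v) + p.kappa * np.asarray(x)) - p.obs_bias
    if p.obs_sigma == 0:
        return (d > 0).astype(float)
    return norm.cdf(d / p.obs_sigma)


def simulate_response(
    participant: SimParticipant, v: float, h: float, x: float,
    rng: np.random.Generator | None = None,
) -> str:
    """One 2AFC judgment: 'felt_larger' or 'felt_smaller'."""
    rng = np.random.default_rng(participant.seed) if rng is None else rng
    p = participant
    d = h - (v + p.kappa * x) - p.obs_bias + rng.normal(0.0, p.obs_sigma)
    return "felt_larger" if d > 0 else "felt_smaller"


def simulate_responses(
    participant: SimParticipant, block: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    """Vectorised judgments for a simulated block (needs state_x column)."""
    p = participant
    d = (block["h_mm"].to_numpy() - (block["v_mm"].to_numpy()
         + p.kappa * block["state_x"].to_numpy()) - p.obs_bias)
    d = d + rng.normal(0.0, p.obs_sigma, size=len(block))
    return pd.Series(np.where(d > 0, "felt_larger", "felt_smaller"), index=block.index)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Position profile on [0, 1] with zero velocity/acceleration at both ends."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trajectory(
    spec: TrajectorySpec,
    mga_mm: float,
    object_size_mm: float,
    object_position_xyz=(0.0, 0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """One reach-to-grasp recording whose true peak aperture equals ``mga_mm``.

    The thumb–index midpoint travels a minimum-jerk path from the start
    position to the object centre over ``movement_time``; the aperture opens
    from ``start_aperture`` to exactly ``mga_mm`` at ``mga_fraction`` of the
    movement (cosine easing, zero rate at the peak), then closes onto the
    object.  After the movement the hand rests on the object.  Marker noise
    and dropouts are applied last.
    """
    if mga_mm <= object_size_mm:
        raise ValueError(
            f"peak aperture ({mga_mm} mm) must exceed object size ({object_size_mm} mm)"
        )
    rng = np.random.default_rng() if rng is None else rng
    fs, mt = spec.sampling_rate, spec.movement_time
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    obj = np.asarray(object_position_xyz, dtype=float)
    start = obj + np.array([0.0, -spec.reach_distance, 0.0])

    # transport: midpoint along y towards the object
    mid = np.tile(start, (n, 1))
    if mt > 0:
        tau = np.clip((t - spec.start_delay) / mt, 0.0, 1.0)
        mid = start + np.outer(_minimum_jerk(tau), obj - start)

    # aperture: open to the peak, then close onto the object
    ap = np.full(n, spec.start_aperture)
    if mt > 0:
        t_rel = t - spec.start_delay
        t_peak = spec.mga_fraction * mt
        rise = (t_rel >= 0) & (t_rel < t_peak)
        u = t_rel[rise] / t_peak
        ap[rise] = spec.start_aperture + (mga_mm - spec.start_aperture) * 0.5 * (
            1 - np.cos(np.pi * u)
        )
        fall = (t_rel >= t_peak) & (t_rel <= mt)
        u = (t_rel[fall] - t_peak) / (mt - t_peak)
        ap[fall] = object_size_mm + (mga_mm - object_size_mm) * 0.5 * (1 + np.cos(np.pi * u))
        ap[t_rel > mt] = object_size_mm

    lateral = np.array([1.0, 0.0, 0.0])
    positions = {
        "thumb": mid - 0.5 * np.outer(ap, lateral),
        "index": mid + 0.5 * np.outer(ap, lateral),
        "wrist": mid + np.array([0.0, -80.0, -20.0]),
        "reference": np.tile(obj + np.array([0.0, 60.0, 0.0]), (n, 1)),
    }
    if spec.marker_noise_sd > 0:
        for name in positions:
            positions[name] = positions[name] + rng.normal(
                0.0, spec.marker_noise_sd, size=(n, 3)
            )
    if spec.dropout_prob > 0:
        for name in ("thumb", "index"):
            drop = rng.random(n) < spec.dropout_prob
            positions[name][drop] = np.nan
    return Trajectory(sampling_rate=fs, t=t, positions=positions)


@dataclass
class SimulatedExperiment:
    """Tidy per-trial table plus (optionally) per-trial marker recordings."""

    trials: pd.DataFrame
    trajectories: dict[tuple, Trajectory]
    experiment: str
    seed: int

    def write(self, out_dir: str | Path) -> Path:
        """Write trial table, trajectory CSVs and a manifest under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        rows = []
        traj_dir = out / "trajectories"
        if self.trajectories:
            traj_dir.mkdir(exist_ok=True)
        for (pid, block, trial), traj in self.trajectories.items():
            fname = f"p{pid:03d}_b{block:02d}_t{trial:02d}.csv"
            traj.to_frame().to_csv(traj_dir / fname, index=False)
            rows.append(
                {"participant": pid, "block": block, "trial": trial,
                 "file": f"trajectories/{fname}", "sampling_rate_hz": traj.sampling_rate}
            )
        pd.DataFrame(rows, columns=["participant", "block", "trial", "file",
                                    "sampling_rate_hz"]).to_csv(
            out / "manifest.csv", index=False
        )
        return out


def make_cohort(
    n: int,
    seed: int = 0,
    base: SimParticipant | None = None,
    a_sd: float = 0.02,
    b_sd: float = 0.04,
    intercept_sd: float = 4.0,
) -> list[SimParticipant]:
    """A cohort of participants jittered around a base parameter point."""
    base = SimParticipant() if base is None else base
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(
            replace(
                base,
                A_true=float(np.clip(base.A_true + rng.normal(0, a_sd), 0.0, 1.0)),
                b_true=float(np.clip(base.b_true + rng.normal(0, b_sd), 0.0, 1.0)),
                intercept_true=float(base.intercept_true + rng.normal(0, intercept_sd)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def simulate_experiment(
    cohort: list[SimParticipant],
    experiment: str = "main",
    include_trajectories: bool = False,
    trajectory_spec: TrajectorySpec | None = None,
) -> SimulatedExperiment:
    """Full 12-block session per participant.

    Returns a tidy trial table (one row per grasp + judgment) and, when
    ``include_trajectories`` is set, a marker recording per trial (slow; off
    by default).  Deterministic given each participant's seed.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    specs = sched.enumerate_block_set(experiment)
    tspec = trajectory_spec or TrajectorySpec.for_experiment(experiment)
    frames = []
    trajectories: dict[tuple, Trajectory] = {}
    for pid, part in enumerate(cohort, start=1):
        ss = np.random.SeedSequence(part.seed)
        block_streams = [np.random.default_rng(s) for s in ss.spawn(len(specs) + 1)]
        for bi, spec in enumerate(specs, start=1):
            rng = block_streams[bi - 1]
            fixed = spec.seen_sizes[(bi - 1) % len(spec.seen_sizes)]
            seen = sched.draw_seen_sequence(spec, rng, fixed_size=fixed)
            schedule = sched.make_schedule(spec, seen)
            block = simulate_mgas(part, schedule, rng)
            block["response"] = simulate_responses(part, block, rng)
            block.insert(0, "start_sign", spec.start_sign.value)
            block.insert(0, "magnitude", spec.magnitude)
            block.insert(0, "schedule_kind", spec.schedule_kind.value)
            block.insert(0, "block", bi)
            block.insert(0, "participant", pid)
            frames.append(block)
            if include_trajectories:
                for _, row in block.iterrows():
                    # a noisy aperture can (rarely) undershoot the object size,
                    # which no physical grasp recording can realise; floor the
                    # recorded peak just above the object in that case
                    traj_mga = max(row["mga_mm"], row["h_mm"] + 0.5)
                    traj = simulate_trajectory(tspec, traj_mga, row["h_mm"], rng=rng)
                    trajectories[(pid, bi, int(row["trial"]))] = traj
    trials = pd.concat(frames, ignore_index=True)
    return SimulatedExperiment(
        trials=trials, trajectories=trajectories, experiment=experiment,
        seed=cohort[0].seed,
    )
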