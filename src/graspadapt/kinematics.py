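"""Reach-to-grasp kinematics: from marker trajectories to maximum grip apertures.

The processing chain mirrors standard grasp-kinematics practice:

1. cubic-spline interpolation of missing motion-capture frames (interior gaps
   only; leading/trailing gaps are left missing),
2. Savitzky–Golay smoothing with a 200 ms window (3rd-order),
3. movement onset by a sustained velocity criterion on thumb and index
   (> 0.05 m/s),
4. "touched" event by the conjunction of a low aperture-velocity criterion
   and a proximity criterion (thumb–index midpoint near the object centre),
5. the maximum grip aperture (MGA) as the largest thumb–index distance
   between onset and touch,
6. four per-trial exclusion rules (interpolated MGA frame, too many missing
   frames, implausibly small MGA, within-cell outlier).

Positions are in mm and time in s throughout; velocity thresholds quoted in
m/s are converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

__all__ = [
    "MARKERS",
    "Trajectory",
    "SegmentationResult",
    "ExclusionFlags",
    "SegmentationError",
    "interpolate_missing",
    "smooth",
    "detect_movement_start",
    "detect_touch",
    "extract_mga",
    "segment_trial",
    "apply_exclusions",
    "TOUCH_CRITERIA",
]

MARKERS = ("thumb", "index", "wrist", "reference")

#: (aperture-velocity threshold m/s, midpoint-to-object radius mm) per experiment
TOUCH_CRITERIA = {"pilot": (0.1, 300.0), "main": (0.075, 150.0)}

ONSET_SPEED_MS = 0.05  # m/s, on both thumb and index
SUSTAIN_S = 0.025  # threshold crossings must hold this long
MISSING_FRACTION_LIMIT = 0.20
OUTLIER_IQR_FACTOR = 3.0


class SegmentationError(RuntimeError):
    """A segmentation criterion was never met (no movement / no touch)."""


@dataclass
class Trajectory:
    """Fixed-rate 3-D marker positions; missing samples are NaN rows.

    ``positions`` maps marker name to an (n_frames, 3) array in mm; ``t`` is
    the shared time base in s.
    """

    sampling_rate: float
    t: np.ndarray
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = self.t.size
        for name, arr in self.positions.items():
            if arr.shape != (n, 3):
                raise ValueError(f"marker {name!r} has shape {arr.shape}, want ({n}, 3)")

    @property
    def n_frames(self) -> int:
        return self.t.size

    def missing_mask(self, markers: Iterable[str] = ("thumb", "index")) -> np.ndarray:
        """Frames where any of the given markers has a missing sample."""
        m = np.zeros(self.n_frames, dtype=bool)
        for name in markers:
            m |= np.isnan(self.positions[name]).any(axis=1)
        return m

    def aperture(self) -> np.ndarray:
        """Thumb–index Euclidean distance per frame (mm)."""
        d = self.positions["thumb"] - self.positions["index"]
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.sampling_rate, self.t.copy(), {k: v.copy() for k, v in self.positions.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: t_s, marker, x_mm, y_mm, z_mm."""
        parts = []
        for name in self.positions:
            p = self.positions[name]
            parts.append(
                pd.DataFrame(
                    {"t_s": self.t, "marker": name,
                     "x_mm": p[:, 0], "y_mm": p[:, 1], "z_mm": p[:, 2]}
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sampling_rate: float | None = None) -> "Trajectory":
        t = np.sort(df["t_s"].unique())
        if sampling_rate is None:
            dt = np.diff(t)
            sampling_rate = float(round(1.0 / np.median(dt)))
        positions = {}
        for name, sub in df.groupby("marker"):
            sub = sub.set_index("t_s").reindex(t)
            positions[name] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        return cls(sampling_rate, t, positions)


@dataclass(frozen=True)
class SegmentationResult:
    start_index: int
    touch_index: int
    mga_mm: float
    mga_index: int
    movement_time_s: float
    time_to_mga_s: float
    interpolated_mask: np.ndarray = field(repr=False)
    missing_fraction: float = 0.0


@dataclass(frozen=True)
class ExclusionFlags:
    mga_on_interpolated: bool = False
    too_many_missing: bool = False
    mga_below_object: bool = False
    mga_outlier: bool = False

    @property
    def excluded(self) -> bool:
        return (self.mga_on_interpolated or self.too_many_missing
                or self.mga_below_object or self.mga_outlier)


def interpolate_missing(traj: Trajectory) -> tuple[Trajectory, np.ndarray]:
    """Fill interior missing samples per marker coordinate by cubic spline.

    Returns the filled trajectory and a boolean (n_frames,) mask of frames
    where thumb or index was filled.  Leading/trailing gaps cannot be
    interpolated without extrapolating and are left missing (they still count
    as missing downstream).
    """
    out = traj.copy()
    mask = np.zeros(traj.n_frames, dtype=bool)
    for name, arr in out.positions.items():
        missing = np.isnan(arr).any(axis=1)
        if not missing.any():
            continue
        present = ~missing
        if present.sum() < 4:
            raise ValueError(f"marker {name!r}: fewer than 4 observed frames")
        first, last = np.flatnonzero(present)[[0, -1]]
        interior = missing & (np.arange(traj.n_frames) > first) & (np.arange(traj.n_frames) < last)
        if interior.any():
            for c in range(3):
                cs = CubicSpline(traj.t[present], arr[present, c])
                arr[interior, c] = cs(traj.t[interior])
            if name in ("thumb", "index"):
                mask |= interior
    return out, mask


def _window_frames(sampling_rate: float, window_s: float = 0.2) -> int:
    w = int(round(window_s * sampling_rate))
    return w + 1 if w % 2 == 0 else w


def smooth(traj: Trajectory, window_s: float = 0.2, polyorder: int = 3) -> Trajectory:
    """Savitzky–Golay smoothing of each marker coordinate.

    Window is ``round(window_s * sampling_rate)`` frames, forced odd.  NaN
    stretches are left untouched; each contiguous observed run is smoothed
    separately (runs shorter than the window are passed through).
    """
    w = _window_frames(traj.sampling_rate, window_s)
    if w <= polyorder:
        raise ValueError("smoothing window shorter than the polynomial order")
    if w > traj.n_frames:
        raise ValueError(f"trace ({traj.n_frames} frames) shorter than window ({w})")
    out = traj.copy()
    for arr in out.positions.values():
        ok = ~np.isnan(arr).any(axis=1)
        # smooth each contiguous observed run
        edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo > w:
                arr[lo:hi] = savgol_filter(arr[lo:hi], w, polyorder, axis=0)
    return out


def _speed(pos: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Speed in m/s from positions in mm, central differences (NaN-tolerant)."""
    v = np.gradient(pos, axis=0) * sampling_rate / 1000.0
    return np.linalg.norm(v, axis=1)


def _sustained_crossing(condition: np.ndarray, n_sustain: int, start: int = 0) -> int | None:
    """First index >= start where ``condition`` holds for ``n_sustain`` frames."""
    n = condition.size
    run = 0
    for i in range(start, n):
        run = run + 1 if condition[i] else 0
        if run >= n_sustain:
            return i - n_sustain + 1
    return None


def _n_sustain(sampling_rate: float) -> int:
    return max(1, int(round(SUSTAIN_S * sampling_rate)))


def detect_movement_start(traj: Trajectory) -> int:
    """First frame where thumb AND index speed exceed 0.05 m/s, sustained 25 ms."""
    thumb = _speed(traj.positions["thumb"], traj.sampling_rate)
    index = _speed(traj.positions["index"], traj.sampling_rate)
    cond = (thumb > ONSET_SPEED_MS) & (index > ONSET_SPEED_MS)
    cond &= ~np.isnan(thumb) & ~np.isnan(index)
    hit = _sustained_crossing(cond, _n_sustain(traj.sampling_rate))
    if hit is None:
        raise SegmentationError("movement-onset velocity criterion never met")
    return hit


def detect_touch(
    traj: Trajectory, start: int, object_center_xyz, experiment: str = "main"
) -> int:
    """First frame after ``start`` with slow aperture change near the object.

    Conjunction of |d(aperture)/dt| below the experiment's threshold and the
    thumb–index midpoint within the experiment's radius of the object centre.
    """
    try:
        vel_thresh, radius = TOUCH_CRITERIA[experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {experiment!r}") from None
    ap = traj.aperture()
    ap_vel = np.abs(np.gradient(ap) * traj.sampling_rate / 1000.0)  # m/s
    mid = 0.5 * (traj.positions["thumb"] + traj.positions["index"])
    dist = np.linalg.norm(mid - np.asarray(object_center_xyz, float), axis=1)
    cond = (ap_vel < vel_thresh) & (dist < radius)
    cond &= ~np.isnan(ap_vel) & ~np.isnan(dist)
    hit = _sustained_crossing(cond, _n_sustain(traj.sampling_rate), start=start + 1)
    if hit is None:
        raise SegmentationError("touch criterion never met")
    return hit


def extract_mga(traj: Trajectory, start: int, touch: int) -> tuple[float, int]:
    """Largest thumb–index distance on [start, touch); earliest frame on ties."""
    if not start < touch:
        raise ValueError(f"need start < touch, got {start} >= {touch}")
    ap = traj.aperture()[start:touch]
    idx = int(np.nanargmax(ap))
    return float(ap[idx]), start + idx


def segment_trial(
    raw: Trajectory, object_center_xyz, experiment: str = "main"
) -> SegmentationResult:
    """Full single-trial chain: interpolate, smooth, segment, extract the MGA."""
    filled, interp_mask = interpolate_missing(raw)
    sm = smooth(filled)
    start = detect_movement_start(sm)
    touch = detect_touch(sm, start, object_center_xyz, experiment)
    mga, mga_idx = extract_mga(sm, start, touch)
    missing = raw.missing_mask()[start : touch + 1]
    return SegmentationResult(
        start_index=start,
        touch_index=touch,
        mga_mm=mga,
        mga_index=mga_idx,
        movement_time_s=float((touch - start) / sm.sampling_rate),
        time_to_mga_s=float((mga_idx - start) / sm.sampling_rate),
        interpolated_mask=interp_mask,
        missing_fraction=float(np.mean(missing)) if missing.size else 0.0,
    )


def apply_exclusions(
    trials: pd.DataFrame,
    *,
    mga_col: str = "mga_mm",
    object_col: str = "h_mm",
    seen_col: str = "v_mm",
    interp_col: str = "mga_on_interpolated",
    missing_col: str = "missing_fraction",
) -> pd.DataFrame:
    """Apply the four per-trial exclusion rules to one participant's results.

    (i) the MGA frame was spline-interpolated; (ii) more than 20% of frames
    between onset and touch were missing; (iii) the MGA is smaller than the
    grasped (felt) object; (iv) the MGA is more than 3 interquartile ranges
    from the participant's median MGA for the same seen and felt size (cells
    with fewer than 2 trials skip this rule).

    Returns a copy of ``trials`` with boolean flag columns and ``excluded``.
    """
    out = trials.copy()
    out["flag_interpolated_mga"] = out.get(interp_col, False)
    out["flag_missing_frames"] = out.get(missing_col, 0.0) > MISSING_FRACTION_LIMIT
    out["flag_mga_below_object"] = out[mga_col] < out[object_col]

    flag_outlier = np.zeros(len(out), dtype=bool)
    for _, cell in out.groupby([seen_col, object_col]):
        if len(cell) < 2:
            continue
        med = cell[mga_col].median()
        q1, q3 = cell[mga_col].quantile([0.25, 0.75])
        iqr = q3 - q1
        dev = (cell[mga_col] - med).abs()
        flag_outlier[out.index.get_indexer(cell.index)] = dev > OUTLIER_IQR_FACTOR * iqr
    out["flag_mga_outlier"] = flag_outlier

    out["excluded"] = (
        out["flag_interpolated_mga"].astype(bool)
        | out["flag_missing_frames"]
        | out["flag_mga_below_object"]
        | out["flag_mga_outlier"]
    )
    return out
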