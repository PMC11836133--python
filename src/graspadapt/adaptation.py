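"""Trial-by-trial state-space model of grip-aperture adaptation.

Grip apertures scale with object size through a linear response function

    MGA(v) = int + slope * v

where ``v`` is the seen size in mm.  Adaptation to a visuo-haptic size
mismatch is captured by a latent state ``x_t`` (a shift of the visuomotor
mapping, in mm of object size) added to the seen size at planning time:

    MGA_mod(t) = int + slope * (v_t + x_t)

After each grasp the haptic feedback defines an error signal: the deviation
of the executed aperture from the comfortable aperture for the *felt* size
``h_t``,

    E_t = MGA_t - (int + slope * h_t)

and the state is carried over and corrected,

    x_{t+1} = A * x_t - b * E_t ,      x_1 = 0

with retention ``A`` and error-correction rate ``b``, both in [0, 1].  With
this sign convention a grasp that was too large for the felt object
(E_t > 0) drives the state down, so the closed loop is stable and converges,
for a constant mismatch ``delta`` and noise-free responses, to the fixed
point ``x* = b*slope*delta / (1 - A + b*slope)``.

The literature sometimes writes the error with the opposite sign
(comfortable minus observed); combined with the ``A x - b E`` update that
convention is unstable (errors amplify).  Both are available through
``error_sign``; the stable convention is the default and the one used for
fitting.

Block-wise fitting minimises the root-mean-square error between observed and
modelled apertures over (A, b, int) with the response slope held fixed at a
participant-set value (slope and b trade off, so the slope is estimated once
from the size scaling of mean apertures and then frozen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .schedules import Schedule

__all__ = [
    "ResponseFunction",
    "AdaptationFit",
    "predict_mga",
    "error_signal",
    "update_state",
    "run_forward",
    "fit_block",
    "fit_response_slope",
    "closed_loop_fixed_point",
    "closed_loop_frequency_response",
]

ErrorSign = Literal["stable", "as_printed"]
ExcludedPolicy = Literal["propagate_model", "freeze_state"]


@dataclass(frozen=True)
class ResponseFunction:
    """Linear mapping from object size (mm) to grip aperture (mm)."""

    intercept: float
    slope: float


def predict_mga(rf: ResponseFunction, v: float, x: float = 0.0):
    """Modelled aperture for seen size ``v`` under state ``x`` (both mm)."""
    return rf.intercept + rf.slope * (np.asarray(v) + np.asarray(x))


def error_signal(
    rf: ResponseFunction, h: float, mga_observed: float, error_sign: ErrorSign = "stable"
):
    """Deviation of the observed aperture from the comfortable grasp of the felt size."""
    e = np.asarray(mga_observed) - (rf.intercept + rf.slope * np.asarray(h))
    return e if error_sign == "stable" else -e


def update_state(A: float, b: float, x: float, E: float) -> float:
    """One trial of state carry-over and error correction."""
    if not (0.0 <= A <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError(f"A and b must lie in [0, 1], got A={A}, b={b}")
    return A * x - b * E


def run_forward(
    A: float,
    b: float,
    rf: ResponseFunction,
    schedule: Schedule | None = None,
    observed_mgas: Sequence[float] | None = None,
    *,
    seen: Sequence[float] | None = None,
    felt: Sequence[float] | None = None,
    usable: Sequence[bool] | None = None,
    error_sign: ErrorSign = "stable",
    excluded_policy: ExcludedPolicy = "propagate_model",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the state-space recursion over one block.

    Returns ``(states, predictions, errors)``, each of block length.  When
    ``observed_mgas`` is given the error uses the observed aperture (the
    closed-loop-on-data mode used for fitting); otherwise the model is
    self-driven and the error uses its own prediction.  Trials flagged
    unusable (excluded grasps) carry the state forward using the model's own
    prediction as the error carrier by default, or freeze the state entirely
    under ``excluded_policy="freeze_state"``.
    """
    if schedule is not None:
        v = schedule.seen
        h = schedule.felt
    else:
        if seen is None or felt is None:
            raise ValueError("provide either a schedule or seen and felt arrays")
        v = np.asarray(seen, dtype=float)
        h = np.asarray(felt, dtype=float)
    n = v.size
    obs = None
    if observed_mgas is not None:
        obs = np.asarray(observed_mgas, dtype=float)
        if obs.size != n:
            raise ValueError(f"observed_mgas length {obs.size} != block length {n}")
    use = np.ones(n, dtype=bool) if usable is None else np.asarray(usable, dtype=bool)

    states = np.empty(n)
    preds = np.empty(n)
    errs = np.empty(n)
    intercept, slope = rf.intercept, rf.slope
    sgn = 1.0 if error_sign == "stable" else -1.0
    x = 0.0
    for t in range(n):
        states[t] = x
        pred = intercept + slope * (v[t] + x)
        preds[t] = pred
        if obs is not None and use[t] and np.isfinite(obs[t]):
            carrier = obs[t]
        elif excluded_policy == "freeze_state" and obs is not None:
            errs[t] = np.nan
            continue  # x unchanged
        else:
            carrier = pred
        e = sgn * (carrier - (intercept + slope * h[t]))
        errs[t] = e
        x = A * x - b * e
    return states, preds, errs


def closed_loop_fixed_point(A: float, b: float, slope: float, delta: float) -> float:
    """Asymptotic state under a constant mismatch ``delta`` (noise-free loop)."""
    return b * slope * delta / (1.0 - A + b * slope)


def closed_loop_frequency_response(
    A: float, b: float, slope: float, period: int
) -> tuple[float, float]:
    """Steady-state gain and phase of the state for a sinusoidal mismatch.

    The noise-free closed loop is the first-order linear filter
    ``x_{t+1} = c x_t + d m_t`` with ``c = A - b*slope`` and ``d = b*slope``
    driven by the mismatch ``m_t``.  Returns ``(gain, phase_rad)`` of
    ``x_t`` relative to ``m_t`` at angular frequency ``2*pi/period``.
    """
    c = A - b * slope
    d = b * slope
    w = 2.0 * np.pi / period
    h = d / (np.exp(1j * w) - c)
    return float(np.abs(h)), float(np.angle(h))


@dataclass(frozen=True)
class AdaptationFit:
    """Block-wise parameter estimates and model trace."""

    A: float
    b: float
    intercept: float
    slope_fixed: float
    rmse: float
    states: np.ndarray
    predicted: np.ndarray
    errors: np.ndarray
    n: int
    n_used: int
    flat_ridge: bool = False  # objective insensitive to b (e.g. unperturbed block)

    @property
    def response_function(self) -> ResponseFunction:
        return ResponseFunction(self.intercept, self.slope_fixed)


def _block_residuals(
    params: np.ndarray,
    obs: np.ndarray,
    v: np.ndarray,
    h: np.ndarray,
    usable: np.ndarray,
    slope: float,
    error_sign: ErrorSign,
    excluded_policy: ExcludedPolicy,
) -> np.ndarray:
    A, b, intercept = params
    rf = ResponseFunction(intercept, slope)
    _, preds, _ = run_forward(
        A, b, rf, observed_mgas=obs, seen=v, felt=h, usable=usable,
        error_sign=error_sign, excluded_policy=excluded_policy,
    )
    return (preds - obs)[usable]


def _block_rmse(params: np.ndarray, *args) -> float:
    resid = _block_residuals(params, *args)
    return float(np.sqrt(np.mean(resid**2)))


# deterministic multi-start grid over the box constraints
_A_STARTS = np.arange(0.1, 0.91, 0.1)
_B_STARTS = np.arange(0.05, 0.51, 0.05)


def fit_block(
    observed_mgas: Sequence[float],
    schedule: Schedule | None = None,
    slope_fixed: float = 1.0,
    *,
    seen: Sequence[float] | None = None,
    felt: Sequence[float] | None = None,
    usable: Sequence[bool] | None = None,
    error_sign: ErrorSign = "stable",
    excluded_policy: ExcludedPolicy = "propagate_model",
    n_refine: int = 3,
    min_trials: int = 6,
) -> AdaptationFit:
    """Estimate (A, b, intercept) for one block by RMSE minimisation.

    Deterministic: a coarse grid over A in {0.1..0.9} and b in {0.05..0.5}
    (intercept seeded from the mean aperture, de-sloped by the seen sizes)
    ranks starting points, and the best ``n_refine`` are polished by bounded
    Powell search.  ``usable`` masks excluded trials: their residuals do not
    enter the objective and the state propagates per ``excluded_policy``.
    """
    obs = np.asarray(observed_mgas, dtype=float)
    if schedule is not None:
        v, h = schedule.seen, schedule.felt
    else:
        v = np.asarray(seen, dtype=float)
        h = np.asarray(felt, dtype=float)
    if obs.size != v.size:
        raise ValueError("observed_mgas and schedule lengths differ")
    use = np.isfinite(obs) if usable is None else (np.asarray(usable, bool) & np.isfinite(obs))
    n_used = int(use.sum())
    if n_used < min_trials:
        raise ValueError(f"need at least {min_trials} usable trials, got {n_used}")

    # intercept start: de-sloped apertures on unperturbed trials where the
    # state is (near) zero; falls back to the whole block
    zero_mm = use & np.isclose(h, v)
    base = zero_mm if zero_mm.any() else use
    int0 = float(np.mean(obs[base] - slope_fixed * v[base]))
    args = (obs, v, h, use, slope_fixed, error_sign, excluded_policy)

    starts = []
    for a0 in _A_STARTS:
        for b0 in _B_STARTS:
            starts.append((_block_rmse(np.array([a0, b0, int0]), *args), a0, b0))
    starts.sort(key=lambda s: (s[0], s[1], s[2]))

    lo = np.array([0.0, 0.0, int0 - 50.0])
    hi = np.array([1.0, 1.0, int0 + 50.0])
    best_x, best_f = None, np.inf
    for f0, a0, b0 in starts[: max(1, n_refine)]:
        res = optimize.least_squares(
            _block_residuals,
            np.array([a0, b0, int0]),
            args=args,
            bounds=(lo, hi),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        f = _block_rmse(res.x, *args)
        if f < best_f:
            best_x, best_f = res.x, f
    A, b, intercept = best_x
    rf = ResponseFunction(intercept, slope_fixed)
    states, preds, errs = run_forward(
        A, b, rf, observed_mgas=obs, seen=v, felt=h, usable=use,
        error_sign=error_sign, excluded_policy=excluded_policy,
    )
    rmse = float(best_f)

    # flat-ridge diagnostic: if perturbing b barely moves the objective the
    # error-correction rate is unidentified (e.g. zero-perturbation block)
    db = 0.1
    probe = _block_rmse(
        np.array([A, min(1.0, b + db) if b < 0.5 else max(0.0, b - db), intercept]), *args
    )
    flat = abs(probe - rmse) < max(1e-6, 1e-4 * max(rmse, 1.0))

    return AdaptationFit(
        A=float(A), b=float(b), intercept=float(intercept), slope_fixed=float(slope_fixed),
        rmse=rmse, states=states, predicted=preds, errors=errs,
        n=int(obs.size), n_used=n_used, flat_ridge=bool(flat),
    )


def fit_response_slope(
    trial_table, participant_col: str = "participant",
    seen_col: str = "v_mm", mga_col: str = "mga_mm",
) -> tuple["pd.Series", float]:
    """Per-participant response slopes (MGA ~ seen size) and their mean.

    For each participant, apertures are averaged per seen size and an
    ordinary least-squares line fitted through the (size, mean aperture)
    pairs.  The across-participant mean slope is what block fits hold fixed.
    """
    import pandas as pd

    slopes = {}
    for pid, sub in trial_table.groupby(participant_col):
        means = sub.groupby(seen_col)[mga_col].mean()
        if means.size < 2:
            raise ValueError(f"participant {pid!r} has fewer than 2 distinct seen sizes")
        slope = np.polyfit(means.index.to_numpy(float), means.to_numpy(float), 1)[0]
        slopes[pid] = float(slope)
    series = pd.Series(slopes, name="slope")
    return series, float(series.mean())
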