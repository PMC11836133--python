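"""2AFC size-judgment analyses: percent correct, trends, and psychometric fits.

After each grasp the participant judges whether the felt object was larger
or smaller than the seen one.  A judgment is *correct* when it matches the
sign of the mismatch ``h - v``; zero-mismatch trials have no correct answer
and are excluded from correctness analyses.

Three views of detection performance:

* per-trial percent correct, averaged over participants, per schedule and
  magnitude (declining traces over perturbed trials indicate that
  adaptation masks the mismatch);
* participant-wise linear trends of percent correct over trials (OLS on
  binary 0/100 outcomes);
* per-participant psychometric functions — a cumulative normal
  ``P(felt larger | mismatch) = Phi((mismatch - PSE)/sigma)`` fitted by
  maximum likelihood, from which the just-noticeable difference (JND) is
  read off.

For sinusoidal blocks, per-trial percent correct confounds trial position
with the momentary magnitude; folding trials into a half-cycle (each
half-cycle contains every magnitude exactly once) removes the confound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "DetectionTrend",
    "score_responses",
    "percent_correct_by_trial",
    "fit_detection_trend",
    "fold_half_cycle",
    "fit_psychometric",
    "jnd_from_sigma",
]

#: JND conventions: distance from the PSE to the 84.1% point (= sigma), or
#: half the 25–75% spread (= 0.6745 * sigma)
JND_CONVENTIONS = {"sigma": 1.0, "half_interquartile": float(norm.ppf(0.75))}


def score_responses(trials: pd.DataFrame, *, mismatch_col: str = "mismatch_mm",
                    response_col: str = "response") -> pd.DataFrame:
    """Attach correctness to judgment trials.

    Adds ``felt_larger`` (bool) and ``correct`` (float: 1.0/0.0, NaN where the
    mismatch is zero and no correct answer exists).  Rows with a missing
    response are dropped with a warning.
    """
    out = trials.copy()
    missing = out[response_col].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} trials with missing responses")
        out = out[~missing].copy()
    out["felt_larger"] = out[response_col].eq("felt_larger")
    sign = np.sign(out[mismatch_col].to_numpy(float))
    said_larger = out["felt_larger"].to_numpy()
    correct = np.where(said_larger, sign > 0, sign < 0).astype(float)
    correct[sign == 0] = np.nan
    out["correct"] = correct
    return out


def percent_correct_by_trial(
    scored: pd.DataFrame,
    group_cols: tuple[str, ...] = ("schedule_kind", "magnitude"),
    trial_col: str = "trial",
) -> pd.DataFrame:
    """Mean percent correct per trial position across participants.

    Zero-mismatch trials (``correct`` NaN) drop out of the denominators; an
    empty cell yields NaN, not zero.
    """
    out = (
        scored.groupby([*group_cols, trial_col], sort=True)["correct"]
        .mean()
        .mul(100.0)
        .rename("percent_correct")
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class DetectionTrend:
    slope: float  # % correct per trial
    intercept: float  # %
    n_trials: int


def fit_detection_trend(
    correct: np.ndarray | pd.Series, trials: np.ndarray | pd.Series
) -> DetectionTrend:
    """OLS of per-trial correctness (as 0/100) on trial index.

    Zero-mismatch trials must already be NaN; they are dropped here.
    """
    c = np.asarray(correct, dtype=float) * 100.0
    t = np.asarray(trials, dtype=float)
    ok = ~np.isnan(c)
    c, t = c[ok], t[ok]
    if c.size < 3:
        raise ValueError(f"need at least 3 usable trials, got {c.size}")
    if np.ptp(t) == 0:
        raise ValueError("trial index is constant; trend undefined")
    slope, intercept = np.polyfit(t, c, 1)
    return DetectionTrend(slope=float(slope), intercept=float(intercept), n_trials=c.size)


def detection_trend_table(
    scored: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "schedule_kind", "magnitude"),
    trial_col: str = "trial",
) -> pd.DataFrame:
    """Participant-wise trend slopes per condition, tidy."""
    rows = []
    for keys, sub in scored.groupby(list(by)):
        tr = fit_detection_trend(sub["correct"], sub[trial_col])
        rows.append(dict(zip(by, keys)) | {
            "slope_pct_per_trial": tr.slope, "intercept_pct": tr.intercept,
            "n_trials": tr.n_trials,
        })
    return pd.DataFrame(rows)


def fold_half_cycle(
    scored: pd.DataFrame, period: int = 12, trial_col: str = "trial"
) -> pd.DataFrame:
    """Collapse sinusoidal-block trials onto positions within a half-cycle.

    Position ``p`` in 1..period/2 collects trials whose phase puts them at
    the same |mismatch| rung; each half-cycle contains every magnitude
    exactly once, so position and magnitude are not confounded.  Positions
    whose mismatch is exactly zero have undefined correctness (NaN).
    """
    if "schedule_kind" in scored.columns:
        kinds = set(scored["schedule_kind"].unique())
        if kinds - {"sinusoidal"}:
            raise ValueError(f"fold_half_cycle applies to sinusoidal blocks only, got {kinds}")
    if period % 2:
        raise ValueError("period must be even")
    half = period // 2
    pos = ((scored[trial_col].to_numpy(int) - 1) % half) + 1
    out = scored.copy()
    out["half_cycle_position"] = pos
    folded = (
        out.groupby("half_cycle_position")["correct"].mean().mul(100.0)
        .rename("percent_correct").reset_index()
    )
    folded["abs_mismatch_mean"] = [
        out.loc[out["half_cycle_position"] == p, "mismatch_mm"].abs().mean()
        for p in folded["half_cycle_position"]
    ]
    return folded


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-normal fit to P(felt larger) vs. mismatch."""

    pse: float  # mm, 50% point
    sigma: float  # mm, spread of the fitted normal
    jnd: float  # mm, per the chosen convention
    loglik: float
    n_trials: int
    separation_flag: bool = False  # data perfectly separated; sigma at bound


_SIGMA_MIN = 1e-2  # mm
_SIGMA_MAX = 1e3


def fit_psychometric(
    scored: pd.DataFrame,
    *,
    mismatch_col: str = "mismatch_mm",
    jnd_convention: str = "sigma",
) -> PsychometricFit:
    """Maximum-likelihood cumulative-normal psychometric function.

    Bernoulli likelihood of 'felt larger' responses at each mismatch; no
    lapse/guess parameters.  Perfect separation drives sigma to the lower
    bound and is flagged rather than raised.
    """
    x = scored[mismatch_col].to_numpy(float)
    y = scored["felt_larger"].to_numpy(bool)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct mismatch levels")
    if y.all() or (~y).all():
        # no information about the slope at all
        warnings.warn("all responses identical; psychometric fit degenerate")

    def nll(params):
        pse, log_sigma = params
        p = norm.cdf((x - pse) / np.exp(log_sigma))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(np.where(y, np.log(p), np.log1p(-p)))

    x0 = np.array([0.0, np.log(max(np.std(x), 1.0))])
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    pse, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    separation = sigma < _SIGMA_MIN or sigma > _SIGMA_MAX or y.all() or (~y).all()
    sigma = float(np.clip(sigma, _SIGMA_MIN, _SIGMA_MAX))
    return PsychometricFit(
        pse=pse, sigma=sigma, jnd=jnd_from_sigma(sigma, jnd_convention),
        loglik=-float(res.fun), n_trials=x.size, separation_flag=bool(separation),
    )


def jnd_from_sigma(sigma: float, convention: str = "sigma") -> float:
    """JND from the fitted spread under the chosen threshold convention."""
    try:
        return float(JND_CONVENTIONS[convention] * sigma)
    except KeyError:
        raise ValueError(
            f"unknown JND convention {convention!r}; options: {sorted(JND_CONVENTIONS)}"
        ) from None


def psychometric_table(
    scored: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "schedule_kind"),
    jnd_convention: str = "sigma",
) -> pd.DataFrame:
    """Per-participant, per-schedule psychometric parameters, tidy."""
    rows = []
    for keys, sub in scored.groupby(list(by)):
        fit = fit_psychometric(sub, jnd_convention=jnd_convention)
        rows.append(dict(zip(by, keys)) | {
            "pse_mm": fit.pse, "sigma_mm": fit.sigma, "jnd_mm": fit.jnd,
            "loglik": fit.loglik, "n_trials": fit.n_trials,
            "separation_flag": fit.separation_flag,
        })
    return pd.DataFrame(rows)
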