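"""End-to-end orchestration: simulate/import → preprocess → fit → detect → stats → report.

A *run* is a directory of tidy CSV tables plus a manifest recording the full
configuration and seed, so that every output is reproducible from the
manifest alone.  Stages can also be called individually on in-memory
tables; the CSVs are simply their serialised results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptation, kinematics, psychometrics, simulate, stats
from . import schedules as sched

log = logging.getLogger("graspadapt")

__all__ = ["RunConfig", "run_pipeline", "import_external", "report"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    experiment: str = "main"  # pilot | main
    n_participants: int = 12
    seed: int = 0
    # cohort generating parameters (None -> SimParticipant defaults)
    A_true: float = 0.95
    b_true: float = 0.2
    motor_noise_sd: float = 2.0
    obs_sigma: float = 4.0
    kappa: float = 1.0
    # preprocessing
    include_trajectories: bool = False
    # model fitting
    error_sign: str = "stable"  # stable | as_printed
    excluded_policy: str = "propagate_model"  # propagate_model | freeze_state
    slope_fixed: float | None = None  # None -> estimate from the data
    # psychometrics
    jnd_convention: str = "sigma"  # sigma | half_interquartile
    # stats
    t_prior_scale: float = 0.707
    r_prior_scale: float = 0.333
    bootstrap_reps: int = 10_000
    make_figures: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------- stages


def simulate_stage(config: RunConfig) -> simulate.SimulatedExperiment:
    base = simulate.SimParticipant(
        A_true=config.A_true, b_true=config.b_true,
        motor_noise_sd=config.motor_noise_sd, obs_sigma=config.obs_sigma,
        kappa=config.kappa,
    )
    cohort = simulate.make_cohort(config.n_participants, seed=config.seed, base=base)
    return simulate.simulate_experiment(
        cohort, config.experiment, include_trajectories=config.include_trajectories
    )


def preprocess_stage(
    sim: simulate.SimulatedExperiment, config: RunConfig
) -> pd.DataFrame:
    """Per-trial MGAs with exclusion flags.

    With marker recordings present, apertures are re-extracted through the
    kinematic chain; otherwise the tabled apertures are used directly.  The
    exclusion rules run per participant either way (the trajectory-based
    rules are vacuous without recordings).
    """
    trials = sim.trials.copy()
    if sim.trajectories:
        seg_rows = []
        for (pid, block, trial), traj in sim.trajectories.items():
            try:
                seg = kinematics.segment_trial(traj, (0.0, 0.0, 0.0), sim.experiment)
                seg_rows.append({
                    "participant": pid, "block": block, "trial": trial,
                    "mga_kin_mm": seg.mga_mm,
                    "movement_time_s": seg.movement_time_s,
                    "time_to_mga_s": seg.time_to_mga_s,
                    "mga_on_interpolated": bool(seg.interpolated_mask[seg.mga_index]),
                    "missing_fraction": seg.missing_fraction,
                })
            except (kinematics.SegmentationError, ValueError) as err:
                log.warning("trial (%s, %s, %s) unsegmentable: %s", pid, block, trial, err)
                seg_rows.append({
                    "participant": pid, "block": block, "trial": trial,
                    "mga_kin_mm": np.nan, "movement_time_s": np.nan,
                    "time_to_mga_s": np.nan, "mga_on_interpolated": False,
                    "missing_fraction": 1.0,
                })
        trials = trials.merge(pd.DataFrame(seg_rows), on=["participant", "block", "trial"])
        trials["mga_mm"] = trials["mga_kin_mm"]
    parts = [
        kinematics.apply_exclusions(sub) for _, sub in trials.groupby("participant")
    ]
    return pd.concat(parts).sort_index()


def fit_stage(trials: pd.DataFrame, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Response slopes, block-wise state-space fits, and Table-1-style CIs."""
    usable_tbl = trials[~trials["excluded"]]
    slopes, mean_slope = adaptation.fit_response_slope(usable_tbl)
    slope_fixed = config.slope_fixed if config.slope_fixed is not None else mean_slope

    fit_rows, state_rows = [], []
    for (pid, block), sub in trials.groupby(["participant", "block"]):
        sub = sub.sort_values("trial")
        fit = adaptation.fit_block(
            sub["mga_mm"].to_numpy(), slope_fixed=slope_fixed,
            seen=sub["v_mm"].to_numpy(), felt=sub["h_mm"].to_numpy(),
            usable=~sub["excluded"].to_numpy(),
            error_sign=config.error_sign, excluded_policy=config.excluded_policy,
        )
        fit_rows.append({
            "participant": pid, "block": block,
            "schedule_kind": sub["schedule_kind"].iloc[0],
            "magnitude": sub["magnitude"].iloc[0],
            "A": fit.A, "b": fit.b, "intercept": fit.intercept,
            "slope_fixed": slope_fixed, "rmse": fit.rmse,
            "n_trials": fit.n, "n_used": fit.n_used, "flat_ridge": fit.flat_ridge,
        })
        state_rows.append(pd.DataFrame({
            "participant": pid, "block": block, "trial": sub["trial"].to_numpy(),
            "state_x": fit.states, "mga_model_mm": fit.predicted,
            "error_mm": fit.errors,
        }))
    fits = pd.DataFrame(fit_rows)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ci_rows = []
    for (kind, mag), sub in fits.groupby(["schedule_kind", "magnitude"]):
        for param in ("A", "b"):
            lo, hi = stats.bootstrap_ci(
                sub[param].to_numpy(), reps=config.bootstrap_reps, seed=rng
            )
            ci_rows.append({
                "schedule_kind": kind, "magnitude": mag, "parameter": param,
                "mean": sub[param].mean(), "ci_lo": lo, "ci_hi": hi,
                "n_blocks": len(sub),
            })
    return {
        "fits": fits,
        "states": pd.concat(state_rows, ignore_index=True),
        "slopes": slopes.rename_axis("participant").reset_index(),
        "param_cis": pd.DataFrame(ci_rows),
    }


def detect_stage(trials: pd.DataFrame, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Correctness, per-trial traces, trend slopes, and psychometric fits."""
    scored = psychometrics.score_responses(trials[~trials["excluded"]])
    by_trial = psychometrics.percent_correct_by_trial(scored)
    trends = psychometrics.detection_trend_table(scored)
    psych = psychometrics.psychometric_table(scored, jnd_convention=config.jnd_convention)

    # Table-2 style: first perturbed abrupt trial vs maximum-magnitude
    # sinusoidal trials, per magnitude
    ab = scored[scored["schedule_kind"] == "abrupt"]
    first_pert = ab[ab["trial"] == 5].groupby(ab["magnitude"].abs())["correct"].mean() * 100
    si = scored[scored["schedule_kind"] == "sinusoidal"]
    at_peak = si[np.isclose(si["mismatch_mm"].abs(), si["magnitude"].abs())]
    peak_pc = at_peak.groupby(at_peak["magnitude"].abs())["correct"].mean() * 100
    table2 = pd.DataFrame({
        "abs_magnitude": first_pert.index,
        "abrupt_first_perturbed_pct": first_pert.to_numpy(),
        "sinusoidal_max_magnitude_pct": peak_pc.reindex(first_pert.index).to_numpy(),
    })
    return {"scored": scored, "percent_correct_by_trial": by_trial,
            "detection_trends": trends, "psychometric": psych,
            "first_vs_peak": table2}


def stats_stage(
    fit_out: dict[str, pd.DataFrame], det_out: dict[str, pd.DataFrame], config: RunConfig
) -> pd.DataFrame:
    """The study's inferential battery on the fitted quantities."""
    rows = []
    fits = fit_out["fits"]

    cell = fits.copy()
    cell["abs_magnitude"] = cell["magnitude"].abs()
    try:
        an = stats.rm_anova_2way(cell, "b", "participant", "schedule_kind", "abs_magnitude")
        for eff in (an.factor1, an.factor2, an.interaction):
            rows.append({"analysis": "rm_anova_b", "term": eff.name, "statistic": eff.F,
                         "df1": eff.df_num, "df2": eff.df_den, "p": eff.p, "bf10": None,
                         "estimate": None})
    except ValueError as err:
        log.warning("rmANOVA on b skipped: %s", err)

    b_means = fits.groupby(["participant", "schedule_kind"])["b"].mean().unstack()
    tt = stats.paired_t(b_means["abrupt"], b_means["sinusoidal"],
                        prior_scale=config.t_prior_scale)
    rows.append({"analysis": "paired_t_b_abrupt_vs_sinusoidal", "term": "difference",
                 "statistic": tt.t, "df1": tt.df, "df2": None, "p": tt.p,
                 "bf10": tt.bf10, "estimate": tt.cohens_d})

    psych = det_out["psychometric"]
    jnd = psych.pivot_table(index="participant", columns="schedule_kind",
                            values="jnd_mm")
    tt = stats.paired_t(jnd["abrupt"], jnd["sinusoidal"], prior_scale=config.t_prior_scale)
    rows.append({"analysis": "paired_t_jnd_abrupt_vs_sinusoidal", "term": "difference",
                 "statistic": tt.t, "df1": tt.df, "df2": None, "p": tt.p,
                 "bf10": tt.bf10, "estimate": tt.cohens_d})

    trends = det_out["detection_trends"]
    slope_means = trends.groupby(["participant", "schedule_kind"])[
        "slope_pct_per_trial"].mean().unstack()
    b_part = fits.groupby(["participant", "schedule_kind"])["b"].mean().unstack()
    for kind in ("abrupt", "sinusoidal"):
        for label, series in (("trend_slope", slope_means[kind]), ("jnd", jnd[kind])):
            try:
                cor = stats.pearson_with_bf(series, b_part[kind], config.r_prior_scale)
                dem = stats.deming_fit(series, b_part[kind])
            except (ValueError, RuntimeError) as err:
                # degenerate with very small cohorts (|r| = 1 at n = 2, etc.)
                log.warning("correlation %s/%s skipped: %s", label, kind, err)
                continue
            rows.append({"analysis": f"correlation_{label}_vs_b", "term": kind,
                         "statistic": cor["r"], "df1": cor["n"] - 2, "df2": None,
                         "p": cor["p"], "bf10": cor["bf10"], "estimate": dem.slope})
    return pd.DataFrame(rows)


def _make_figures(run_dir: Path, trials, fit_out, det_out) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    # mean baseline-corrected MGA per trial, per schedule (Fig.-2 style)
    t = trials.copy()
    base = t[t["mismatch_mm"] == 0].groupby("participant")["mga_mm"].mean()
    t["mga_bc"] = t["mga_mm"] - t["participant"].map(base)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, kind in zip(axes, ("abrupt", "sinusoidal")):
        sub = t[t["schedule_kind"] == kind]
        for mag, g in sub.groupby("magnitude"):
            tr = g.groupby("trial")["mga_bc"].mean()
            ax.plot(tr.index, tr.values, label=f"{mag:+g} mm", lw=1)
        ax.set_title(kind)
        ax.set_xlabel("trial")
    axes[0].set_ylabel("MGA - baseline (mm)")
    axes[1].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(fig_dir / "mga_by_trial.png", dpi=120)
    plt.close(fig)

    # percent correct over trials (Fig.-4 style)
    pc = det_out["percent_correct_by_trial"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, kind in zip(axes, ("abrupt", "sinusoidal")):
        sub = pc[pc["schedule_kind"] == kind]
        for mag, g in sub.groupby("magnitude"):
            ax.plot(g["trial"], g["percent_correct"], lw=1, label=f"{mag:+g} mm")
        ax.set_title(kind)
        ax.set_xlabel("trial")
    axes[0].set_ylabel("% correct")
    fig.tight_layout()
    fig.savefig(fig_dir / "percent_correct_by_trial.png", dpi=120)
    plt.close(fig)

    # JND per schedule (Fig.-5 style)
    psych = det_out["psychometric"]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    jnd = psych.pivot_table(index="participant", columns="schedule_kind", values="jnd_mm")
    for _, row in jnd.iterrows():
        ax.plot(["abrupt", "sinusoidal"], [row.get("abrupt"), row.get("sinusoidal")],
                color="grey", alpha=0.5, lw=0.8)
    ax.plot(["abrupt", "sinusoidal"], jnd.mean().reindex(["abrupt", "sinusoidal"]),
            "o-", color="red")
    ax.set_ylabel("JND (mm)")
    fig.tight_layout()
    fig.savefig(fig_dir / "jnd_by_schedule.png", dpi=120)
    plt.close(fig)


def run_pipeline(
    config: RunConfig, out_dir: str | Path, input_tables: pd.DataFrame | None = None
) -> Path:
    """Execute all stages and write a run directory.

    ``input_tables`` substitutes an imported (e.g. deposited) trial table for
    the simulation stage; it must carry the canonical columns (participant,
    block, schedule_kind, magnitude, trial, v_mm, h_mm, mga_mm, response).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run %s -> %s", config.config_hash, out)

    if input_tables is None:
        sim = simulate_stage(config)
    else:
        sim = simulate.SimulatedExperiment(
            trials=input_tables.copy(), trajectories={},
            experiment=config.experiment, seed=config.seed,
        )
    trials = preprocess_stage(sim, config)
    fit_out = fit_stage(trials, config)
    det_out = detect_stage(trials, config)
    stats_tbl = stats_stage(fit_out, det_out, config)

    trials.to_csv(out / "trials.csv", index=False)
    fit_out["fits"].to_csv(out / "fits.csv", index=False)
    fit_out["states"].to_csv(out / "states.csv", index=False)
    fit_out["slopes"].to_csv(out / "response_slopes.csv", index=False)
    fit_out["param_cis"].to_csv(out / "adaptation_parameters_ci.csv", index=False)
    det_out["percent_correct_by_trial"].to_csv(out / "percent_correct_by_trial.csv",
                                               index=False)
    det_out["detection_trends"].to_csv(out / "detection_trends.csv", index=False)
    det_out["psychometric"].to_csv(out / "psychometric.csv", index=False)
    det_out["first_vs_peak"].to_csv(out / "first_vs_peak_percent_correct.csv", index=False)
    stats_tbl.to_csv(out / "stats_report.csv", index=False)
    if config.make_figures:
        _make_figures(out, trials, fit_out, det_out)

    manifest = {"config": config.to_dict(), "config_hash": config.config_hash,
                "seed": config.seed,
                "n_trials": int(len(trials)),
                "exclusion_fraction": float(trials["excluded"].mean())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


REQUIRED_COLUMNS = ("participant", "block", "schedule_kind", "magnitude",
                    "trial", "v_mm", "h_mm", "response")


def import_external(
    path: str | Path, column_map: dict[str, str], mga_col: str | None = "mga_mm"
) -> pd.DataFrame:
    """Map an externally deposited trial table onto the canonical layout.

    ``column_map`` maps canonical names to the file's column names.  Unit
    sanity is enforced (sizes and apertures in mm within physiological
    range); violations raise with the offending field named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; place the deposited trial table there "
            "(merged data from the study's public archive) and supply a column map"
        )
    df = pd.read_csv(path, sep=None, engine="python")
    rename = {src: dst for dst, src in column_map.items()}
    missing_src = set(rename) - set(df.columns)
    if missing_src:
        raise ValueError(f"column(s) named in column_map absent from file: {sorted(missing_src)}")
    df = df.rename(columns=rename)
    need = list(REQUIRED_COLUMNS) + ([mga_col] if mga_col else [])
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"unmapped required column(s): {missing}")
    for col, lo, hi in (("v_mm", 10, 100), ("h_mm", 10, 100)):
        vals = df[col].astype(float)
        if not vals.between(lo, hi).all():
            raise ValueError(f"{col} outside {lo}-{hi} mm; are units really mm?")
    if mga_col:
        vals = df[mga_col].astype(float)
        if not vals.dropna().between(10, 200).all():
            raise ValueError(f"{mga_col} outside 10-200 mm; are units really mm?")
    log.info("imported %d trials from %s", len(df), path)
    return df


def infer_sampling_rate(t_s: np.ndarray) -> float:
    """Sampling rate from timestamp spacing (median of dt, Hz)."""
    dt = np.diff(np.sort(np.asarray(t_s, float)))
    dt = dt[dt > 0]
    if dt.size == 0:
        raise ValueError("cannot infer sampling rate from constant timestamps")
    return float(1.0 / np.median(dt))


def report(run_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{run_dir} has no manifest.json; incomplete run?")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# graspadapt run summary",
        "",
        f"- config hash: `{manifest['config_hash']}`, seed {manifest['seed']}",
        f"- trials: {manifest['n_trials']}, excluded fraction "
        f"{manifest['exclusion_fraction']:.3f}",
        "",
    ]
    fits_path = run_dir / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        g = fits.groupby("schedule_kind")[["A", "b", "rmse"]].mean()
        lines.append("## Adaptation fits (means per schedule)")
        lines.append("")
        lines.append(g.round(3).to_markdown())
        lines.append("")
    psych_path = run_dir / "psychometric.csv"
    if psych_path.exists():
        psych = pd.read_csv(psych_path)
        g = psych.groupby("schedule_kind")["jnd_mm"].agg(["mean", "std"])
        lines.append("## Detection (JND per schedule, mm)")
        lines.append("")
        lines.append(g.round(2).to_markdown())
        lines.append("")
    else:
        lines.append("## Detection: absent from this run")
        lines.append("")
    stats_path = run_dir / "stats_report.csv"
    if stats_path.exists():
        lines.append("## Inferential statistics")
        lines.append("")
        lines.append(pd.read_csv(stats_path).round(4).to_markdown(index=False))
        lines.append("")
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
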