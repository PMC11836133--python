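"""Inferential toolbox: repeated-measures ANOVA, paired tests, JZS Bayes
factors, Deming regression, and percentile-bootstrap intervals.

The two-way repeated-measures ANOVA uses the classical fully-within-subject
decomposition: each effect (factor 1, factor 2, interaction) is tested
against its own effect-by-participant interaction.  No sphericity
correction is applied by default (Greenhouse–Geisser is available).

Bayes factors follow the default-prior ("JZS") conventions: a Cauchy prior
of scale r on the standardised effect for t-tests, and a stretched-beta
prior of width r on the population correlation for correlation tests; both
marginal likelihoods are computed by numerical integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "RmAnovaEffect",
    "RmAnovaResult",
    "PairedTestResult",
    "DemingFit",
    "rm_anova_2way",
    "paired_t",
    "bf10_ttest",
    "bf10_correlation",
    "pearson_with_bf",
    "deming_fit",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class RmAnovaEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    ss_effect: float
    ss_error: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass(frozen=True)
class RmAnovaResult:
    factor1: RmAnovaEffect
    factor2: RmAnovaEffect
    interaction: RmAnovaEffect

    def to_frame(self) -> pd.DataFrame:
        rows = [self.factor1, self.factor2, self.interaction]
        return pd.DataFrame(
            [{"effect": e.name, "F": e.F, "df_num": e.df_num, "df_den": e.df_den,
              "p": e.p, "p_gg": e.p_gg} for e in rows]
        )


def _gg_epsilon(cell_matrix: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a subjects x conditions matrix."""
    S = np.cov(cell_matrix, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factor1: str,
    factor2: str,
    gg_correction: bool = False,
) -> RmAnovaResult:
    """Two-way fully repeated-measures ANOVA.

    Requires a complete balanced design: every participant contributes one
    value per (factor1, factor2) cell (replicate observations are averaged
    per cell first).  Each effect is tested against its interaction with
    participants.
    """
    cells = (
        data.groupby([subject, factor1, factor2])[dv].mean().rename("y").reset_index()
    )
    subjects = np.sort(cells[subject].unique())
    l1 = np.sort(cells[factor1].unique())
    l2 = np.sort(cells[factor2].unique())
    n, a, b = len(subjects), len(l1), len(l2)
    if len(cells) != n * a * b:
        missing = n * a * b - len(cells)
        raise ValueError(
            f"incomplete design: expected {n * a * b} cells "
            f"({n} subjects x {a} x {b} levels), {missing} missing"
        )
    y = (
        cells.pivot_table(index=subject, columns=[factor1, factor2], values="y")
        .loc[subjects]
        .to_numpy(float)
        .reshape(n, a, b)
    )

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_1 = y.mean(axis=(0, 2))
    m_2 = y.mean(axis=(0, 1))
    m_s1 = y.mean(axis=2)
    m_s2 = y.mean(axis=1)
    m_12 = y.mean(axis=0)

    ss_1 = n * b * np.sum((m_1 - grand) ** 2)
    ss_2 = n * a * np.sum((m_2 - grand) ** 2)
    ss_12 = n * np.sum((m_12 - m_1[:, None] - m_2[None, :] + grand) ** 2)
    ss_s1 = b * np.sum((m_s1 - m_s[:, None] - m_1[None, :] + grand) ** 2)
    ss_s2 = a * np.sum((m_s2 - m_s[:, None] - m_2[None, :] + grand) ** 2)
    ss_s12 = np.sum(
        (y - m_s1[:, :, None] - m_s2[:, None, :] - m_12[None, :, :]
         + m_s[:, None, None] + m_1[None, :, None] + m_2[None, None, :] - grand) ** 2
    )

    def effect(name, ss_eff, df_eff, ss_err, df_err, cond_matrix):
        F = (ss_eff / df_eff) / (ss_err / df_err) if ss_err > 0 else (
            np.inf if ss_eff > 0 else 0.0
        )
        p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        eps = p_gg = None
        if gg_correction:
            eps = _gg_epsilon(cond_matrix)
            p_gg = float(sps.f.sf(F, df_eff * eps, df_err * eps))
        return RmAnovaEffect(name, float(F), int(df_eff), int(df_err), p,
                             float(ss_eff), float(ss_err), eps, p_gg)

    return RmAnovaResult(
        factor1=effect(factor1, ss_1, a - 1, ss_s1, (n - 1) * (a - 1), m_s1),
        factor2=effect(factor2, ss_2, b - 1, ss_s2, (n - 1) * (b - 1), m_s2),
        interaction=effect(
            f"{factor1}:{factor2}", ss_12, (a - 1) * (b - 1), ss_s12,
            (n - 1) * (a - 1) * (b - 1), y.reshape(n, a * b),
        ),
    )


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    bf10: float | None = None


def paired_t(x, y, prior_scale: float | None = None) -> PairedTestResult:
    """Two-sided paired t-test with Cohen's d = t / sqrt(n).

    Passing ``prior_scale`` also computes the JZS Bayes factor for the
    difference.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.all(d == 0.0):
        # identical samples: no effect, by convention t = 0
        return PairedTestResult(t=0.0, df=n - 1, p=1.0, cohens_d=0.0, mean_diff=0.0,
                                bf10=bf10_ttest(0.0, n, prior_scale) if prior_scale else None)
    if np.isclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of non-zero differences; t undefined")
    res = sps.ttest_rel(x, y)
    t = float(res.statistic)
    out_bf = bf10_ttest(t, n, prior_scale) if prior_scale is not None else None
    return PairedTestResult(
        t=t, df=n - 1, p=float(res.pvalue), cohens_d=t / np.sqrt(n),
        mean_diff=float(d.mean()), bf10=out_bf,
    )


def bf10_ttest(t: float, n: int, prior_scale: float = 0.707) -> float:
    """JZS Bayes factor for a one-sample / paired t statistic.

    Marginal likelihood of the data under a Cauchy(0, r) prior on the
    standardised effect delta (noncentral-t likelihood with noncentrality
    sqrt(n)*delta), divided by the point-null central-t likelihood.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    nu = n - 1
    rt_n = np.sqrt(n)

    def integrand(delta):
        return sps.nct.pdf(t, nu, rt_n * delta) * sps.cauchy.pdf(delta, 0.0, prior_scale)

    m1, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if m1 <= 0 or not np.isfinite(m1) or err > max(1e-8, 1e-4 * m1):
        raise RuntimeError(f"marginal-likelihood integration failed (m1={m1}, err={err})")
    return float(m1 / sps.t.pdf(t, nu))


def _r_density(r: float, rho: float, n: int) -> float:
    """Sampling density of the Pearson correlation r given rho (Hotelling)."""
    log_c = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - special.gammaln(n - 0.5)
        - 0.5 * np.log(2 * np.pi)
        + ((n - 1) / 2) * np.log1p(-rho**2)
        + ((n - 4) / 2) * np.log1p(-r**2)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(log_c) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def bf10_correlation(r_obs: float, n: int, prior_scale: float = 0.333) -> float:
    """Bayes factor for a Pearson correlation under a stretched-beta prior.

    The prior on rho is symmetric on (-1, 1) with density proportional to
    ``(1 - rho^2)^(1/prior_scale - 1)`` (width 1 = uniform); the marginal
    likelihood integrates the exact sampling density of r over it.
    """
    if not -1.0 < r_obs < 1.0:
        raise ValueError("r_obs must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4 for a proper correlation Bayes factor")
    alpha = 1.0 / prior_scale

    def prior(rho):
        return (1 - rho**2) ** (alpha - 1) / (2 ** (2 * alpha - 1) * special.beta(alpha, alpha))

    m1, err = integrate.quad(
        lambda rho: _r_density(r_obs, rho, n) * prior(rho), -1.0, 1.0, limit=200
    )
    m0 = _r_density(r_obs, 0.0, n)
    if m1 <= 0 or m0 <= 0 or not np.isfinite(m1):
        raise RuntimeError("correlation Bayes-factor integration failed")
    return float(m1 / m0)


def pearson_with_bf(x, y, prior_scale: float = 0.333) -> dict:
    """Pearson r, two-sided p, and the default-prior Bayes factor."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = sps.pearsonr(x, y)
    return {
        "r": float(res.statistic), "p": float(res.pvalue), "n": x.size,
        "bf10": bf10_correlation(float(res.statistic), x.size, prior_scale),
    }


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    variance_ratio: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x)


def deming_fit(x, y, variance_ratio: float = 1.0) -> DemingFit:
    """Errors-in-variables straight line (Deming regression).

    ``variance_ratio`` is lambda = var(error in y) / var(error in x); with
    lambda = 1 the fit minimises perpendicular distances (orthogonal
    regression).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 and syy == 0:
        raise ValueError("both variables are constant; line undefined")
    lam = variance_ratio
    if sxy == 0:
        slope = 0.0 if syy <= lam * sxx else np.inf
        if not np.isfinite(slope):
            raise ValueError("vertical line (x constant); slope undefined")
    else:
        slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (
            2 * sxy
        )
    intercept = y.mean() - slope * x.mean()
    return DemingFit(slope=float(slope), intercept=float(intercept), variance_ratio=lam)


def bootstrap_ci(
    values,
    statistic=np.mean,
    reps: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of one sample."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    boot = np.apply_along_axis(statistic, 1, values[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
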