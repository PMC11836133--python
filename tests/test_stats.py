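import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from graspadapt import stats as gstats


def _long(y, subjects, l1, l2):
    """y indexed [subject, f1, f2] -> long frame."""
    rows = []
    for i, s in enumerate(subjects):
        for j, a in enumerate(l1):
            for k, b in enumerate(l2):
                rows.append({"sub": s, "f1": a, "f2": b, "y": y[i, j, k]})
    return pd.DataFrame(rows)


def _brute_force_ss(y):
    """Textbook sums of squares for a fully within-subject two-way design."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {}
    ss["f1"] = sum(n * b * (y[:, j, :].mean() - grand) ** 2 for j in range(a))
    ss["f2"] = sum(n * a * (y[:, :, k].mean() - grand) ** 2 for k in range(b))
    ss["f1f2"] = sum(
        n * (y[:, j, k].mean() - y[:, j, :].mean() - y[:, :, k].mean() + grand) ** 2
        for j, k in itertools.product(range(a), range(b))
    )
    ss["sf1"] = sum(
        b * (y[i, j, :].mean() - y[i].mean() - y[:, j, :].mean() + grand) ** 2
        for i, j in itertools.product(range(n), range(a))
    )
    ss["sf2"] = sum(
        a * (y[i, :, k].mean() - y[i].mean() - y[:, :, k].mean() + grand) ** 2
        for i, k in itertools.product(range(n), range(b))
    )
    ss["sf1f2"] = sum(
        (y[i, j, k] - y[i, j, :].mean() - y[i, :, k].mean() - y[:, j, k].mean()
         + y[i].mean() + y[:, j, :].mean() + y[:, :, k].mean() - grand) ** 2
        for i, j, k in itertools.product(range(n), range(a), range(b))
    )
    return ss


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        y = np.full((5, 2, 3), 7.0)
        res = gstats.rm_anova_2way(_long(y, range(5), "ab", "xyz"),
                                   "y", "sub", "f1", "f2")
        assert res.factor1.F == 0.0 and res.factor2.F == 0.0
        assert res.interaction.F == 0.0

    @pytest.mark.parametrize("shape", [(3, 2, 2), (6, 2, 3), (5, 4, 4)])
    def test_matches_brute_force_decomposition(self, shape, rng):
        y = rng.normal(50, 5, size=shape)
        n, a, b = shape
        res = gstats.rm_anova_2way(
            _long(y, range(n), [f"a{j}" for j in range(a)],
                  [f"b{k}" for k in range(b)]), "y", "sub", "f1", "f2"
        )
        ss = _brute_force_ss(y)
        f1 = (ss["f1"] / (a - 1)) / (ss["sf1"] / ((n - 1) * (a - 1)))
        f2 = (ss["f2"] / (b - 1)) / (ss["sf2"] / ((n - 1) * (b - 1)))
        f12 = (ss["f1f2"] / ((a - 1) * (b - 1))) / (
            ss["sf1f2"] / ((n - 1) * (a - 1) * (b - 1)))
        assert res.factor1.F == pytest.approx(f1)
        assert res.factor2.F == pytest.approx(f2)
        assert res.interaction.F == pytest.approx(f12)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, size=(8, 2, 3))
        df = _long(y, range(8), "ab", "xyz")
        res = gstats.rm_anova_2way(df, "y", "sub", "f1", "f2")
        ref = pg.rm_anova(data=df, dv="y", within=["f1", "f2"], subject="sub")
        for eff, name in ((res.factor1, "f1"), (res.factor2, "f2"),
                          (res.interaction, "f1 * f2")):
            row = ref[ref["Source"] == name].iloc[0]
            assert eff.F == pytest.approx(row["F"], rel=1e-6)
            assert eff.p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_study_design_degrees_of_freedom(self, rng):
        # 23 participants, schedule (2) x magnitude (3): dfs (1,22) and (2,44)
        y = rng.normal(0.3, 0.1, size=(23, 2, 3))
        res = gstats.rm_anova_2way(_long(y, range(23), "ab", "xyz"),
                                   "y", "sub", "f1", "f2")
        assert (res.factor1.df_num, res.factor1.df_den) == (1, 22)
        assert (res.factor2.df_num, res.factor2.df_den) == (2, 44)
        assert (res.interaction.df_num, res.interaction.df_den) == (2, 44)

    def test_participant_order_invariance(self, rng):
        y = rng.normal(0, 1, size=(6, 2, 3))
        df = _long(y, range(6), "ab", "xyz")
        shuffled = df.sample(frac=1.0, random_state=1)
        a = gstats.rm_anova_2way(df, "y", "sub", "f1", "f2")
        b = gstats.rm_anova_2way(shuffled, "y", "sub", "f1", "f2")
        assert a.factor1.F == pytest.approx(b.factor1.F)
        assert a.interaction.F == pytest.approx(b.interaction.F)

    def test_missing_cell_refused(self, rng):
        y = rng.normal(0, 1, size=(4, 2, 2))
        df = _long(y, range(4), "ab", "xy").iloc[:-1]
        with pytest.raises(ValueError, match="incomplete design"):
            gstats.rm_anova_2way(df, "y", "sub", "f1", "f2")


class TestPairedT:
    def test_identical_samples(self):
        res = gstats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_hand_computed_differences(self):
        # d = {1,2,3}: t = mean/(sd/sqrt(3)) = 2/(1/sqrt(3)) = 2*sqrt(3)
        res = gstats.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    @pytest.mark.parametrize("t, n, printed_d", [(2.76, 23, 0.6), (5.25, 48, 0.8)])
    def test_cohens_d_matches_printed_values(self, t, n, printed_d):
        assert t / np.sqrt(n) == pytest.approx(printed_d, abs=0.05)

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            gstats.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def _bf_g_integral(t, n, r):
    """Independent JZS route: Zellner–Siow as a mixture of g-priors.

    Cauchy(0, r) on the effect equals an inverse-gamma(1/2, r^2/2) mixture
    over the variance g of a normal prior, giving the one-dimensional
    integral over g of the classic Rouder form.
    """
    nu = n - 1

    def integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
            * sps.invgamma.pdf(g, 0.5, scale=r**2 / 2)
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


class TestBayesFactors:
    def test_null_t_favours_null(self):
        assert gstats.bf10_ttest(0.0, 23) < 1.0

    def test_pilot_jnd_comparison_value(self):
        assert gstats.bf10_ttest(2.76, 23, 0.707) == pytest.approx(4.4, abs=0.1)

    def test_agrees_with_g_prior_mixture_route(self):
        for t, n in ((1.0, 10), (2.76, 23), (3.5, 40)):
            a = gstats.bf10_ttest(t, n, 0.707)
            b = _bf_g_integral(t, n, 0.707)
            assert a == pytest.approx(b, rel=1e-4)

    def test_monotone_in_effect_size(self):
        bfs = [gstats.bf10_ttest(t, 23, 0.707) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert np.all(np.diff(bfs) > 0)

    def test_null_correlation_favours_null(self):
        assert gstats.bf10_correlation(0.0, 40) < 1.0

    def test_correlation_bf_symmetric_in_sign(self):
        a = gstats.bf10_correlation(0.35, 30)
        b = gstats.bf10_correlation(-0.35, 30)
        assert a == pytest.approx(b, rel=1e-6)

    def test_correlation_bf_grows_with_evidence(self):
        assert (gstats.bf10_correlation(0.8, 40)
                > gstats.bf10_correlation(0.4, 40)
                > gstats.bf10_correlation(0.1, 40))

    def test_pearson_with_bf_consistent_with_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        out = gstats.pearson_with_bf(x, y)
        ref = sps.pearsonr(x, y)
        assert out["r"] == pytest.approx(ref.statistic)
        assert out["p"] == pytest.approx(ref.pvalue)
        assert out["bf10"] > 0


class TestDeming:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = gstats.deming_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_swap_symmetric_data_has_unit_slope(self, rng):
        # augmenting with the swapped pairs forces equal sample variances, for
        # which the orthogonal (lambda = 1) slope is exactly the geometric
        # mean of the two directional OLS slopes, i.e. 1
        x = rng.normal(0, 2, 40)
        y = x + rng.normal(0, 1, 40)
        X = np.concatenate([x, y])
        Y = np.concatenate([y, x])
        fit = gstats.deming_fit(X, Y)
        b_yx = np.cov(X, Y)[0, 1] / np.var(X, ddof=1)
        b_xy = np.cov(X, Y)[0, 1] / np.var(Y, ddof=1)
        assert fit.slope == pytest.approx(np.sqrt(b_yx / b_xy))
        assert fit.slope == pytest.approx(1.0)

    def test_axis_swap_inverts_the_line(self, rng):
        x = rng.normal(size=50)
        y = 1.7 * x + rng.normal(scale=0.3, size=50)
        f = gstats.deming_fit(x, y)
        g = gstats.deming_fit(y, x)
        assert g.slope == pytest.approx(1 / f.slope, rel=1e-9)

    def test_agrees_with_orthogonal_distance_regression(self, rng):
        odr = pytest.importorskip("scipy.odr")
        x = rng.normal(0, 3, 60)
        y = 0.8 * x + 2 + rng.normal(0, 1, 60)
        fit = gstats.deming_fit(x, y)
        model = odr.ODR(odr.Data(x, y), odr.unilinear, beta0=[1.0, 0.0]).run()
        assert fit.slope == pytest.approx(model.beta[0], rel=1e-3)
        assert fit.intercept == pytest.approx(model.beta[1], abs=1e-2)

    def test_degenerate_input(self):
        with pytest.raises(ValueError, match="constant"):
            gstats.deming_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestBootstrap:
    def test_constant_sample_degenerate_interval(self):
        lo, hi = gstats.bootstrap_ci([5.0] * 20, seed=0)
        assert lo == hi == 5.0

    def test_deterministic_under_seed(self, rng):
        vals = rng.normal(size=40)
        assert gstats.bootstrap_ci(vals, seed=7) == gstats.bootstrap_ci(vals, seed=7)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            sample = rng.normal(size=100)
            lo, hi = gstats.bootstrap_ci(sample, reps=400, seed=rng)
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / n_rep <= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gstats.bootstrap_ci([])
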