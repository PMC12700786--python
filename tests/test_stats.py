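import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from thalcortex.stats import (StatsConfig, adjusted_r2, cluster_mcs, fdr_bh,
                              linreg_trend, perm_anova, perm_posthoc,
                              perm_spearman, perm_ttest_paired, r2_from_f,
                              shapiro_wilk)


def cfg(n=1000, seed=0, **kw):
    return StatsConfig(n_permutations=n, seed=seed, **kw)


class TestConfig:
    def test_bounds(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=0.0)
        with pytest.raises(ValueError):
            StatsConfig(n_permutations=10)


class TestPairedTTest:
    def test_identical_samples(self):
        x = np.arange(5.0)
        res = perm_ttest_paired(x, x, cfg())
        assert res.statistic == 0.0
        assert res.p_mc == 1.0
        assert res.flags

    def test_large_shift_hits_resolution_floor(self, rng):
        x = rng.standard_normal(12)
        res = perm_ttest_paired(x + 10.0, x + 0.001 * rng.standard_normal(12),
                                cfg(2000))
        assert res.p_mc <= 2 / 2001

    def test_monte_carlo_matches_exact_enumeration(self, rng):
        """n=5: all 32 sign patterns enumerated as the oracle."""
        for trial in range(5):
            x = rng.standard_normal(5)
            y = rng.standard_normal(5)
            d = x - y
            ts = []
            for signs in itertools.product([-1, 1], repeat=5):
                dd = d * np.array(signs)
                ts.append(dd.mean() / (dd.std(ddof=1) / math.sqrt(5)))
            t_obs = d.mean() / (d.std(ddof=1) / math.sqrt(5))
            p_exact = np.mean(np.abs(ts) >= abs(t_obs) - 1e-12)
            res = perm_ttest_paired(x, y, cfg(5000, seed=trial))
            assert res.p_mc == pytest.approx(p_exact, abs=0.02)

    def test_p_never_zero(self, rng):
        res = perm_ttest_paired(np.full(6, 100.0), np.zeros(6), cfg(500))
        assert res.p_mc >= 1 / 501

    def test_null_p_values_uniform(self):
        """KS check of p under the null (sign-symmetric differences)."""
        master = np.random.default_rng(99)
        ps = []
        for i in range(500):
            x = master.standard_normal(10)
            y = master.standard_normal(10)
            ps.append(perm_ttest_paired(x, y, cfg(300, seed=i)).p_mc)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            perm_ttest_paired([1.0, 2.0], [1.0], cfg())


class TestPermAnova:
    A = np.array(["a1"] * 4 + ["a2"] * 4)
    B = np.array(["b1", "b1", "b2", "b2"] * 2)

    def test_hand_computed_two_by_two(self):
        # docs/methods.md worked example: cell means 1.5/1.5/5.5/5.5,
        # SS_A = 32, SSE = 2 on 4 df -> F_A = 64
        y = np.array([1.0, 2.0, 1.0, 2.0, 5.0, 6.0, 5.0, 6.0])
        res = perm_anova(y, {"A": self.A, "B": self.B}, cfg(500))
        assert res[("A",)].statistic == pytest.approx(64.0)
        assert res[("B",)].statistic == pytest.approx(0.0)
        assert res[("A", "B")].statistic == pytest.approx(0.0)
        assert res[("A",)].df == (1, 4)

    def test_main_effect_p_matches_exact_enumeration(self):
        """All C(8,4)=70 label assignments enumerated as the oracle."""
        rng = np.random.default_rng(5)
        y = rng.standard_normal(8) + np.where(self.A == "a2", 1.5, 0.0)
        fs = []
        for pos in itertools.combinations(range(8), 4):
            lab = np.array(["a2"] * 8, dtype=object)
            for p in pos:
                lab[p] = "a1"
            from thalcortex.stats import _anova_f
            out, _ = _anova_f(y, {"A": lab, "B": self.B},
                              [("A",), ("B",), ("A", "B")],
                              test_terms=[("A",)])
            fs.append(out[("A",)][0])
        from thalcortex.stats import _anova_f
        obs = _anova_f(y, {"A": self.A, "B": self.B},
                       [("A",), ("B",), ("A", "B")],
                       test_terms=[("A",)])[0][("A",)][0]
        p_exact = np.mean(np.asarray(fs) >= obs - 1e-12)
        res = perm_anova(y, {"A": self.A, "B": self.B}, cfg(4000, seed=1))
        assert res[("A",)].p_mc == pytest.approx(p_exact, abs=0.02)

    def test_identical_groups_yield_unit_p(self):
        y = np.ones(8)
        res = perm_anova(y, {"A": self.A, "B": self.B}, cfg(200))
        for r in res.values():
            assert r.statistic == 0.0
            assert r.p_mc == 1.0

    def test_empty_cell_rejected(self):
        y = np.zeros(4)
        with pytest.raises(ValueError, match="empty"):
            perm_anova(y, {"A": ["a1", "a1", "a2", "a2"],
                           "B": ["b1", "b1", "b1", "b2"]}, cfg(200))

    def test_null_rejection_rate_is_nominal(self):
        """Type-I error of the main-effect test at alpha = 0.05."""
        master = np.random.default_rng(17)
        A = np.repeat(["a1", "a2"], 8)
        B = np.tile(["b1", "b2"], 8)
        rejections = 0
        runs = 300
        for i in range(runs):
            y = master.standard_normal(16)
            res = perm_anova(y, {"A": A, "B": B}, cfg(150, seed=i),
                             terms=[("A",), ("B",), ("A", "B")])
            rejections += res[("A",)].p_mc <= 0.05
        rate = rejections / runs
        # binomial 95% CI half-width at p=.05, n=300 is ~0.025
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_three_way_balanced_against_statsmodels(self):
        """Observed Type II F statistics cross-checked with statsmodels OLS."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(2)
        n_h = 6
        cond = np.tile(np.repeat(["orig", "surr"], 3), n_h)
        freq = np.tile(["theta", "alpha", "beta"], 2 * n_h)
        hemi = np.repeat(["L", "R"], 18)
        y = rng.standard_normal(cond.size) + (cond == "orig") * 0.8
        res = perm_anova(y, {"c": cond, "f": freq, "h": hemi}, cfg(150, seed=0))
        df = pd.DataFrame({"y": y, "c": cond, "f": freq, "h": hemi})
        fit = ols("y ~ C(c) * C(f) * C(h)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res[("c",)].statistic == pytest.approx(tab.loc["C(c)", "F"])
        assert res[("c", "f")].statistic == pytest.approx(
            tab.loc["C(c):C(f)", "F"])
        assert res[("c", "f", "h")].statistic == pytest.approx(
            tab.loc["C(c):C(f):C(h)", "F"])


class TestPosthoc:
    def test_identical_cells(self):
        y = np.concatenate([np.ones(5), np.ones(5)])
        labels = np.array(["x"] * 5 + ["y"] * 5)
        res = perm_posthoc(y, labels, cfg(300))[0]
        assert res.statistic == 0.0
        assert res.p_mc == 1.0

    def test_shifted_cell_detected(self, rng):
        y = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(3, 0.1, 6)])
        labels = np.array(["x"] * 6 + ["y"] * 6)
        res = perm_posthoc(y, labels, cfg(1000))[0]
        assert res.p_mc < 0.01
        assert res.statistic == pytest.approx(-3.0, abs=0.2)

    def test_matches_exact_enumeration_at_4_plus_4(self, rng):
        y = rng.standard_normal(8)
        labels = np.array(["x"] * 4 + ["y"] * 4)
        diffs = []
        for pos in itertools.combinations(range(8), 4):
            sel = np.zeros(8, dtype=bool)
            sel[list(pos)] = True
            diffs.append(y[sel].mean() - y[~sel].mean())
        obs = y[:4].mean() - y[4:].mean()
        p_exact = np.mean(np.abs(diffs) >= abs(obs) - 1e-12)
        res = perm_posthoc(y, labels, cfg(4000, seed=3))[0]
        assert res.p_mc == pytest.approx(p_exact, abs=0.02)

    def test_tiny_cell_rejected(self):
        with pytest.raises(ValueError):
            perm_posthoc(np.arange(3.0), np.array(["x", "y", "y"]), cfg(200))


class TestFdrBH:
    def test_textbook_example(self):
        rejected, adj = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert np.allclose(adj, 0.04)
        assert rejected.all()

    def test_single_p_unchanged(self):
        _, adj = fdr_bh([0.2])
        assert adj[0] == pytest.approx(0.2)

    def test_all_ones_reject_nothing(self):
        rejected, _ = fdr_bh([1.0, 1.0, 1.0])
        assert not rejected.any()

    def test_adjusted_at_least_raw_and_never_more_rejections(self, rng):
        p = rng.uniform(size=50)
        rejected, adj = fdr_bh(p, q=0.05)
        assert np.all(adj >= p - 1e-15)
        assert rejected.sum() <= (p <= 0.05).sum()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestClusterMCS:
    def test_saturated_series_forms_single_maximal_cluster(self):
        # with every window significant the shuffled null reproduces the
        # full-length run identically, so the cluster cannot exceed the
        # null's 99.9th percentile — the correction is degenerate there
        res = cluster_mcs(np.full(50, 0.001), cfg(2000))
        assert res.clusters == [(0, 50, 50)]
        assert res.threshold_size == 50.0
        assert res.significant == [False]

    def test_nearly_saturated_run_is_significant(self):
        p = np.full(50, 0.5)
        p[2:48] = 0.001
        res = cluster_mcs(p, cfg(2000, seed=2))
        assert res.clusters == [(2, 48, 46)]
        assert res.significant == [True]

    def test_no_significant_windows(self):
        res = cluster_mcs(np.full(50, 0.5), cfg(500))
        assert res.clusters == []

    def test_long_run_flagged_isolated_singles_not(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.06, 1.0, size=116)
        p[40:70] = 0.01          # one 30-window cluster
        p[5] = 0.01              # isolated significant window
        p[100] = 0.01
        res = cluster_mcs(p, cfg(2000, seed=0))
        by_size = {c[2]: s for c, s in zip(res.clusters, res.significant)}
        assert by_size[30] is True
        assert by_size[1] is False

    def test_threshold_is_999th_percentile(self):
        res = cluster_mcs(np.full(20, 0.01), cfg(2000, seed=1))
        assert res.threshold_size == pytest.approx(
            np.percentile(res.null_max_sizes, 99.9))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cluster_mcs([0.01], cfg(200))


class TestPermSpearman:
    def test_printed_rank_configuration(self):
        res = perm_spearman([1, 2, 3, 4, 5, 6], [5, 6, 4, 3, 1, 2])
        assert res.rho == pytest.approx(-0.8857, abs=1e-4)
        assert res.exact
        assert res.p == pytest.approx(24 / 720)

    def test_perfect_monotone(self):
        res = perm_spearman([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(2 / 720)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            perm_spearman([1, 2, 3], [5, 5, 5])

    def test_ties_use_average_ranks(self):
        x = [1, 2, 2, 4, 5, 6]
        y = [3, 1, 4, 1, 5, 9]
        res = perm_spearman(x, y)
        assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_monte_carlo_path_for_larger_n(self, rng):
        x = rng.standard_normal(20)
        y = x + 0.5 * rng.standard_normal(20)
        res = perm_spearman(x, y, cfg(3000, seed=2))
        assert not res.exact
        assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic)
        assert res.p == pytest.approx(sps.spearmanr(x, y).pvalue, abs=0.02)


class TestTrend:
    def test_perfect_line(self):
        t = np.linspace(-1.8, 0.0, 451)
        res = linreg_trend(t, 3.0 - 2.0 * t, cfg(200))
        assert res.r2_adjusted == pytest.approx(1.0)
        assert res.slope == pytest.approx(-2.0)
        assert res.df == (1, 449)

    def test_null_adjusted_r2_near_zero(self, rng):
        t = np.linspace(-1.8, 0.0, 451)
        res = linreg_trend(t, rng.standard_normal(451), cfg(200))
        assert abs(res.r2_adjusted) < 0.02

    def test_f_r2_identity(self, rng):
        t = rng.standard_normal(100)
        v = 0.3 * t + rng.standard_normal(100)
        res = linreg_trend(t, v, cfg(200))
        assert res.r2 == pytest.approx(r2_from_f(res.F, 98))

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linreg_trend(np.ones(10), np.arange(10.0), cfg(200))

    def test_adjusted_r2_can_be_negative(self):
        assert adjusted_r2(r2_from_f(0.0, 449), 451) < 0.0


class TestShapiroGate:
    def test_reports_without_branching(self, rng):
        W, p = shapiro_wilk(rng.standard_normal(30))
        assert 0 < W <= 1 and 0 <= p <= 1
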