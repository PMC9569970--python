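"""Two-way ANOVA, Tukey HSD, median split, log-rank and Kaplan-Meier,
checked against independent oracles (explicit textbook decompositions,
numerical integration of the studentized-range distribution, lifelines and
statsmodels)."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

import ppptrace as pt
from ppptrace.exceptions import (
    InvalidGroupingError,
    InvalidInputError,
    SplitImpossibleError,
    UnbalancedDesignError,
)


def random_balanced_table(a=2, b=2, r=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for la in range(a):
        for lb in range(b):
            effect = 1.0 * la + 0.5 * lb + 0.3 * la * lb
            for _ in range(r):
                rows.append(
                    {
                        "factor_a": f"A{la}",
                        "factor_b": f"B{lb}",
                        "value": effect + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def anova_oracle(df):
    """Brute-force mean decomposition: every SS from explicit loops."""
    y = df["value"].to_numpy()
    grand = y.mean()
    a_levels = sorted(df["factor_a"].unique())
    b_levels = sorted(df["factor_b"].unique())
    r = len(df) // (len(a_levels) * len(b_levels))
    ss_a = ss_b = ss_ab = ss_e = 0.0
    for la in a_levels:
        ma = df.loc[df.factor_a == la, "value"].mean()
        ss_a += len(b_levels) * r * (ma - grand) ** 2
    for lb in b_levels:
        mb = df.loc[df.factor_b == lb, "value"].mean()
        ss_b += len(a_levels) * r * (mb - grand) ** 2
    for la in a_levels:
        for lb in b_levels:
            cell = df.loc[(df.factor_a == la) & (df.factor_b == lb), "value"]
            ma = df.loc[df.factor_a == la, "value"].mean()
            mb = df.loc[df.factor_b == lb, "value"].mean()
            ss_ab += r * (cell.mean() - ma - mb + grand) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_e


class TestTwoWayAnova:
    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            df = random_balanced_table(a=3, b=2, r=4, seed=seed)
            res = pt.two_way_anova(df)
            ss_a, ss_b, ss_ab, ss_e = anova_oracle(df)
            assert res.effects["factor_a"]["ss"] == pytest.approx(ss_a, abs=1e-9)
            assert res.effects["factor_b"]["ss"] == pytest.approx(ss_b, abs=1e-9)
            assert res.effects["interaction"]["ss"] == pytest.approx(ss_ab, abs=1e-9)
            assert res.effects["residual"]["ss"] == pytest.approx(ss_e, abs=1e-9)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = random_balanced_table(a=2, b=3, r=3, seed=11)
        fit = ols("value ~ C(factor_a) * C(factor_b)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = pt.two_way_anova(df)
        assert res.effects["factor_a"]["F"] == pytest.approx(
            table.loc["C(factor_a)", "F"], rel=1e-9
        )
        assert res.effects["interaction"]["p"] == pytest.approx(
            table.loc["C(factor_a):C(factor_b)", "PR(>F)"], rel=1e-9
        )

    def test_ss_decomposition_is_exact(self):
        df = random_balanced_table(a=4, b=3, r=2, seed=5)
        res = pt.two_way_anova(df)
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        parts = sum(e["ss"] for e in res.effects.values())
        assert parts == pytest.approx(total, abs=1e-9)
        assert sum(e["df"] for e in res.effects.values()) == len(df) - 1

    def test_all_equal_values_degenerate(self):
        df = random_balanced_table(seed=0)
        df["value"] = 7.0
        res = pt.two_way_anova(df)
        assert res.degenerate
        for name in ("factor_a", "factor_b", "interaction"):
            assert res.effects[name]["F"] == 0.0
            assert res.effects[name]["p"] == 1.0

    def test_additive_effects_have_zero_interaction(self):
        rows = []
        for la, va in enumerate([0.0, 2.0]):
            for lb, vb in enumerate([0.0, 5.0, 7.0]):
                for rep in range(3):
                    rows.append(
                        {"factor_a": f"A{la}", "factor_b": f"B{lb}", "value": va + vb + rep}
                    )
        res = pt.two_way_anova(pd.DataFrame(rows))
        assert res.effects["interaction"]["ss"] == pytest.approx(0.0, abs=1e-9)

    def test_unbalanced_design_refused(self):
        df = random_balanced_table(seed=0).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            pt.two_way_anova(df)

    def test_single_replicate_refused(self):
        df = random_balanced_table(r=1, seed=0)
        with pytest.raises(UnbalancedDesignError):
            pt.two_way_anova(df)


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) by direct numerical integration of the range distribution."""

    def inner(s):
        def f(z):
            return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(f, -8, 8, epsabs=1e-10)
        return k * val

    def outer(s):
        # density of chi_df / sqrt(df)
        from scipy.special import gammaln

        logdens = (
            (1 - df / 2) * np.log(2)
            + (df / 2) * np.log(df)
            - gammaln(df / 2)
            + (df - 1) * np.log(s)
            - df * s**2 / 2
        )
        return np.exp(logdens) * inner(s)

    cdf, _ = integrate.quad(outer, 1e-8, 10, epsabs=1e-8, limit=200)
    return 1.0 - cdf


class TestTukeyHSD:
    def test_equal_means_give_p_one(self):
        out = pt.tukey_hsd({"a": 1.0, "b": 1.0, "c": 1.0}, mse=2.0, df_resid=12, n_per_group=4)
        assert (out["q"] == 0).all()
        assert (out["p_adj"] == 1.0).all()

    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        n = 6
        mse = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        dfres = 2 * n - 2
        mse /= dfres
        out = pt.tukey_hsd({"x": x.mean(), "y": y.mean()}, mse, dfres, n)
        t = abs(x.mean() - y.mean()) / np.sqrt(2 * mse / n)
        p_t = 2 * sps.t.sf(t, dfres)
        assert out["q"].iloc[0] == pytest.approx(t * np.sqrt(2), rel=1e-12)
        assert out["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-8)

    def test_four_groups_match_integration_oracle(self):
        means = {"g1": 0.0, "g2": 0.8, "g3": 1.5, "g4": 0.3}
        mse, n, dfres = 1.2, 5, 16
        out = pt.tukey_hsd(means, mse, dfres, n)
        for _, row in out.iterrows():
            oracle = studentized_range_sf_oracle(row["q"], 4, dfres)
            assert row["p_adj"] == pytest.approx(oracle, abs=1e-4)

    def test_zero_mse_flagged_degenerate(self):
        out = pt.tukey_hsd({"a": 1.0, "b": 2.0}, mse=0.0, df_resid=4, n_per_group=3)
        assert out["degenerate"].all()

    def test_star_annotation(self):
        assert pt.significance_stars(0.2) == "ns"
        assert pt.significance_stars(0.03) == "*"
        assert pt.significance_stars(0.005) == "**"
        assert pt.significance_stars(0.0005) == "***"
        assert pt.significance_stars(0.00005) == "****"


class TestMedianSplit:
    def test_even_split(self):
        labels = pt.median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_n_median_goes_low(self):
        labels = pt.median_split([1, 2, 3])
        assert list(labels) == ["low", "low", "high"]

    def test_duplicated_median_values_all_low(self):
        labels = pt.median_split([1, 2, 2, 2, 5, 6])
        assert list(labels) == ["low", "low", "low", "low", "high", "high"]

    def test_all_identical_rejected(self):
        with pytest.raises(SplitImpossibleError):
            pt.median_split([3, 3, 3, 3])


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a"] * 3 + ["b"] * 3
        res = pt.logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_enumerated_separated_groups(self):
        # group A dies at 1,2,3; group B at 4,5,6 - enumerate the
        # hypergeometric expectations and variances by hand
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        groups = ["a", "a", "a", "b", "b", "b"]
        o_minus_e = (1 - 3 / 6) + (1 - 2 / 5) + (1 - 1 / 4)
        var = (
            (3 / 6) * (3 / 6) * (5 / 5)
            + (2 / 5) * (3 / 5) * (4 / 4)
            + (1 / 4) * (3 / 4) * (3 / 3)
        )
        expected_stat = o_minus_e**2 / var
        res = pt.logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(expected_stat, abs=1e-9)
        assert res.p_value == pytest.approx(sps.chi2.sf(expected_stat, 1), abs=1e-12)

    def test_invariant_to_group_label_swap(self):
        df = pt.simulate_survival(30, hazard_ratio=2.0, censor_rate=0.2, seed=3)
        labels = pt.median_split(df["expression"].to_numpy())
        swapped = np.where(labels == "high", "low", "high")
        r1 = pt.logrank_test(df["time"], df["event"], labels)
        r2 = pt.logrank_test(df["time"], df["event"], swapped)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        for seed in range(5):
            df = pt.simulate_survival(40, hazard_ratio=1.8, censor_rate=0.25, seed=seed)
            labels = pt.median_split(df["expression"].to_numpy())
            mine = pt.logrank_test(df["time"], df["event"], labels)
            hi = labels == "high"
            theirs = ll_logrank(
                df["time"][hi], df["time"][~hi], df["event"][hi], df["event"][~hi]
            )
            assert mine.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(theirs.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidGroupingError):
            pt.logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_no_events_rejected(self):
        with pytest.raises(InvalidInputError):
            pt.logrank_test([1, 2], [0, 0], ["a", "b"])


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = pt.km_curve([5, 6, 7], [0, 0, 0])
        assert curve.survival == (1.0,)
        assert curve.probability_at(10.0) == 1.0

    def test_all_events_distinct_times(self):
        curve = pt.km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_censoring_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        df = pt.simulate_survival(60, hazard_ratio=1.0, censor_rate=0.4, seed=9)
        curve = pt.km_curve(df["time"], df["event"])
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-9
            )

    def test_survival_non_increasing_from_one(self):
        df = pt.simulate_survival(50, hazard_ratio=2.0, censor_rate=0.3, seed=4)
        curve = pt.km_curve(df["time"], df["event"])
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)
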