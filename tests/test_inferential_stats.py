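"""t-tests, correlation, and the split-plot Type III mixed ANOVA.

The ANOVA is cross-checked against three independent routes: a textbook
hand computation of the 2x2 split-plot decomposition, pingouin's
mixed_anova for one-between/one-within designs, and statsmodels' AnovaRM
for pure within-subject designs.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vividstats.datatypes import SummaryStats
from vividstats.inferential_stats import (
    mixed_anova,
    pearson_correlation,
    summary_stats,
    t_from_summary,
)

from conftest import SEED


def effect(table, name):
    return table[table["effect"] == name].iloc[0]


class TestTFromSummary:
    @pytest.mark.parametrize("variance", ["pooled", "welch"])
    def test_matches_scipy_from_stats(self, variance, rng):
        for _ in range(20):
            a = SummaryStats(rng.normal(), rng.uniform(0.5, 3), int(rng.integers(3, 40)))
            b = SummaryStats(rng.normal(), rng.uniform(0.5, 3), int(rng.integers(3, 40)))
            res = t_from_summary(a, b, variance=variance)
            ref = stats.ttest_ind_from_stats(
                a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variance == "pooled")
            )
            assert res.t == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_extreme_group_vividness_means(self):
        """Summary statistics of the low/high vividness groups give a large
        negative pooled t on 18 df."""
        res = t_from_summary(
            SummaryStats(41.9, 11.99, 10), SummaryStats(75.5, 2.72, 10)
        )
        assert res.df == 18
        assert res.t == pytest.approx(-8.6422, abs=1e-4)
        assert res.p < 1e-6
        assert res.d == pytest.approx(-3.865, abs=1e-3)

    def test_identical_groups_give_zero_t(self):
        s = SummaryStats(5.0, 2.0, 12)
        res = t_from_summary(s, s)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_welch_df_collapses_to_pooled_for_equal_n_and_sd(self):
        a, b = SummaryStats(0.0, 1.0, 30), SummaryStats(0.5, 1.0, 30)
        assert t_from_summary(a, b, "welch").df == pytest.approx(58.0)
        assert t_from_summary(a, b, "pooled").df == 58

    def test_zero_variance_handling(self):
        same = t_from_summary(SummaryStats(3, 0, 5), SummaryStats(3, 0, 5))
        assert same.t == 0.0 and same.p == 1.0
        with pytest.raises(ValueError, match="infinite"):
            t_from_summary(SummaryStats(3, 0, 5), SummaryStats(4, 0, 5))

    def test_one_tailed_p_is_half_two_tailed(self):
        a, b = SummaryStats(0.0, 1.0, 10), SummaryStats(1.0, 1.0, 10)
        assert t_from_summary(a, b, tails=1).p == pytest.approx(
            t_from_summary(a, b, tails=2).p / 2
        )


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_on_noise(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = pearson_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert (r, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_independent_samples_have_small_r(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        r, _ = pearson_correlation(x, y)
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _split_plot_hand_ss(y, groups, n_per_group, p):
    """Textbook 2-group split-plot decomposition; y has shape (subjects, p)."""
    grand = y.mean()
    subj_means = y.mean(axis=1)
    g_means = np.array([y[groups == g].mean() for g in (0, 1)])
    w_means = y.mean(axis=0)
    gw_means = np.array([y[groups == g].mean(axis=0) for g in (0, 1)])
    ss_group = n_per_group * p * ((g_means - grand) ** 2).sum()
    ss_subj = p * ((subj_means - grand) ** 2).sum() - ss_group
    ss_w = 2 * n_per_group * ((w_means - grand) ** 2).sum()
    ss_gw = n_per_group * (
        (gw_means - g_means[:, None] - w_means[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - subj_means[:, None]
        - gw_means[groups]
        + g_means[groups][:, None]
    )
    ss_err_w = (resid**2).sum()
    return ss_group, ss_subj, ss_w, ss_gw, ss_err_w


class TestMixedAnova:
    def test_f_equals_t_squared_for_two_groups(self, rng):
        g = np.repeat(["a", "b"], [6, 4])
        y = rng.normal(size=10) + (g == "a") * 0.8
        df = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(10)], "grp": g, "response": y}
        )
        tab = mixed_anova(df, between=["grp"])
        t = stats.ttest_ind(y[g == "a"], y[g == "b"])
        assert effect(tab, "grp")["F"] == pytest.approx(t.statistic**2, rel=1e-10)
        assert effect(tab, "grp")["p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_hand_worked_split_plot(self, rng):
        """SS and F of a small 2x2 split-plot agree with the classical
        mean-decomposition formulas to 1e-10."""
        n_per_group, p = 4, 2
        groups = np.repeat([0, 1], n_per_group)
        y = rng.normal(size=(8, p)) + groups[:, None] * 0.7 + np.array([0.0, 0.4])
        long = pd.DataFrame(
            {
                "subject": np.repeat([f"s{i}" for i in range(8)], p),
                "grp": np.repeat(np.where(groups == 0, "g0", "g1"), p),
                "cond": np.tile(["c1", "c2"], 8),
                "response": y.ravel(),
            }
        )
        tab = mixed_anova(long, between=["grp"], within=["cond"])
        ss_group, ss_subj, ss_w, ss_gw, ss_err_w = _split_plot_hand_ss(
            y, groups, n_per_group, p
        )
        assert effect(tab, "grp")["SS"] == pytest.approx(ss_group, abs=1e-10)
        assert effect(tab, "Error(between)")["SS"] == pytest.approx(ss_subj, abs=1e-10)
        assert effect(tab, "cond")["SS"] == pytest.approx(ss_w, abs=1e-10)
        assert effect(tab, "grp:cond")["SS"] == pytest.approx(ss_gw, abs=1e-10)
        assert effect(tab, "Error(within:cond)")["SS"] == pytest.approx(
            ss_err_w, abs=1e-10
        )
        f_group = (ss_group / 1) / (ss_subj / 6)
        assert effect(tab, "grp")["F"] == pytest.approx(f_group, rel=1e-10)

    def test_matches_pingouin_mixed_anova(self, rng):
        """Balanced one-between/one-within design: pingouin's mixed ANOVA and
        the Type III split-plot coincide exactly."""
        pg = pytest.importorskip("pingouin")
        n = 14
        subj = np.repeat([f"s{i}" for i in range(n)], 4)
        grp = np.repeat(np.where(np.arange(n) % 2 == 0, "hi", "lo"), 4)
        cond = np.tile(["c1", "c2", "c3", "c4"], n)
        y = rng.normal(size=4 * n) + (grp == "hi") * 0.5 + (cond == "c2") * 0.4
        df = pd.DataFrame(
            {"subject": subj, "grp": grp, "cond": cond, "response": y}
        )
        ours = mixed_anova(df, between=["grp"], within=["cond"])
        ref = pg.mixed_anova(
            df, dv="response", within="cond", between="grp", subject="subject"
        ).set_index("Source")
        for mine, theirs in [("grp", "grp"), ("cond", "cond"), ("grp:cond", "Interaction")]:
            assert effect(ours, mine)["F"] == pytest.approx(
                ref.loc[theirs, "F"], rel=1e-8
            )
            assert effect(ours, mine)["p"] == pytest.approx(
                ref.loc[theirs, "p_unc"], rel=1e-8
            )
            assert effect(ours, mine)["partial_eta_sq"] == pytest.approx(
                ref.loc[theirs, "np2"], rel=1e-8
            )

    def test_unbalanced_group_effect_equals_anova_on_subject_means(self, rng):
        """With a single between factor the between-stratum Type III F equals
        the one-way ANOVA on per-subject means, even with unequal groups."""
        n = 14
        subj = np.repeat([f"s{i}" for i in range(n)], 4)
        grp = np.repeat(np.where(np.arange(n) % 3 == 0, "hi", "lo"), 4)
        cond = np.tile(["c1", "c2", "c3", "c4"], n)
        y = rng.normal(size=4 * n) + (grp == "hi") * 0.5
        df = pd.DataFrame({"subject": subj, "grp": grp, "cond": cond, "response": y})
        ours = mixed_anova(df, between=["grp"], within=["cond"])
        means = df.groupby(["subject", "grp"])["response"].mean().reset_index()
        ref = stats.f_oneway(
            means.loc[means["grp"] == "hi", "response"],
            means.loc[means["grp"] == "lo", "response"],
        )
        assert effect(ours, "grp")["F"] == pytest.approx(ref.statistic, rel=1e-10)
        assert effect(ours, "grp")["p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_matches_statsmodels_anovarm_pure_within(self, rng):
        anova_rm = pytest.importorskip("statsmodels.stats.anova").AnovaRM
        n = 10
        rows = []
        for i in range(n):
            for a in ["a1", "a2"]:
                for b in ["b1", "b2", "b3"]:
                    rows.append(
                        {
                            "subject": f"s{i}",
                            "fa": a,
                            "fb": b,
                            "response": rng.normal()
                            + (a == "a2") * 0.5
                            + (b == "b2") * 0.3,
                        }
                    )
        df = pd.DataFrame(rows)
        ours = mixed_anova(df, within=["fa", "fb"])
        ref = anova_rm(df, "response", "subject", within=["fa", "fb"]).fit().anova_table
        for mine, theirs in [("fa", "fa"), ("fb", "fb"), ("fa:fb", "fa:fb")]:
            assert effect(ours, mine)["F"] == pytest.approx(
                ref.loc[theirs, "F Value"], rel=1e-8
            )
            assert effect(ours, mine)["df1"] == ref.loc[theirs, "Num DF"]
            assert effect(ours, mine)["df2"] == ref.loc[theirs, "Den DF"]

    def test_stratum_ss_additivity_balanced(self, rng):
        """In each balanced stratum the effect SS plus error SS equals the
        stratum total."""
        n = 12
        subj = np.repeat([f"s{i}" for i in range(n)], 2)
        grp = np.repeat(np.where(np.arange(n) < 6, "g0", "g1"), 2)
        cond = np.tile(["c1", "c2"], n)
        y = rng.normal(size=2 * n)
        df = pd.DataFrame({"subject": subj, "grp": grp, "cond": cond, "response": y})
        tab = mixed_anova(df, between=["grp"], within=["cond"])
        wide = df.pivot(index="subject", columns="cond", values="response")
        subj_means = wide.mean(axis=1)
        between_total = 2 * ((subj_means - subj_means.mean()) ** 2).sum()
        got = (
            effect(tab, "grp")["SS"] + effect(tab, "Error(between)")["SS"]
        )
        assert got == pytest.approx(between_total, rel=1e-8)
        within_scores = (wide["c1"] - wide["c2"]) / np.sqrt(2)  # orthonormal contrast
        within_total = (within_scores**2).sum()
        got_w = (
            effect(tab, "cond")["SS"]
            + effect(tab, "grp:cond")["SS"]
            + effect(tab, "Error(within:cond)")["SS"]
        )
        assert got_w == pytest.approx(within_total, rel=1e-8)

    def test_covariate_consumes_one_between_df(self, rng):
        n = 16
        subj = [f"s{i}" for i in range(n)]
        grp = np.where(np.arange(n) < 8, "g0", "g1")
        cov = rng.normal(size=n)
        rows = []
        for i in range(n):
            for c in ["c1", "c2"]:
                rows.append(
                    {
                        "subject": subj[i],
                        "grp": grp[i],
                        "scale": cov[i],
                        "cond": c,
                        "response": rng.normal(),
                    }
                )
        df = pd.DataFrame(rows)
        plain = mixed_anova(df, between=["grp"], within=["cond"])
        with_cov = mixed_anova(
            df, between=["grp"], within=["cond"], covariate="scale"
        )
        assert effect(plain, "grp")["df2"] == n - 2
        assert effect(with_cov, "grp")["df2"] == n - 3
        assert "scale" in set(with_cov["effect"])

    def test_missing_within_cell_rejected(self):
        df = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2"],
                "grp": ["a", "a", "b"],
                "cond": ["c1", "c2", "c1"],
                "response": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="s2"):
            mixed_anova(df, between=["grp"], within=["cond"])

    def test_rank_deficient_design_rejected(self, rng):
        # two between factors perfectly confounded
        n = 8
        rows = []
        for i in range(n):
            rows.append(
                {
                    "subject": f"s{i}",
                    "f1": "a" if i < 4 else "b",
                    "f2": "x" if i < 4 else "y",
                    "response": rng.normal(),
                }
            )
        with pytest.raises(ValueError, match="rank"):
            mixed_anova(pd.DataFrame(rows), between=["f1", "f2"])

    def test_partial_eta_squared_definition(self, rng):
        n = 10
        g = np.repeat(["a", "b"], 5)
        df = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "grp": g,
                "response": rng.normal(size=n) + (g == "a"),
            }
        )
        tab = mixed_anova(df, between=["grp"])
        row = effect(tab, "grp")
        err = effect(tab, "Error(between)")
        assert row["partial_eta_sq"] == pytest.approx(
            row["SS"] / (row["SS"] + err["SS"])
        )
        assert 0 <= row["partial_eta_sq"] <= 1


def test_summary_stats_roundtrip(rng):
    x = rng.normal(2.0, 3.0, 25)
    s = summary_stats(x)
    assert s.mean == pytest.approx(x.mean())
    assert s.sd == pytest.approx(x.std(ddof=1))
    assert s.n == 25
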