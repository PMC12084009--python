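"""Cohort statistics: ANOVA oracle equivalence, t-tests, correlations,
assumption checks, demographic summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroei.demographics import load_study_cohort
from neuroei.stats import (anova_group_condition, assumption_checks,
                           bonferroni, count_operated_within, independent_t,
                           pearson_ci, summarize_cohort)


def brute_force_two_way(df, outcome):
    """Independent oracle: explicit balanced two-way SS decomposition."""
    y = df[outcome].to_numpy()
    grand = y.mean()
    ss = {}
    cell = df.groupby(["group", "condition"])[outcome].mean()
    na = df.groupby("group").size().iloc[0]
    ga = df.groupby("group")[outcome].mean()
    gb = df.groupby("condition")[outcome].mean()
    n_a = df.groupby("group").size()
    n_b = df.groupby("condition").size()
    ss["group"] = float((n_a * (ga - grand) ** 2).sum())
    ss["condition"] = float((n_b * (gb - grand) ** 2).sum())
    n_cell = df.groupby(["group", "condition"]).size()
    ss_cells = float((n_cell * (cell - grand) ** 2).sum())
    ss["group:condition"] = ss_cells - ss["group"] - ss["condition"]
    resid = y - df.groupby(["group", "condition"])[outcome].transform("mean")
    ss["error"] = float((resid ** 2).sum())
    df_err = len(df) - cell.size
    out = {}
    for name, df_num in (("group", ga.size - 1), ("condition", gb.size - 1),
                         ("group:condition",
                          (ga.size - 1) * (gb.size - 1))):
        ms = ss[name] / df_num
        f = ms / (ss["error"] / df_err)
        p = sps.f.sf(f, df_num, df_err)
        out[name] = (f, p, ss[name] / (ss[name] + ss["error"]))
    assert na > 0
    return out


class TestAnova:
    def _toy(self, seed=0):
        """2×2 balanced, n = 3/cell, unit group effect, σ = 0.1 noise."""
        rng = np.random.default_rng(seed)
        rows = []
        for g, mean in (("A", 0.0), ("B", 1.0)):
            for c in ("EO", "EC"):
                for i in range(3):
                    rows.append({"group": g, "condition": c,
                                 "subject": f"{g}{i}",
                                 "y": mean + 0.1 * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_matches_brute_force_ss_oracle(self):
        df = self._toy()
        oracle = brute_force_two_way(df, "y")
        for res in anova_group_condition(df, "y"):
            f, p, eta = oracle[res.effect]
            assert res.F == pytest.approx(f, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)
            assert res.partial_eta_sq == pytest.approx(eta, abs=1e-9)

    def test_partial_eta_squared_identity(self):
        """η_p² = F·df1/(F·df1 + df2) holds for every reported effect."""
        for res in anova_group_condition(self._toy(3), "y"):
            implied = res.F * res.df_num / (res.F * res.df_num + res.df_den)
            assert res.partial_eta_sq == pytest.approx(implied, abs=1e-9)

    def test_all_equal_observations_reported_degenerate(self):
        df = self._toy()
        df["y"] = 1.0
        assert all(r.degenerate for r in anova_group_condition(df, "y"))

    def test_single_level_factor_rejected(self):
        df = self._toy()
        df["group"] = "A"
        with pytest.raises(ValueError):
            anova_group_condition(df, "y")

    def test_repeated_measures_variant_runs(self):
        df = self._toy()
        out = anova_group_condition(df, "y", repeated=True)
        names = {r.effect for r in out}
        assert {"group", "condition"} <= names
        grp = next(r for r in out if r.effect == "group")
        assert grp.p < 0.01  # unit effect, tiny noise


class TestTTests:
    def test_identical_samples_t_zero(self):
        x = np.arange(10.0)
        t, df, p = independent_t(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_two_sample_closed_form(self):
        # hand-computed pooled-variance example
        x = np.array([1.0, 2.0, 3.0, 4.0])   # mean 2.5, var 5/3
        y = np.array([3.0, 4.0, 5.0, 6.0])   # mean 4.5, var 5/3
        t, df, p = independent_t(x, y)
        se = np.sqrt((5 / 3) * (1 / 4 + 1 / 4))
        assert t == pytest.approx(-2.0 / se, rel=1e-12)
        assert df == 6

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            independent_t([1.0, 2.0], [1.0, 2.0, 3.0], "paired")

    def test_age_matching_of_study_groups(self):
        """The bundled CC/SC ages are statistically indistinguishable
        (|t| ≈ 0.11 unpaired on the printed one-decimal ages)."""
        coh = load_study_cohort()
        cc = coh.loc[coh.group == "CC", "age"]
        sc = coh.loc[coh.group == "SC", "age"]
        t, df, p = independent_t(cc, sc)
        assert t == pytest.approx(-0.109, abs=0.005)
        assert p > 0.9


class TestPearson:
    def test_perfect_linear_relation_degenerate_ci(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == 1.0
        assert res.ci95 == (1.0, 1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson_ci(x, -x).r == -1.0

    def test_fisher_z_interval_matches_brute_force(self, rng):
        x = rng.standard_normal(24)
        y = 0.5 * x + rng.standard_normal(24)
        res = pearson_ci(x, y)
        z = np.arctanh(res.r)
        half = 1.959963984540054 / np.sqrt(24 - 3)
        assert res.ci95[0] == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert res.ci95[1] == pytest.approx(np.tanh(z + half), abs=1e-9)
        assert res.ci95[0] < res.r < res.ci95[1]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestBonferroni:
    def test_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.3], m=6), [0.06, 1.0])

    def test_order_preserved(self, rng):
        p = rng.uniform(size=20)
        adj = bonferroni(p, m=6)
        assert (np.argsort(adj) == np.argsort(np.minimum(1, p * 6))).all()


class TestAssumptionChecks:
    def test_normal_sample_passes_shapiro(self, rng):
        out = assumption_checks([rng.standard_normal(50)])
        assert out["shapiro"][0]["p"] > 0.01

    def test_heavy_tailed_sample_rejected_by_shapiro(self, rng):
        rejections = 0
        for _ in range(20):
            sample = rng.standard_cauchy(50)
            out = assumption_checks([sample])
            rejections += out["shapiro"][0]["p"] < 0.05
        assert rejections > 10  # rejection rate >> nominal 5%

    def test_equal_variance_groups_pass_levene(self, rng):
        out = assumption_checks([rng.standard_normal(30),
                                 rng.standard_normal(30)])
        assert out["levene"]["p"] > 0.01


class TestCohortSummaries:
    def test_deprivation_duration_matches_study_report(self):
        """CC deprivation duration: mean 11.8 y, SD 9.7 y (one-decimal)."""
        s = summarize_cohort(load_study_cohort())
        row = s.query("group == 'CC' and variable == 'deprivation_duration'")
        assert round(float(row["mean"].iloc[0]), 1) == 11.8
        assert round(float(row["sd"].iloc[0]), 1) == 9.7

    def test_time_since_surgery_matches_study_report(self):
        s = summarize_cohort(load_study_cohort())
        row = s.query("group == 'CC' and variable == 'time_since_surgery'")
        assert round(float(row["mean"].iloc[0]), 1) == 14.0
        assert round(float(row["sd"].iloc[0]), 1) == 9.1

    def test_group_mean_ages(self):
        s = summarize_cohort(load_study_cohort())
        cc = s.query("group == 'CC' and variable == 'age'")["mean"].iloc[0]
        sc = s.query("group == 'SC' and variable == 'age'")["mean"].iloc[0]
        assert round(float(cc), 1) == 25.8
        assert round(float(sc), 1) == 26.3

    def test_two_participants_operated_within_first_year(self):
        assert count_operated_within(load_study_cohort(), 1.0) == 2

    def test_single_row_group_sd_undefined(self):
        df = pd.DataFrame({"group": ["A", "B", "B"],
                           "age": [30.0, 20.0, 25.0]})
        s = summarize_cohort(df, columns=("age",))
        assert np.isnan(s.query("group == 'A'")["sd"].iloc[0])

    def test_missing_column_rejected(self):
        with pytest.raises(KeyError):
            summarize_cohort(pd.DataFrame({"group": ["A"]}),
                             columns=("age",))
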