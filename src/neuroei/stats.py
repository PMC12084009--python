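"""Cohort-level statistics: group×condition ANOVA, t-tests, Pearson
correlations with Fisher-z intervals, Bonferroni adjustment, assumption
checks, and demographic summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM

from .types import CorrelationResult, StatsResult


def anova_group_condition(df: pd.DataFrame, outcome: str,
                          group_col: str = "group",
                          condition_col: str = "condition",
                          repeated: bool = False,
                          subject_col: str = "subject",
                          ) -> list[StatsResult]:
    """Two-factor group-by-condition ANOVA with partial η² per effect.

    The default treats every (subject, condition) observation as independent
    and uses Type-II sums of squares (identical to Type I/III on balanced
    data).  ``repeated=True`` switches to a repeated-measures model with
    condition as the within-subject factor (group tested on subject means).
    Partial η² = SS_effect / (SS_effect + SS_error).
    """
    data = df[[c for c in {outcome, group_col, condition_col, subject_col}
               if c in df.columns]].dropna().copy()
    if data[group_col].nunique() < 2:
        raise ValueError("group factor needs at least two levels")
    if data[condition_col].nunique() < 2:
        raise ValueError("condition factor needs at least two levels")
    if not np.all(np.isfinite(data[outcome])):
        raise ValueError("outcome must be finite")
    if repeated:
        return _anova_rm(data, outcome, group_col, condition_col, subject_col)

    if np.allclose(data[outcome], data[outcome].iloc[0]):
        return [StatsResult(effect=e, F=np.nan, df_num=np.nan, df_den=np.nan,
                            p=np.nan, partial_eta_sq=np.nan, degenerate=True)
                for e in ("group", "condition", "group:condition")]

    model = smf.ols(
        f"Q('{outcome}') ~ C(Q('{group_col}')) * C(Q('{condition_col}'))",
        data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])
    rename = {
        f"C(Q('{group_col}'))": "group",
        f"C(Q('{condition_col}'))": "condition",
        f"C(Q('{group_col}')):C(Q('{condition_col}'))": "group:condition",
    }
    results = []
    for row, name in rename.items():
        ss = float(table.loc[row, "sum_sq"])
        if ss_err == 0:
            results.append(StatsResult(effect=name, F=np.nan, df_num=np.nan,
                                       df_den=np.nan, p=np.nan,
                                       partial_eta_sq=np.nan, degenerate=True))
            continue
        results.append(StatsResult(
            effect=name, F=float(table.loc[row, "F"]),
            df_num=float(table.loc[row, "df"]), df_den=df_err,
            p=float(table.loc[row, "PR(>F)"]),
            partial_eta_sq=ss / (ss + ss_err)))
    return results


def _anova_rm(data, outcome, group_col, condition_col, subject_col):
    """Mixed design: within-subject condition effect via repeated-measures
    ANOVA per the AnovaRM decomposition; between-subject group effect on
    subject means."""
    aov = AnovaRM(data, depvar=outcome, subject=subject_col,
                  within=[condition_col]).fit()
    row = aov.anova_table.loc[condition_col]
    # partial eta^2 from the F statistic and dfs: F·df1/(F·df1 + df2)
    f, d1, d2 = (float(row["F Value"]), float(row["Num DF"]),
                 float(row["Den DF"]))
    cond = StatsResult(effect="condition", F=f, df_num=d1, df_den=d2,
                       p=float(row["Pr > F"]),
                       partial_eta_sq=f * d1 / (f * d1 + d2))
    means = data.groupby([subject_col, group_col])[outcome].mean().reset_index()
    groups = [g[outcome].to_numpy()
              for _, g in means.groupby(group_col)]
    t, p = sps.ttest_ind(*groups)
    d1, d2 = 1.0, float(len(means) - 2)
    f = float(t ** 2)
    grp = StatsResult(effect="group", F=f, df_num=d1, df_den=d2, p=float(p),
                      partial_eta_sq=f / (f + d2))
    return [grp, cond]


def independent_t(x, y, variant: str = "student") -> tuple[float, float, float]:
    """t-test: ``student`` (pooled), ``welch``, or ``paired``.

    Returns (t, df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if variant == "student":
        t, p = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    elif variant == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = float(res.df)
    elif variant == "paired":
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        t, p = sps.ttest_rel(x, y)
        df = x.size - 1
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(t), float(df), float(p)


def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with p-value (t transform) and Fisher-z confidence interval.

    A numerically perfect linear relation (|r| = 1) yields the degenerate
    interval [r, r].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    n = x.size
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))  # snap a numerically perfect fit to ±1
        ci = (r, r)
    elif n == 3:
        ci = (-1.0, 1.0)  # Fisher z has no finite standard error at n = 3
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        q = sps.norm.ppf(1.0 - alpha / 2.0)
        ci = (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))
    return CorrelationResult(r=r, p=float(p), ci95=ci, n=n)


def bonferroni(p_values, m: int = 6) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p)."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def adjust_correlations(results: list[CorrelationResult],
                        m: int | None = None) -> list[CorrelationResult]:
    """Attach Bonferroni-adjusted p values to a family of correlations."""
    m = m if m is not None else len(results)
    adjusted = bonferroni([r.p for r in results], m=m)
    for res, pa in zip(results, adjusted):
        res.p_adjusted = float(pa)
        res.m = m
    return results


def assumption_checks(samples) -> dict:
    """Shapiro–Wilk normality (per sample and pooled) and Levene homogeneity.

    ``samples`` is a sequence of 1-D arrays (e.g. residuals per group).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    out = {"shapiro": []}
    for s in samples:
        w, p = sps.shapiro(s)
        out["shapiro"].append({"W": float(w), "p": float(p), "n": s.size})
    if len(samples) >= 2:
        stat, p = sps.levene(*samples)
        out["levene"] = {"W": float(stat), "p": float(p)}
    return out


def summarize_cohort(cohort: pd.DataFrame,
                     columns: tuple[str, ...] = ("age",
                                                 "deprivation_duration",
                                                 "time_since_surgery",
                                                 "logmar"),
                     group_col: str = "group") -> pd.DataFrame:
    """Per-group mean, SD (n−1), min, max and count for demographic columns.

    Columns absent for a group (e.g. surgery fields for controls) yield NaN
    rows; a single-observation group reports SD as NaN.
    """
    missing = [c for c in (group_col,) if c not in cohort.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    rows = []
    for grp, sub in cohort.groupby(group_col):
        for col in columns:
            if col not in cohort.columns:
                raise KeyError(f"missing column: {col}")
            vals = sub[col].dropna().to_numpy(dtype=float)
            rows.append({
                "group": grp, "variable": col, "n": vals.size,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                "min": float(np.min(vals)) if vals.size else np.nan,
                "max": float(np.max(vals)) if vals.size else np.nan,
            })
    return pd.DataFrame(rows)


def count_operated_within(cohort: pd.DataFrame, years: float = 1.0,
                          column: str = "deprivation_duration") -> int:
    """Number of participants operated within ``years`` of birth."""
    vals = cohort[column].dropna()
    return int((vals < years).sum())
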