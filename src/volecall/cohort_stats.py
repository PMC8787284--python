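"""Cohort-level statistics over per-animal summaries.

The statistical battery for developmental USV cohorts: two-way
(age x sex) ANOVAs with a sex-collapse rule, one-way ANOVAs with Tukey
HSD post-hocs, mixed factorial (age between x context within) ANOVA,
paired t-tests with Benjamini-Hochberg correction, z-tests of difference
distributions against zero, and one-tailed t-tests for distributions
falling below zero.  All decisions use alpha = 0.05.

Input tables are long-format pandas DataFrames with one row per animal
(or per animal x context for within-subject designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "PairwiseResult",
    "two_way_anova",
    "collapse_sex_if_ns",
    "one_way_anova_tukey",
    "mixed_anova",
    "paired_ttests_bh",
    "z_test_vs_zero",
    "one_tailed_t_below_zero",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """One test statistic with degrees of freedom and p-value."""

    effect: str
    statistic: float
    df: tuple[float, ...]
    p: float
    test_kind: str

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class PairwiseResult:
    """One post-hoc comparison, raw and multiplicity-adjusted."""

    group_a: object
    group_b: object
    statistic: float
    raw_p: float
    adjusted_p: float
    method: str

    @property
    def significant(self) -> bool:
        return self.adjusted_p < ALPHA


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str = "age",
    factor_b: str = "sex",
    ss_type: int = 2,
) -> dict[str, StatResult]:
    """Two-way between-subjects ANOVA with interaction.

    Uses Type-II sums of squares by default; with unbalanced cells the
    convention matters, so Type I/III are selectable.  Returns results
    keyed by ``factor_a``, ``factor_b`` and ``"interaction"``.
    """
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    data = table[[response, factor_a, factor_b]].rename(
        columns={response: "_y", factor_a: "_a", factor_b: "_b"}
    )
    n_cells = data.groupby(["_a", "_b"]).ngroups
    if np.ptp(data["_y"].to_numpy()) == 0:  # constant response: all effects null
        df_resid = float(len(data) - n_cells)
        return {
            key: StatResult(effect=key, statistic=0.0, df=(float(df1), df_resid),
                            p=1.0, test_kind="two_way_anova")
            for key, df1 in [
                (factor_a, data["_a"].nunique() - 1),
                (factor_b, data["_b"].nunique() - 1),
                ("interaction", (data["_a"].nunique() - 1) * (data["_b"].nunique() - 1)),
            ]
        }
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    tab = anova_lm(model, typ=ss_type)
    df_resid = float(tab.loc["Residual", "df"])
    out = {}
    for key, row_name in [
        (factor_a, "C(_a)"),
        (factor_b, "C(_b)"),
        ("interaction", "C(_a):C(_b)"),
    ]:
        row = tab.loc[row_name]
        f_val = float(row["F"])
        p_val = float(row["PR(>F)"])
        if not np.isfinite(f_val):  # zero-variance response
            f_val, p_val = 0.0, 1.0
        out[key] = StatResult(
            effect=key,
            statistic=f_val,
            df=(float(row["df"]), df_resid),
            p=p_val,
            test_kind="two_way_anova",
        )
    return out


@dataclass
class SexCollapseDecision:
    """Record of the sex-collapse rule applied to one response."""

    response: str
    sex_p: float
    collapsed: bool
    one_way: StatResult | None = None
    pairwise: list[PairwiseResult] | None = None


def collapse_sex_if_ns(
    two_way: dict[str, StatResult],
    table: pd.DataFrame,
    response: str,
    age_factor: str = "age",
    sex_factor: str = "sex",
    alpha: float = ALPHA,
) -> SexCollapseDecision:
    """Pool sexes and rerun a one-way age ANOVA when sex is not significant.

    The main effect of sex is "not found" when p >= alpha (strict
    rejection at p < alpha), in which case male and female data are
    collapsed and the age effect is re-assessed with a one-way ANOVA plus
    Tukey HSD.
    """
    sex_p = two_way[sex_factor].p
    if sex_p >= alpha:
        omnibus, pairwise = one_way_anova_tukey(table, response, factor=age_factor)
        return SexCollapseDecision(
            response=response, sex_p=sex_p, collapsed=True,
            one_way=omnibus, pairwise=pairwise,
        )
    return SexCollapseDecision(response=response, sex_p=sex_p, collapsed=False)


def one_way_anova_tukey(
    table: pd.DataFrame,
    response: str,
    factor: str = "age",
) -> tuple[StatResult, list[PairwiseResult]]:
    """One-way ANOVA with all-pairs Tukey HSD post-hoc comparisons."""
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    groups = [table.loc[table[factor] == lv, response].to_numpy(float) for lv in levels]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    f_val, p_val = stats.f_oneway(*groups)
    n_total = sum(g.size for g in groups)
    omnibus = StatResult(
        effect=factor,
        statistic=float(f_val) if np.isfinite(f_val) else 0.0,
        df=(float(len(levels) - 1), float(n_total - len(levels))),
        p=float(p_val) if np.isfinite(p_val) else 1.0,
        test_kind="one_way_anova",
    )
    hsd = stats.tukey_hsd(*groups)
    pairwise = [
        PairwiseResult(
            group_a=levels[i],
            group_b=levels[j],
            statistic=float(hsd.statistic[i, j]),
            raw_p=float(hsd.pvalue[i, j]),
            adjusted_p=float(hsd.pvalue[i, j]),  # HSD p is family-adjusted
            method="tukey_hsd",
        )
        for i, j in combinations(range(len(levels)), 2)
    ]
    return omnibus, pairwise


def mixed_anova(
    table: pd.DataFrame,
    response: str = "count",
    between: str = "age",
    within: str = "context",
    subject: str = "pup_id",
) -> dict[str, StatResult]:
    """Mixed factorial ANOVA: one between- and one within-subjects factor.

    Subjects are the repeated-measures unit; every subject must appear in
    every level of the within factor.  With a two-level within factor
    sphericity holds trivially, so no correction is applied.
    """
    counts = table.groupby(subject)[within].nunique()
    n_within = table[within].nunique()
    if (counts < n_within).any():
        missing = counts[counts < n_within].index.tolist()
        raise ValueError(f"subjects missing a {within} level: {missing}")
    with np.errstate(invalid="ignore", divide="ignore"):  # degenerate 0/0 -> NaN
        aov = pg.mixed_anova(
            data=table, dv=response, within=within, between=between, subject=subject
        ).set_index("Source")
    out = {}
    for key, src in [(between, between), (within, within), ("interaction", "Interaction")]:
        row = aov.loc[src]
        f_val = float(row["F"])
        p_val = float(row["p_unc"])
        if not np.isfinite(f_val):
            f_val, p_val = 0.0, 1.0
        out[key] = StatResult(
            effect=key,
            statistic=f_val,
            df=(float(row["DF1"]), float(row["DF2"])),
            p=p_val,
            test_kind="mixed_anova",
        )
    return out


def benjamini_hochberg(raw_p) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, never below raw)."""
    raw_p = np.asarray(raw_p, dtype=float)
    return multipletests(raw_p, method="fdr_bh")[1]


def paired_ttests_bh(
    table: pd.DataFrame,
    response: str = "count",
    within: str = "context",
    subject: str = "pup_id",
    group: str = "age",
    levels: tuple | None = None,
) -> list[PairwiseResult]:
    """Per-group paired t-tests across the two within-factor levels, with
    Benjamini-Hochberg correction over the family of groups.

    Each level of ``group`` contributes one paired two-tailed t-test
    comparing the two ``within`` conditions subject-by-subject; the BH
    family size is the number of groups.
    """
    if levels is None:
        levels = tuple(sorted(table[within].unique()))
    if len(levels) != 2:
        raise ValueError("paired t-tests need exactly 2 within-factor levels")
    groups = sorted(table[group].unique())
    t_vals, p_vals = [], []
    for g in groups:
        sub = table[table[group] == g]
        wide = sub.pivot(index=subject, columns=within, values=response).dropna()
        if len(wide) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 complete pairs")
        t, p = stats.ttest_rel(wide[levels[0]], wide[levels[1]])
        t_vals.append(float(t))
        p_vals.append(float(p))
    adj = benjamini_hochberg(p_vals)
    return [
        PairwiseResult(
            group_a=(g, levels[0]),
            group_b=(g, levels[1]),
            statistic=t_vals[i],
            raw_p=p_vals[i],
            adjusted_p=float(adj[i]),
            method="benjamini_hochberg",
        )
        for i, g in enumerate(groups)
    ]


def z_test_vs_zero(differences) -> StatResult:
    """Two-sided z-test of a distribution of differences against zero."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: z-test undefined")
    z = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.norm.sf(abs(z))
    return StatResult(
        effect="difference_vs_zero",
        statistic=float(z),
        df=(float(d.size),),
        p=float(p),
        test_kind="z_vs_zero",
    )


def one_tailed_t_below_zero(values) -> StatResult:
    """One-sample, lower-tailed t-test: does the distribution fall below 0?"""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    t, p = stats.ttest_1samp(v, 0.0, alternative="less")
    return StatResult(
        effect="below_zero",
        statistic=float(t),
        df=(float(v.size - 1),),
        p=float(p),
        test_kind="one_tailed_t",
    )
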