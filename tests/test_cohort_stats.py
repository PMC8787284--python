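"""Tests of the statistics battery against hand computations and
independent textbook-formula reference implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from volecall.cohort_stats import (
    StatResult,
    benjamini_hochberg,
    collapse_sex_if_ns,
    mixed_anova,
    one_tailed_t_below_zero,
    one_way_anova_tukey,
    paired_ttests_bh,
    two_way_anova,
    z_test_vs_zero,
)


def balanced_table(values, ages, sexes):
    """values[i][j] is the list of observations for cell (age i, sex j)."""
    rows = []
    for i, age in enumerate(ages):
        for j, sex in enumerate(sexes):
            for v in values[i][j]:
                rows.append(dict(age=age, sex=sex, y=float(v)))
    return pd.DataFrame(rows)


def reference_two_way_balanced(table):
    """Independent oracle: classical balanced two-way ANOVA formulas."""
    y = table["y"].to_numpy()
    grand = y.mean()
    ages = sorted(table["age"].unique())
    sexes = sorted(table["sex"].unique())
    a, b = len(ages), len(sexes)
    n = len(table) // (a * b)
    ss_a = sum(
        b * n * (table.loc[table.age == ag, "y"].mean() - grand) ** 2 for ag in ages
    )
    ss_b = sum(
        a * n * (table.loc[table.sex == sx, "y"].mean() - grand) ** 2 for sx in sexes
    )
    ss_ab = 0.0
    for ag in ages:
        for sx in sexes:
            cell = table.loc[(table.age == ag) & (table.sex == sx), "y"].mean()
            mu_a = table.loc[table.age == ag, "y"].mean()
            mu_b = table.loc[table.sex == sx, "y"].mean()
            ss_ab += n * (cell - mu_a - mu_b + grand) ** 2
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_a - ss_b - ss_ab
    df_err = a * b * (n - 1)
    out = {}
    for name, ss, df in [("age", ss_a, a - 1), ("sex", ss_b, b - 1),
                         ("interaction", ss_ab, (a - 1) * (b - 1))]:
        f = (ss / df) / (ss_err / df_err)
        out[name] = (f, sps.f.sf(f, df, df_err))
    return out


def reference_mixed_balanced(table, dv="count"):
    """Independent oracle: balanced mixed-design ANOVA textbook formulas."""
    ages = sorted(table["age"].unique())
    ctxs = sorted(table["context"].unique())
    a, b = len(ages), len(ctxs)
    subjects = table["pup_id"].unique()
    n = len(subjects) // a
    y = table[dv].to_numpy()
    grand = y.mean()
    subj_means = table.groupby("pup_id")[dv].mean()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_a = sum(n * b * (table.loc[table.age == ag, dv].mean() - grand) ** 2 for ag in ages)
    ss_subj_in_a = ss_between_subj - ss_a
    ss_b = sum(n * a * (table.loc[table.context == c, dv].mean() - grand) ** 2 for c in ctxs)
    ss_ab = 0.0
    for ag in ages:
        for c in ctxs:
            cell = table.loc[(table.age == ag) & (table.context == c), dv].mean()
            mu_a = table.loc[table.age == ag, dv].mean()
            mu_b = table.loc[table.context == c, dv].mean()
            ss_ab += n * (cell - mu_a - mu_b + grand) ** 2
    ss_tot = ((y - grand) ** 2).sum()
    ss_err_within = ss_tot - ss_between_subj - ss_b - ss_ab
    df_subj = a * (n - 1)
    df_err = a * (n - 1) * (b - 1)
    out = {}
    f_a = (ss_a / (a - 1)) / (ss_subj_in_a / df_subj)
    out["age"] = (f_a, sps.f.sf(f_a, a - 1, df_subj))
    f_b = (ss_b / (b - 1)) / (ss_err_within / df_err)
    out["context"] = (f_b, sps.f.sf(f_b, b - 1, df_err))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_err_within / df_err)
    out["interaction"] = (f_ab, sps.f.sf(f_ab, (a - 1) * (b - 1), df_err))
    return out


def random_mixed_table(rng, n_per_age=5, ages=(8, 12, 16)):
    rows = []
    for age in ages:
        for i in range(n_per_age):
            pid = f"a{age}s{i}"
            base = rng.normal(100, 20)
            for ctx in ("isolation", "mother"):
                rows.append(dict(pup_id=pid, age=age, context=ctx,
                                 count=base + rng.normal(0, 10)))
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_hand_computed_2x2(self):
        # 8 observations, all sums of squares computable by hand
        table = balanced_table([[[1, 3], [2, 6]], [[5, 7], [10, 14]]], [6, 8], ["F", "M"])
        res = two_way_anova(table, "y")
        ref = reference_two_way_balanced(table)
        for key in ("age", "sex", "interaction"):
            assert res[key].statistic == pytest.approx(ref[key][0], abs=1e-10)
            assert res[key].p == pytest.approx(ref[key][1], abs=1e-10)
        assert res["age"].df == (1.0, 4.0)

    def test_constant_response_gives_zero_f(self):
        table = balanced_table([[[5, 5], [5, 5]], [[5, 5], [5, 5]]], [6, 8], ["F", "M"])
        res = two_way_anova(table, "y")
        for key in ("age", "sex", "interaction"):
            assert res[key].statistic == 0.0
            assert res[key].p == 1.0

    def test_matches_reference_on_random_balanced_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a_levels = rng.integers(2, 4)
            vals = [
                [rng.normal(50, 10, 4).tolist() for _ in range(2)]
                for _ in range(a_levels)
            ]
            table = balanced_table(vals, list(range(a_levels)), ["F", "M"])
            res = two_way_anova(table, "y")
            ref = reference_two_way_balanced(table)
            for key in ("age", "sex", "interaction"):
                assert res[key].statistic == pytest.approx(ref[key][0], abs=1e-8)
                assert res[key].p == pytest.approx(ref[key][1], abs=1e-8)

    def test_single_level_factor_rejected(self):
        table = balanced_table([[[1, 2], [3, 4]]], [6], ["F", "M"])
        with pytest.raises(ValueError):
            two_way_anova(table, "y")


class TestCollapseRule:
    def _res(self, sex_p):
        return {
            "age": StatResult("age", 5.0, (5, 84), 0.001, "two_way_anova"),
            "sex": StatResult("sex", 2.4, (1, 84), sex_p, "two_way_anova"),
            "interaction": StatResult("interaction", 1.0, (5, 84), 0.4, "two_way_anova"),
        }

    def _table(self):
        rng = np.random.default_rng(0)
        rows = []
        for age in (6, 8, 10):
            for sex in ("F", "M"):
                for _ in range(5):
                    rows.append(dict(age=age, sex=sex, y=rng.normal(100 - 5 * age, 5)))
        return pd.DataFrame(rows)

    def test_nonsignificant_sex_collapses(self):
        d = collapse_sex_if_ns(self._res(0.13), self._table(), "y")
        assert d.collapsed
        assert d.one_way is not None and d.one_way.test_kind == "one_way_anova"
        assert len(d.pairwise) == 3

    def test_significant_sex_blocks_collapse(self):
        d = collapse_sex_if_ns(self._res(0.002), self._table(), "y")
        assert not d.collapsed
        assert d.one_way is None

    def test_boundary_p_exactly_alpha_collapses(self):
        # "not found" means p >= alpha: rejection is strict
        assert collapse_sex_if_ns(self._res(0.05), self._table(), "y").collapsed


class TestOneWayTukey:
    def test_two_group_tukey_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        table = pd.DataFrame(
            dict(age=[6] * 12 + [8] * 12, y=np.concatenate([x, y]))
        )
        _, pairwise = one_way_anova_tukey(table, "y")
        t_p = sps.ttest_ind(x, y).pvalue
        assert pairwise[0].adjusted_p == pytest.approx(t_p, abs=1e-10)

    def test_identical_group_means_p_near_one(self):
        table = pd.DataFrame(
            dict(age=[6, 6, 6, 8, 8, 8, 10, 10, 10],
                 y=[1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        )
        _, pairwise = one_way_anova_tukey(table, "y")
        assert all(p.adjusted_p > 0.999 for p in pairwise)

    def test_omnibus_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.5)]
        table = pd.DataFrame(
            dict(age=np.repeat([6, 8, 10], 8), y=np.concatenate(groups))
        )
        omnibus, _ = one_way_anova_tukey(table, "y")
        f, p = sps.f_oneway(*groups)
        assert omnibus.statistic == pytest.approx(f)
        assert omnibus.p == pytest.approx(p)

    def test_tiny_group_rejected(self):
        table = pd.DataFrame(dict(age=[6, 8, 8], y=[1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            one_way_anova_tukey(table, "y")


class TestMixedAnova:
    def test_zero_within_subject_change_gives_zero_context_f(self):
        rows = []
        rng = np.random.default_rng(1)
        for age in (8, 12):
            for i in range(4):
                level = rng.normal(100, 30)
                for ctx in ("isolation", "mother"):
                    rows.append(dict(pup_id=f"{age}-{i}", age=age, context=ctx, count=level))
        res = mixed_anova(pd.DataFrame(rows))
        assert res["context"].statistic == 0.0
        assert res["context"].p == 1.0

    def test_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            table = random_mixed_table(rng, n_per_age=int(rng.integers(3, 7)))
            res = mixed_anova(table)
            ref = reference_mixed_balanced(table)
            for key in ("age", "context", "interaction"):
                assert res[key].statistic == pytest.approx(ref[key][0], abs=1e-8)
                assert res[key].p == pytest.approx(ref[key][1], abs=1e-8)

    def test_subject_missing_context_rejected(self):
        table = random_mixed_table(np.random.default_rng(0))
        table = table.drop(table.index[0])
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(table)


class TestPairedTBH:
    def test_bh_step_up_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])
        assert (adj <= 0.05).all()

    def test_bh_single_and_degenerate(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 15))
            m = p.size
            order = np.argsort(p)
            brute = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                brute[i] = running
            assert np.allclose(benjamini_hochberg(p), brute, atol=1e-12)

    def test_bh_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 20)
        assert (benjamini_hochberg(p) >= p - 1e-15).all()

    def test_paired_t_per_group_matches_closed_form(self):
        rng = np.random.default_rng(7)
        table = random_mixed_table(rng, n_per_age=6)
        results = paired_ttests_bh(table)
        assert len(results) == 3
        for res in results:
            age = res.group_a[0]
            sub = table[table.age == age].pivot(
                index="pup_id", columns="context", values="count"
            )
            d = (sub["isolation"] - sub["mother"]).to_numpy()
            t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            p = 2 * sps.t.sf(abs(t), d.size - 1)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.raw_p == pytest.approx(p, abs=1e-10)
            assert res.adjusted_p >= res.raw_p - 1e-15


class TestZAndOneTailedT:
    def test_z_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            d = rng.normal(0.3, 1.0, rng.integers(5, 50))
            res = z_test_vs_zero(d)
            z = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            assert res.statistic == pytest.approx(z, abs=1e-12)
            assert res.p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_symmetric_values_z_zero(self):
        res = z_test_vs_zero([-2.0, -1.0, 1.0, 2.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError, match="spread"):
            z_test_vs_zero([0.0, 0.0, 0.0])

    def test_one_tailed_t_strongly_negative(self):
        rng = np.random.default_rng(9)
        values = -1.0 + rng.normal(0, 0.01, 10)
        assert one_tailed_t_below_zero(values).p < 1e-3

    def test_one_tailed_t_mean_zero(self):
        res = one_tailed_t_below_zero([-1.0, 1.0, -2.0, 2.0])
        assert res.p == pytest.approx(0.5)

    def test_mirror_image_flips_p(self):
        rng = np.random.default_rng(10)
        v = rng.normal(0.5, 1.0, 15)
        p1 = one_tailed_t_below_zero(v).p
        p2 = one_tailed_t_below_zero(-v).p
        assert p1 + p2 == pytest.approx(1.0)
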