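"""cohort_stats: t-tests and split-plot mixed ANOVA."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from allotrace.exceptions import ContractError
from allotrace.stats import (
    AnovaResult,
    gg_epsilon,
    mauchly_test,
    mixed_anova,
    mixed_anova_long,
    t_test,
)


# ----------------------------------------------------------------------
# independent naive sums-of-squares oracle (split-plot, epsilon = 1)
# ----------------------------------------------------------------------


def naive_split_plot(y: np.ndarray, groups: np.ndarray):
    """Textbook cell-mean sums-of-squares computation via explicit loops."""
    n, k = y.shape
    labels = list(dict.fromkeys(groups))
    g = len(labels)
    grand = y.mean()

    ss_group = 0.0
    for lab in labels:
        sub = y[groups == lab]
        ss_group += sub.shape[0] * k * (sub.mean() - grand) ** 2
    ss_between_subj = 0.0
    for i in range(n):
        ss_between_subj += k * (y[i].mean() - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    ss_time = 0.0
    for t in range(k):
        ss_time += n * (y[:, t].mean() - grand) ** 2
    ss_gt = 0.0
    for lab in labels:
        sub = y[groups == lab]
        for t in range(k):
            ss_gt += sub.shape[0] * (
                sub[:, t].mean() - sub.mean() - y[:, t].mean() + grand) ** 2
    ss_total = ((y - grand) ** 2).sum()
    ss_err_w = ss_total - ss_between_subj - ss_time - ss_gt

    def f_and_p(ss, df1, ss_err, df2):
        f = (ss / df1) / (ss_err / df2)
        return f, float(sps.f.sf(f, df1, df2))

    out = {}
    out["group"] = f_and_p(ss_group, g - 1, ss_subj_within, n - g)
    out["time"] = f_and_p(ss_time, k - 1, ss_err_w, (n - g) * (k - 1))
    out["group_x_time"] = f_and_p(ss_gt, (g - 1) * (k - 1), ss_err_w, (n - g) * (k - 1))
    return out


def make_frames(y: np.ndarray, groups):
    values = pd.DataFrame(y, index=[f"s{i}" for i in range(len(y))],
                          columns=[f"t{j}" for j in range(y.shape[1])])
    return values, pd.Series(list(groups), index=values.index)


class TestTTest:
    def test_paired_identical_samples(self):
        res = t_test([1.0, 2, 3], [1.0, 2, 3], paired=True)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_paired_constant_nonzero_difference(self):
        res = t_test([2.0, 3, 4, 5], [1.0, 2, 3, 4], paired=True)
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0
        assert res.degenerate

    def test_paired_closed_form_example(self):
        # diffs {2,-1,3,0,1}: mean 1, sd sqrt(2.5), t = sqrt(5)/sqrt(2.5)
        x = np.array([2.0, -1, 3, 0, 1])
        res = t_test(x, np.zeros(5), paired=True)
        assert res.statistic == pytest.approx(math.sqrt(5) / math.sqrt(2.5), abs=1e-12)
        assert res.df == 4
        expected_p = 2 * sps.t.sf(res.statistic, 4)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)
        assert res.p_value == pytest.approx(0.2302, abs=5e-4)

    def test_matches_scipy_paired(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = t_test(x, y, paired=True)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("welch", [False, True])
    def test_matches_scipy_unpaired(self, rng, welch):
        x, y = rng.normal(size=12), rng.normal(1.0, 2.0, size=17)
        res = t_test(x, y, welch=welch)
        ref = sps.ttest_ind(x, y, equal_var=not welch)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == pytest.approx(ref.df, abs=1e-9)

    def test_swap_invariance_up_to_sign(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = t_test(x, y)
        b = t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_sample_size_errors(self):
        with pytest.raises(ContractError):
            t_test([1.0], [2.0], paired=True)
        with pytest.raises(ContractError):
            t_test([1.0], [2.0, 3.0])


class TestMixedAnova:
    def test_matches_naive_oracle_on_random_designs(self, rng):
        for _ in range(50):
            g = int(rng.integers(2, 4))
            per = int(rng.integers(2, 6))
            k = int(rng.integers(2, 6))
            n = g * per
            y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            groups = np.repeat([f"g{j}" for j in range(g)], per)
            values, gser = make_frames(y, groups)
            mine = mixed_anova(values, gser, correction="never")
            oracle = naive_split_plot(y, groups)
            for effect in ("group", "time", "group_x_time"):
                f_ref, p_ref = oracle[effect]
                assert mine[effect].F == pytest.approx(f_ref, abs=1e-9, rel=1e-9)
                assert mine[effect].p_value == pytest.approx(p_ref, abs=1e-9)

    def test_worked_reference_example(self):
        # frozen reference values computed independently with R 4.3:
        #   aov(y ~ group*time + Error(subject/time))
        y = np.array([[3, 5, 7], [4, 6, 9], [2, 4, 6], [5, 7, 8],
                      [6, 6, 7], [5, 4, 6], [7, 8, 8], [4, 5, 5]], float)
        values, groups = make_frames(y, ["A"] * 4 + ["B"] * 4)
        res = mixed_anova(values, groups, correction="never")
        assert res["group"].F == pytest.approx(0.20436, abs=5e-4)
        assert res["group"].p_value == pytest.approx(0.66711, abs=5e-4)
        assert res["time"].F == pytest.approx(47.52632, abs=5e-4)
        assert res["time"].p_value == pytest.approx(1.9838e-06, abs=1e-8)
        assert res["group_x_time"].F == pytest.approx(17.21053, abs=5e-4)
        assert res["group_x_time"].p_value == pytest.approx(0.0002984, abs=5e-6)
        assert (res["group"].df1, res["group"].df2) == (1.0, 6.0)
        assert (res["time"].df1, res["time"].df2) == (2.0, 12.0)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
        values, groups = make_frames(y, ["A"] * 5 + ["B"] * 5)
        mine = mixed_anova(values, groups, correction="never")
        long = values.reset_index().melt(id_vars="index", var_name="time",
                                         value_name="y").rename(columns={"index": "subj"})
        long["group"] = long["subj"].map(dict(zip(values.index, groups)))
        ref = pg.mixed_anova(long, dv="y", within="time", subject="subj",
                             between="group").set_index("Source")
        assert mine["group"].F == pytest.approx(ref.loc["group", "F"], abs=1e-9)
        assert mine["time"].F == pytest.approx(ref.loc["time", "F"], abs=1e-9)
        assert mine["group_x_time"].F == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-9)

    def test_df_structure_matches_design(self, rng):
        # g = 2, n = 5 per group, k = 4 -> uncorrected within dfs (3, 24),
        # between df (1, 8)
        y = rng.normal(size=(10, 4))
        values, groups = make_frames(y, ["A"] * 5 + ["B"] * 5)
        res = mixed_anova(values, groups, correction="never")
        assert (res["time"].df1, res["time"].df2) == (3.0, 24.0)
        assert (res["group"].df1, res["group"].df2) == (1.0, 8.0)
        assert (res["group_x_time"].df1, res["group_x_time"].df2) == (3.0, 24.0)

    def test_gg_correction_shrinks_dfs(self, rng):
        # strongly non-spherical covariance to trigger the correction
        n, k = 12, 4
        base = rng.normal(size=(n, 1))
        y = np.hstack([base + rng.normal(scale=0.05, size=(n, 1)) for _ in range(3)]
                      + [rng.normal(scale=4.0, size=(n, 1))])
        values, groups = make_frames(y, ["A"] * 6 + ["B"] * 6)
        res = mixed_anova(values, groups, correction="always")
        eps = res["time"].gg_epsilon
        assert 1.0 / (k - 1) <= eps < 1.0
        assert res["time"].corrected
        assert res["time"].df1 == pytest.approx((k - 1) * eps)
        assert res["time"].df2 == pytest.approx((n - 2) * (k - 1) * eps)

    def test_epsilon_one_for_compound_symmetry(self):
        # CS covariance: equal variances, equal covariances -> eps exactly 1
        k = 5
        cov = np.full((k, k), 0.3) + np.eye(k) * 0.7
        assert gg_epsilon(cov) == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_lower_bound(self):
        k = 4
        cov = np.zeros((k, k))
        cov[0, 0] = 1.0  # rank-1: maximal non-sphericity
        assert gg_epsilon(cov) == pytest.approx(1.0 / (k - 1), abs=1e-9)

    def test_mauchly_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(12, 4)) @ rng.normal(size=(4, 4))
        cov = np.cov(y, rowvar=False)
        w, p = mauchly_test(cov, 11)
        ref = pg.sphericity(pd.DataFrame(y))
        assert w == pytest.approx(ref.W, abs=1e-12)
        assert p == pytest.approx(ref.pval, abs=1e-12)

    def test_all_equal_observations(self):
        y = np.full((6, 3), 2.5)
        values, groups = make_frames(y, ["A"] * 3 + ["B"] * 3)
        res = mixed_anova(values, groups)
        for effect in res.values():
            assert effect.p_value == 1.0

    def test_missing_cells_rejected(self):
        y = np.random.default_rng(0).normal(size=(6, 3))
        values, groups = make_frames(y, ["A"] * 3 + ["B"] * 3)
        values.iloc[0, 0] = np.nan
        with pytest.raises(ContractError):
            mixed_anova(values, groups)

    def test_long_format_wrapper(self, rng):
        y = rng.normal(size=(6, 3))
        values, groups = make_frames(y, ["A"] * 3 + ["B"] * 3)
        long = values.reset_index().melt(
            id_vars="index", var_name="timepoint", value_name="mean"
        ).rename(columns={"index": "patient_id"})
        long["group"] = long["patient_id"].map(dict(zip(values.index, groups)))
        res_wide = mixed_anova(values, groups, correction="never")
        res_long = mixed_anova_long(long, value="mean", correction="never",
                                    within_order=["t0", "t1", "t2"])
        for effect in res_wide:
            assert res_wide[effect].F == pytest.approx(res_long[effect].F, abs=1e-12)
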