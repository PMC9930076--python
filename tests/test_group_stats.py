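"""Statistics battery: oracles, SPSS conventions, effect sizes, RM-ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

import prokin
from prokin import group_stats as gs


class TestNormalityRouting:
    def test_normal_sample_routes_parametric(self):
        rng = np.random.default_rng(0)
        sw, ks, parametric = gs.check_normality(rng.normal(0, 1, 100))
        assert parametric
        assert 0 <= sw.p_value <= 1 and 0 <= ks.p_value <= 1

    def test_lognormal_sample_routes_nonparametric(self):
        rng = np.random.default_rng(1)
        _, _, parametric = gs.check_normality(np.exp(rng.normal(0, 1, 100)))
        assert not parametric

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(gs.StatError):
            gs.check_normality([1.0, 2.0])
        with pytest.raises(gs.StatError):
            gs.check_normality([3.0] * 10)


def t_sf_numeric(t, df):
    """Two-sided t p-value via direct numeric integration of the t density."""
    c = special.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * special.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t), np.inf)
    return 2 * tail


class TestPairedT:
    def test_hand_computed_oracle(self):
        res = gs.paired_t([1, 2, 3], [2, 3, 5])
        assert res.statistic == pytest.approx(-4.0)
        assert res.df == 2
        assert res.effect_size == pytest.approx(-0.9428, abs=1e-4)
        assert res.effect_label == "large"

    def test_identical_samples_degenerate(self):
        with pytest.raises(gs.StatError):
            gs.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_p_matches_numeric_cdf_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
            res = gs.paired_t(x, y)
            assert res.p_value == pytest.approx(
                t_sf_numeric(res.statistic, res.df), abs=1e-6
            )

    def test_p_matches_signflip_permutation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 8), rng.normal(1.0, 1, 8)
        res = gs.paired_t(x, y)
        d = np.asarray(x) - np.asarray(y)
        n = len(d)
        tobs = abs(res.statistic)
        count = 0
        for signs in itertools.product([1, -1], repeat=n):
            ds = d * signs
            t = ds.mean() / (ds.std(ddof=1) / math.sqrt(n))
            if abs(t) >= tobs - 1e-12:
                count += 1
        p_perm = count / 2**n
        assert res.p_value == pytest.approx(p_perm, abs=0.05)


class TestIndependentT:
    def test_levene_routing_auto(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 8, 30)
        res = gs.independent_t(x, y, "auto")
        assert res.method == "welch_t"  # grossly unequal variances
        rng = np.random.default_rng(14)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        res = gs.independent_t(x, y, "auto")
        assert res.method == "pooled_t"

    def test_identical_samples_give_zero_t(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = gs.independent_t(x, x, "pooled")
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 1.0  # same SD, same n
        pooled = gs.independent_t(x, y, "pooled")
        welch = gs.independent_t(x, y, "welch")
        assert pooled.statistic == pytest.approx(welch.statistic)
        assert pooled.df == pytest.approx(welch.df)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
    )
    def test_welch_df_bounds(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
            return
        res = gs.independent_t(x, y, "welch")
        assert min(len(x), len(y)) - 1 <= res.df + 1e-9
        assert res.df <= len(x) + len(y) - 2 + 1e-9


class TestTFromSummary:
    def test_reproduces_printed_age_row(self):
        res = gs.t_from_summary(48.6, 12.4, 14, 58.1, 15.7, 19, "pooled")
        assert round(res.statistic, 1) == -1.9
        assert res.df == 31

    def test_reproduces_printed_experience_row(self):
        res = gs.t_from_summary(3.1, 2.8, 14, 29.4, 19.8, 19, "welch")
        assert round(res.statistic, 1) == -5.7

    def test_equal_means_give_zero(self):
        assert gs.t_from_summary(5, 1, 10, 5, 1, 10).statistic == 0.0

    def test_matches_sample_level_pooled_t(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 2, 15)
        direct = gs.independent_t(x, y, "pooled")
        summary = gs.t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), "pooled"
        )
        assert summary.statistic == pytest.approx(direct.statistic)
        assert summary.p_value == pytest.approx(direct.p_value)

    def test_degenerate_summaries_rejected(self):
        with pytest.raises(gs.StatError):
            gs.t_from_summary(1, 0, 10, 2, 0, 10)


def exact_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by exhaustive label permutation."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    from scipy.stats import rankdata

    def u1_of(idx):
        ranks = rankdata(pooled)
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u1_of(range(n1))
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u1_of(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_hand_computed_oracle_no_ties(self):
        res = gs.mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0  # U (smaller-group convention)
        assert res.extras["z"] == pytest.approx(-1.5492, abs=1e-4)
        assert res.effect_size == pytest.approx(-0.7746, abs=1e-4)

    def test_identical_multisets_give_zero_z(self):
        res = gs.mann_whitney([1, 2, 3], [3, 1, 2])
        assert res.extras["z"] == 0.0
        assert res.effect_size == 0.0

    def test_u_plus_uprime_is_n1n2(self):
        rng = np.random.default_rng(6)
        x, y = rng.integers(0, 10, 7).astype(float), rng.integers(0, 10, 9).astype(float)
        res = gs.mann_whitney(x, y)
        assert res.extras["u1"] + res.extras["u2"] == len(x) * len(y)

    def test_u_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        a = gs.mann_whitney(x, y)
        b = gs.mann_whitney(np.exp(x), np.exp(y))
        assert a.statistic == b.statistic
        assert a.extras["z"] == pytest.approx(b.extras["z"])

    def test_p_close_to_exact_enumeration_in_tail(self):
        # the tie-corrected normal approximation tracks the exact permutation
        # p closely where decisions are made (small p); x shifted well apart
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(8):
            x = rng.normal(0, 1, 8)
            y = rng.normal(1.8, 1, 8)
            res = gs.mann_whitney(x, y)
            p_exact = exact_mw_p(x, y)
            if p_exact < 0.15:
                assert res.p_value == pytest.approx(p_exact, abs=0.02)
                checked += 1
        assert checked >= 3

    def test_matches_scipy_asymptotic_convention(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 10)
        y = np.round(rng.normal(0.5, 1, 12), 1)  # some ties after rounding
        y = np.concatenate([y, y[:2]])
        res = gs.mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_identical_degenerate(self):
        with pytest.raises(gs.StatError):
            gs.mann_whitney([2.0, 2.0], [2.0, 2.0])


class TestChiSquared:
    def test_reproduces_printed_side_of_limb_row(self):
        res = gs.chi_squared([[9, 5], [13, 6]])
        assert round(res.statistic, 1) == 0.1
        assert round(res.p_value, 2) == 0.80
        assert round(res.effect_size, 1) == 0.0

    def test_identical_row_proportions_give_zero(self):
        res = gs.chi_squared([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_2x2_closed_form(self, counts):
        a, b, c, d = counts
        res = gs.chi_squared([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.statistic == pytest.approx(expected, rel=1e-9)
        assert 0 <= res.effect_size <= 1

    def test_permutation_invariance(self):
        t = np.array([[3, 7, 2], [8, 1, 5]])
        a = gs.chi_squared(t)
        b = gs.chi_squared(t[:, ::-1])
        c = gs.chi_squared(t[::-1, :])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.statistic == pytest.approx(c.statistic)

    def test_zero_margin_degenerate(self):
        with pytest.raises(gs.StatError):
            gs.chi_squared([[0, 0], [3, 4]])


def balanced_rm_data(seed=0, subjects=10, hand_effect=1.5, noise=3.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(subjects):
        base = rng.normal(0, 5)
        for h, hand in enumerate(("MHP", "SHP")):
            for j in range(7):
                rows.append(
                    dict(subject=f"s{s:02d}", hand=hand, joint=f"j{j}",
                         value=base + 2.0 * j + hand_effect * h + rng.normal(0, noise))
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_ss_conservation(self):
        res = prokin.rm_anova_hand_by_joint(balanced_rm_data(seed=1))
        parts = sum(v for k, v in res.ss.items() if k != "total")
        assert parts == pytest.approx(res.ss["total"], rel=1e-8)

    def test_f_hand_equals_paired_t_squared(self):
        df = balanced_rm_data(seed=2)
        res = prokin.rm_anova_hand_by_joint(df)
        piv = df.pivot_table(index="subject", columns="hand", values="value")
        t = gs.paired_t(piv["MHP"], piv["SHP"])
        assert res.table("hand").F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.table("hand").p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_null_hand_effect(self):
        # balanced +/- hand offsets cancel exactly: grand hand means equal,
        # so F_hand = 0 and its eta_G^2 = 0 while the error term is nonzero
        rng = np.random.default_rng(3)
        w = rng.normal(0, 3, size=(10, 7))  # hand-independent subject x joint values
        rows = []
        for s in range(10):
            offset = 1.0 if s % 2 == 0 else -1.0  # cancels over subjects
            for hand in ("MHP", "SHP"):
                for j in range(7):
                    rows.append(
                        dict(subject=f"s{s:02d}", hand=hand, joint=f"j{j}",
                             value=w[s, j] + offset * (hand == "MHP"))
                    )
        res = prokin.rm_anova_hand_by_joint(pd.DataFrame(rows))
        assert res.table("hand").F == pytest.approx(0.0, abs=1e-12)
        assert res.table("hand").eta_g_sq == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = balanced_rm_data(seed=4)
        res = prokin.rm_anova_hand_by_joint(df)
        ref = pg.rm_anova(data=df, dv="value", within=["hand", "joint"],
                          subject="subject", detailed=True).set_index("Source")
        for mine, theirs in (("hand", "hand"), ("joint", "joint"),
                             ("hand_x_joint", "hand * joint")):
            t = res.table(mine)
            assert t.F == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert t.eta_g_sq == pytest.approx(ref.loc[theirs, "ng2"], rel=1e-6)
            assert t.epsilon_gg == pytest.approx(ref.loc[theirs, "eps"], rel=1e-6)

    def test_epsilon_bounds(self):
        res = prokin.rm_anova_hand_by_joint(balanced_rm_data(seed=5))
        joint = res.table("joint")
        assert 1.0 / 6.0 <= joint.epsilon_gg <= 1.0
        assert res.table("hand").epsilon_gg == 1.0

    def test_unbalanced_design_rejected(self):
        df = balanced_rm_data(seed=6)
        df = df.iloc[:-1]  # drop one cell
        with pytest.raises(gs.StatError, match="unbalanced"):
            prokin.rm_anova_hand_by_joint(df)

    def test_eta_g_in_unit_interval(self):
        res = prokin.rm_anova_hand_by_joint(balanced_rm_data(seed=7))
        for t in res.tables:
            assert 0.0 <= t.eta_g_sq <= 1.0
            assert t.F >= 0.0
            assert 0.0 <= t.p_value <= 1.0


class TestEffectSizes:
    def test_r_from_t_printed_rows(self):
        assert round(gs.r_from_t(4.1, 12), 1) == 0.8
        assert round(gs.r_from_t(1.6, 13), 1) == 0.4
        assert gs.r_from_t(0.0, 10) == 0.0

    def test_r_from_z_printed_rows(self):
        assert round(gs.r_from_z(-3.7, 33), 1) == -0.6
        assert round(gs.r_from_z(-3.5, 33), 1) == -0.6
        assert gs.r_from_z(0.0, 33) == 0.0

    def test_r_from_t_monotone_and_limits(self):
        rs = [gs.r_from_t(t, 10) for t in (0.5, 1, 2, 5, 50, 1e6)]
        assert all(b > a for a, b in zip(rs, rs[1:]))
        assert rs[-1] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "value,metric,df,expected",
        [
            (0.8, "pearson_r", None, "large"),
            (0.0, "pearson_r", None, "negligible"),
            (0.3, "pearson_r", None, "medium"),   # boundary -> higher category
            (0.1, "pearson_r", None, "small"),
            (-0.45, "pearson_r", None, "medium"),
            (0.17, "cramers_v", 3, "medium"),
            (0.29, "cramers_v", 3, "large"),
            (0.05, "cramers_v", 3, "negligible"),
            (0.4, "cramers_v", 1, "medium"),
            (0.13, "eta_g_sq", None, "medium"),
            (0.01, "eta_g_sq", None, "negligible"),
        ],
    )
    def test_labels(self, value, metric, df, expected):
        assert gs.classify_effect(value, metric, df_for_v=df) == expected

    def test_unknown_metric_rejected(self):
        with pytest.raises(gs.StatError):
            gs.classify_effect(0.5, "cohens_d")
        with pytest.raises(gs.StatError):
            gs.classify_effect(0.5, "cramers_v", df_for_v=2)

    def test_report_rounding(self):
        res = gs.StatTestResult("paired_t", -1.872, 31.0, 0.0705, effect_size=0.319)
        rounded = gs.round_for_report(res)
        assert rounded == {
            "statistic": -1.9, "df": 31.0, "p_value": 0.07, "effect_size": 0.3
        }
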