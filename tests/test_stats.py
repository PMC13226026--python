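"""Classical inference: oracle equivalence and calibration checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from placentapd import (
    ConfigurationError,
    UnbalancedDesignError,
    ancova_slopes,
    linear_regression,
    oneway_anova_tukey,
    pairwise_contrasts_by_time,
    pearson,
    rm_anova,
)


def mixed_anova_bruteforce(df):
    """Independent cell-means oracle for the mixed-design SS decomposition."""
    wide = df.pivot(index="subject", columns="time", values="value")
    groups = df.drop_duplicates("subject").set_index("subject")["group"].loc[wide.index]
    y = wide.to_numpy()
    grand = y.mean()
    ss = {}
    subj_means = y.mean(axis=1)
    ss["subjects"] = len(wide.columns) * np.sum((subj_means - grand) ** 2)
    glabels = sorted(groups.unique())
    n = (groups == glabels[0]).sum()
    t = y.shape[1]
    gmeans = {g: y[groups.to_numpy() == g].mean() for g in glabels}
    tmeans = y.mean(axis=0)
    ss["group"] = n * t * sum((gmeans[g] - grand) ** 2 for g in glabels)
    ss["time"] = len(glabels) * n * np.sum((tmeans - grand) ** 2)
    inter = 0.0
    for gi, g in enumerate(glabels):
        cell = y[groups.to_numpy() == g].mean(axis=0)
        inter += n * np.sum((cell - gmeans[g] - tmeans + grand) ** 2)
    ss["group:time"] = inter
    ss["subject(group)"] = ss["subjects"] - ss["group"]
    ss["total"] = np.sum((y - grand) ** 2)
    ss["error"] = ss["total"] - ss["subjects"] - ss["time"] - ss["group:time"]
    return ss


def random_long(rng, a=3, n=4, t=3):
    rows = []
    for gi in range(a):
        for si in range(n):
            for ti in range(t):
                rows.append({"subject": f"g{gi}s{si}", "group": f"g{gi}",
                             "time": ti, "value": rng.normal()})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_ss_decomposition_matches_bruteforce(self, rng):
        df = random_long(rng)
        table = rm_anova(df, gg_correction=False)
        oracle = mixed_anova_bruteforce(df)
        for effect in ("group", "subject(group)", "time", "group:time", "error"):
            assert table[effect].ss == pytest.approx(oracle[effect], rel=1e-8)

    def test_balanced_ss_additivity(self, rng):
        df = random_long(rng, a=3, n=5, t=4)
        table = rm_anova(df)
        total = sum(row.ss for row in table.rows)
        assert total == pytest.approx(mixed_anova_bruteforce(df)["total"], rel=1e-8)

    def test_agrees_with_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        df = random_long(rng, a=3, n=6, t=3)
        table = rm_anova(df, gg_correction=False)
        ref = pg.mixed_anova(data=df, dv="value", within="time", subject="subject",
                             between="group")
        ref = ref.set_index("Source")
        assert table["group"].f == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert table["time"].f == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert table["group:time"].f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)
        assert table["group"].p == pytest.approx(ref.loc["group", "p_unc"], rel=1e-6)

    def test_all_identical_values_give_f0_p1(self):
        df = random_long(np.random.default_rng(0))
        df["value"] = 7.0
        table = rm_anova(df)
        for effect in ("group", "time", "group:time"):
            assert table[effect].f == 0.0
            assert table[effect].p == 1.0

    def test_pure_group_shift_matches_oneway_on_subject_means(self, rng):
        df = random_long(rng, a=3, n=6, t=3)
        shift = df["group"].map({"g0": 0.0, "g1": 3.0, "g2": 6.0})
        subj_effect = {s: rng.normal() for s in df["subject"].unique()}
        df["value"] = shift + df["subject"].map(subj_effect)
        # no within-subject variation: time and interaction SS vanish
        table = rm_anova(df, gg_correction=False)
        assert table["time"].ss == pytest.approx(0.0, abs=1e-18)
        assert table["group:time"].ss == pytest.approx(0.0, abs=1e-18)
        subj_means = df.groupby(["subject", "group"])["value"].mean().reset_index()
        oneway, _ = oneway_anova_tukey(
            {g: s["value"].to_numpy() for g, s in subj_means.groupby("group")})
        assert table["group"].f == pytest.approx(oneway["between"].f, rel=1e-9)

    def test_missing_cell_raises_instead_of_imputing(self, rng):
        df = random_long(rng).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            rm_anova(df)

    def test_gg_epsilon_bounds(self, rng):
        df = random_long(rng, a=2, n=8, t=4)
        table = rm_anova(df, gg_correction=True)
        assert 1.0 / 3.0 <= table.gg_epsilon <= 1.0


class TestContrasts:
    def test_bonferroni_never_decreases_p_and_caps_at_one(self, rng):
        df = random_long(rng)
        out = pairwise_contrasts_by_time(df)
        assert (out["p_bonferroni"] >= out["p_unadjusted"] - 1e-15).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_matches_hand_pooled_t(self):
        df = pd.DataFrame({
            "subject": list("abcdef"), "group": ["x"] * 3 + ["y"] * 3,
            "time": [1] * 6, "value": [1.0, 2.0, 3.0, 4.0, 5.0, 9.0],
        })
        out = pairwise_contrasts_by_time(df).iloc[0]
        t_ref, p_ref = sps.ttest_ind([1, 2, 3], [4, 5, 9.0])
        assert out["t"] == pytest.approx(t_ref, rel=1e-12)
        assert out["p_unadjusted"] == pytest.approx(p_ref, rel=1e-12)
        assert out["p_bonferroni"] == pytest.approx(min(1.0, p_ref), rel=1e-12)


def slope_data(rng, slopes, sigma=1.0, intercept_sd=0.0, n=8, grid=(14, 16, 18)):
    rows = []
    for g, slope in slopes.items():
        for s in range(n):
            b = rng.normal(0.0, intercept_sd)
            for gd in grid:
                rows.append({"subject": f"{g}{s}", "group": g, "gd": gd,
                             "value": b + slope * gd + rng.normal(0.0, sigma)})
    return pd.DataFrame(rows)


class TestAncovaSlopes:
    def test_group_slope_estimates_equal_subject_slope_means(self, rng):
        # exact identity in the balanced equal-grid case
        df = slope_data(rng, {"disease": 1.0, "treated": 2.0}, intercept_sd=3.0)
        comp = ancova_slopes(df)
        for g in ("disease", "treated"):
            subj = []
            for _, sub in df[df["group"] == g].groupby("subject"):
                subj.append(np.polyfit(sub["gd"], sub["value"], 1)[0])
            assert comp.group_slopes[g][0] == pytest.approx(np.mean(subj), rel=1e-9)

    def test_agrees_with_statsmodels_interaction_f(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        sma = pytest.importorskip("statsmodels.api")
        df = slope_data(rng, {"a": 1.0, "b": 1.5})
        comp = ancova_slopes(df)
        fit = smf.ols("value ~ gd * C(group)", data=df).fit()
        ref = sma.stats.anova_lm(fit, typ=2)
        assert comp.f_interaction == pytest.approx(ref.loc["gd:C(group)", "F"], rel=1e-8)
        assert comp.p == pytest.approx(ref.loc["gd:C(group)", "PR(>F)"], rel=1e-6)

    def test_null_p_uniform_under_iid_noise(self):
        # type-I calibration at the classical sampling model (equal slopes)
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(300):
            df = slope_data(rng, {"a": 1.0, "b": 1.0}, sigma=1.0, n=6)
            pvals.append(ancova_slopes(df).p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_for_printed_sbp_slope_difference(self):
        # slope gap 1.76 mmHg/day at calibration-scale session noise, n = 8/group:
        # the per-subject-slope test rejects at alpha = 0.001 in most replicates
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(60):
            df = slope_data(rng, {"disease": 3.91, "treated": 2.15}, sigma=5.7,
                            intercept_sd=23.0, n=8, grid=(7, 10, 13, 18))
            comp = ancova_slopes(df)
            rejections += comp.p_subject < 0.001
        assert rejections > 30

    def test_single_gd_rejected(self):
        df = pd.DataFrame({"subject": ["a", "b"], "group": ["x", "y"],
                           "gd": [14, 14], "value": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            ancova_slopes(df)


class TestOnewayTukey:
    def test_identical_lists(self):
        table, tukey = oneway_anova_tukey({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert table["between"].f == 0.0
        assert table["between"].p == 1.0
        assert (tukey["p_tukey"] == 1.0).all()

    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        _, tukey = oneway_anova_tukey({"a": x, "b": y})
        t_ref, p_ref = sps.ttest_ind(x, y)
        # q = t * sqrt(2) identity
        assert tukey["q"].iloc[0] == pytest.approx(abs(t_ref) * np.sqrt(2), rel=1e-10)
        assert tukey["p_tukey"].iloc[0] == pytest.approx(p_ref, rel=1e-6)

    def test_tukey_p_never_below_unadjusted_t(self, rng):
        groups = {g: rng.normal(i * 0.5, 1, 6) for i, g in enumerate("abcd")}
        table, tukey = oneway_anova_tukey(groups)
        mse = table["within"].ms
        df_w = table["within"].df
        for _, row in tukey.iterrows():
            t = row["q"] / np.sqrt(2)
            p_t = 2 * sps.t.sf(t, df_w)
            assert row["p_tukey"] >= p_t - 1e-12

    def test_degenerate_group_rejected(self):
        with pytest.raises(ConfigurationError):
            oneway_anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestPearsonRegression:
    def test_perfect_linear_relations(self):
        x = np.arange(1.0, 9.0)
        assert pearson(x, 2 * x + 1).r == 1.0
        assert pearson(x, -x).r == -1.0

    def test_hand_product_moment_fixture(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 3, 4, 5])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        res = pearson(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        t_hand = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 3), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_regression_recovers_exact_line(self):
        res = linear_regression([1.0, 2, 3, 4], [3.0, 5, 7, 9])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.p == 0.0

    def test_regression_matches_normal_equations_on_random_fixture(self, rng):
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        res = linear_regression(x, y)
        slope_ref, intercept_ref = np.polyfit(x, y, 1)
        assert res.slope == pytest.approx(slope_ref, rel=1e-10)
        assert res.intercept == pytest.approx(intercept_ref, rel=1e-10)
        ref = sps.linregress(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ConfigurationError):
            linear_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
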