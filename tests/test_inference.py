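import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from pseshift.inference import (
    adjust_pvalues,
    mixed_anova,
    one_sample_t,
    paired_t,
    pearson_r,
    pool_baseline,
    quadratic_dose_contrast,
    within_subject_sem,
)


class TestPairedT:
    def test_matches_scipy_and_closed_form(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = paired_t(x, y)
        t_ref, p_ref = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)
        d = x - y
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)

    def test_dz_equals_t_over_sqrt_n(self, rng):
        res = paired_t(rng.normal(0.4, 1, 24))
        assert res.effect_size == pytest.approx(res.statistic / math.sqrt(24), abs=1e-12)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = paired_t(np.zeros(10))
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert math.isnan(res.effect_size)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            paired_t([0.3])


class TestOneSampleT:
    def test_values_at_null_give_zero_t(self):
        with pytest.warns(UserWarning):
            res = one_sample_t(np.full(12, 1 / 3), mu0=1 / 3)
        assert res.statistic == 0.0

    def test_all_correct_panel_gives_large_t(self):
        res = one_sample_t(np.ones(48), mu0=1 / 3)
        assert res.statistic > 100 or math.isinf(res.statistic)

    def test_guessing_panel_rarely_beats_chance(self):
        # 48 raters x 6 triangle trials at chance 1/3: level ~ alpha
        rng = np.random.default_rng(0)
        sig = 0
        seeds = 400
        for _ in range(seeds):
            acc = rng.binomial(6, 1 / 3, size=48) / 6
            if one_sample_t(acc, mu0=1 / 3).p_value < 0.05:
                sig += 1
        assert sig / seeds <= 0.07  # non-significant in >= 93% of panels


class TestMixedAnova:
    @staticmethod
    def _mixed_data(rng, n_per=12):
        rows = []
        for g in range(2):
            for s in range(n_per):
                base = rng.normal()
                for w in range(3):
                    rows.append(dict(
                        subject=f"g{g}s{s}", grp=f"G{g}", cond=f"C{w}",
                        y=base + 0.3 * w + 0.5 * g * (w == 2) + rng.normal(),
                    ))
        return pd.DataFrame(rows)

    def test_matches_pingouin_on_one_between_one_within(self, rng):
        df = self._mixed_data(rng)
        mine = mixed_anova(df, "y", "subject", within=["cond"], between=["grp"])
        ref = pg.mixed_anova(df, dv="y", within="cond", between="grp",
                             subject="subject")
        for effect, source in (("grp", "grp"), ("cond", "cond"),
                               ("grp:cond", "Interaction")):
            m = mine.set_index("effect").loc[effect]
            r = ref.set_index("Source").loc[source]
            assert m["F"] == pytest.approx(r["F"], rel=1e-9)
            assert m["p_value"] == pytest.approx(r["p_unc"], rel=1e-9)
            assert m["partial_eta_sq"] == pytest.approx(r["np2"], rel=1e-9)

    def test_matches_anovarm_on_two_within_factors(self, rng):
        rows = []
        for s in range(10):
            base = rng.normal()
            for a in range(2):
                for b in range(3):
                    rows.append(dict(subject=f"s{s}", A=f"a{a}", B=f"b{b}",
                                     y=base + 0.4 * a + 0.1 * b + rng.normal()))
        df = pd.DataFrame(rows)
        mine = mixed_anova(df, "y", "subject", within=["A", "B"]).set_index("effect")
        ref = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        for eff in ("A", "B", "A:B"):
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[eff, "F Value"], rel=1e-9)
            assert mine.loc[eff, "p_value"] == pytest.approx(ref.loc[eff, "Pr > F"], rel=1e-9)

    def test_two_level_within_factor_equals_squared_paired_t(self, rng):
        rows = []
        for s in range(14):
            base = rng.normal()
            rows.append(dict(subject=f"s{s}", w="A", y=base + rng.normal()))
            rows.append(dict(subject=f"s{s}", w="B", y=base + 0.3 + rng.normal()))
        df = pd.DataFrame(rows)
        F = mixed_anova(df, "y", "subject", within=["w"])["F"].iloc[0]
        wide = df.pivot(index="subject", columns="w", values="y")
        t = paired_t(wide["B"], wide["A"]).statistic
        assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_unbalanced_design_rejected(self, rng):
        df = self._mixed_data(rng)
        with pytest.raises(ValueError, match="unbalanced|incomplete"):
            mixed_anova(df.iloc[:-1], "y", "subject", within=["cond"], between=["grp"])
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df[df.subject != "g0s0"], "y", "subject",
                        within=["cond"], between=["grp"])

    def test_three_factor_mixed_layout_runs(self, rng):
        # the omnibus layout: odor within, drug and orientation between
        rows = []
        for o, orient in enumerate(("het", "hom")):
            for d, drug in enumerate(("ATO", "OT", "VP")):
                for s in range(4):
                    base = rng.normal()
                    for w, odor in enumerate(("AND", "EST", "CTRL")):
                        rows.append(dict(subject=f"{orient}{drug}{s}",
                                         orient=orient, drug=drug, odor=odor,
                                         y=base + rng.normal()))
        res = mixed_anova(pd.DataFrame(rows), "y", "subject",
                          within=["odor"], between=["drug", "orient"])
        assert set(res["effect"]) == {
            "drug", "orient", "odor", "drug:orient", "drug:odor",
            "orient:odor", "drug:orient:odor"}
        odor = res.set_index("effect").loc["odor"]
        assert odor["df1"] == 2 and odor["df2"] == 2 * (24 - 6)


class TestQuadraticContrast:
    def test_linear_profile_annihilated(self, rng):
        # integer-valued scores keep the cancellation exact in floating point
        base = rng.integers(0, 100, 24).astype(float)
        x = np.column_stack([base, base + 1.0, base + 2.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = quadratic_dose_contrast(x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_inverted_u_detected(self, rng):
        delta = 0.05
        x = np.column_stack([rng.normal(0, 0.01, 24),
                             delta + rng.normal(0, 0.01, 24),
                             rng.normal(0, 0.01, 24)])
        res = quadratic_dose_contrast(x)
        assert res.statistic > 10 and res.p_value < 0.001

    def test_equals_polynomial_trend_decomposition(self, rng):
        x = rng.normal(size=(20, 3))
        res = quadratic_dose_contrast(x)
        # orthonormal quadratic contrast of the one-way RM decomposition
        u = x @ (np.array([1.0, -2.0, 1.0]) / math.sqrt(6))
        F_ref = len(u) * u.mean() ** 2 / u.var(ddof=1)
        assert res.statistic == pytest.approx(F_ref, rel=1e-10)
        assert res.df1 == 1 and res.df2 == 19
        assert res.effect_size == pytest.approx(
            res.statistic / (res.statistic + res.df2), rel=1e-12)

    def test_missing_dose_level_excluded(self, rng):
        x = rng.normal(size=(10, 3))
        x[3, 1] = np.nan
        assert quadratic_dose_contrast(x).n == 9


class TestPearson:
    def test_perfect_and_inverse_correlation(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x).effect_size == pytest.approx(1.0)
        noisy = -x + rng.normal(0, 0.3, 20)
        assert pearson_r(x, noisy).effect_size < -0.8

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = pearson_r(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.effect_size == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)
        assert res.df1 == 38

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        rej = sum(
            pearson_r(rng.normal(size=30), rng.normal(size=30)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08


class TestWithinSubjectSem:
    def test_pure_additive_offsets_give_zero_sem(self):
        rows = [dict(subject=f"s{s}", cond=c, y=s * 10.0 + {"a": 1, "b": 2}[c])
                for s in range(8) for c in ("a", "b")]
        sem = within_subject_sem(pd.DataFrame(rows), "y", "subject", ["cond"])
        assert np.allclose(sem, 0.0)

    def test_single_condition_reduces_to_ordinary_sem(self, rng):
        y = rng.normal(size=10)
        df = pd.DataFrame(dict(subject=range(10), cond="a", y=y))
        sem = within_subject_sem(df, "y", "subject", ["cond"])
        assert sem.iloc[0] == pytest.approx(y.std(ddof=1) / math.sqrt(10))

    def test_matches_two_step_oracle(self, rng):
        rows = [dict(subject=f"s{s}", cond=c, y=rng.normal() + off)
                for s in range(12) for c, off in (("a", 0), ("b", 0.5), ("c", 1))]
        df = pd.DataFrame(rows)
        sem = within_subject_sem(df, "y", "subject", ["cond"])
        grand = df["y"].mean()
        adj = df["y"] - df.groupby("subject")["y"].transform("mean") + grand
        for c in ("a", "b", "c"):
            v = adj[df["cond"] == c]
            ref = v.std(ddof=1) / math.sqrt(len(v)) * math.sqrt(3 / 2)
            assert sem[c] == pytest.approx(ref, rel=1e-12)


class TestPoolBaseline:
    def test_identical_cohorts_pool_quietly(self, rng):
        a = rng.normal(0.03, 0.05, 24)
        b = rng.normal(0.03, 0.05, 24)
        pooled, check = pool_baseline(a, b)
        assert pooled.shape == (48,)
        assert check.p_value > 0.05
        # pooled n = 48 gives df 47 downstream
        assert paired_t(pooled).df1 == 47

    def test_discordant_cohorts_warn_but_still_pool(self, rng):
        a = rng.normal(0.0, 0.01, 24)
        b = rng.normal(0.5, 0.01, 24)
        with pytest.warns(UserWarning, match="differ"):
            pooled, check = pool_baseline(a, b)
        assert pooled.shape == (48,)
        assert check.p_value < 0.001


def test_bonferroni_and_holm_corrections():
    p = np.array([0.01, 0.04, 0.5])
    assert np.allclose(adjust_pvalues(p), [0.03, 0.12, 1.0])
    holm = adjust_pvalues(p, "holm")
    assert np.allclose(holm, [0.03, 0.08, 0.5])
    with pytest.raises(ValueError):
        adjust_pvalues(p, "fdr")
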