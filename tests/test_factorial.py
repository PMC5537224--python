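"""Factorial statistics: oracles for ANOVA, Tukey, Fisher, GG epsilon, mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drphenome import (
    fisher_exact_2x2,
    fit_longitudinal_mixed,
    generate_longitudinal_weights,
    gg_epsilon,
    mixed_rm_anova,
    tukey_hsd,
    two_way_anova,
)

from .conftest import balanced_factors


def regression_type3_oracle(values, age, diet):
    """Independent Type-III SS via sum-coded full-vs-reduced OLS in statsmodels."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "age": age, "diet": diet})
    model = smf.ols("y ~ C(age, Sum) * C(diet, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    return {
        "age": float(tab.loc["C(age, Sum)", "sum_sq"]),
        "diet": float(tab.loc["C(diet, Sum)", "sum_sq"]),
        "age:diet": float(tab.loc["C(age, Sum):C(diet, Sum)", "sum_sq"]),
        "residual": float(tab.loc["Residual", "sum_sq"]),
        "p_age": float(tab.loc["C(age, Sum)", "PR(>F)"]),
    }


class TestTwoWayAnova:
    def test_hand_decomposition(self):
        vals = [1, 2, 1, 2, 3, 4, 3, 4]
        age = ["young"] * 4 + ["old"] * 4
        diet = ["AL", "AL", "EOD", "EOD"] * 2
        res = two_way_anova(vals, age, diet)
        assert res["age"].ss == pytest.approx(8.0)
        assert res["age"].F == pytest.approx(16.0)
        assert res["age"].p == pytest.approx(stats.f.sf(16, 1, 4), abs=1e-6)
        assert res["diet"].F == pytest.approx(0.0, abs=1e-12)
        assert res["age:diet"].F == pytest.approx(0.0, abs=1e-12)

    def test_location_invariance(self, rng):
        age, diet = balanced_factors(6)
        y = rng.normal(size=24)
        r1, r2 = two_way_anova(y, age, diet), two_way_anova(y + 117.3, age, diet)
        for term in ("age", "diet", "age:diet"):
            assert r1[term].F == pytest.approx(r2[term].F, rel=1e-9)

    def test_balanced_matches_projection_oracle(self, rng):
        age, diet = balanced_factors(5)
        for _ in range(20):
            y = rng.normal(size=20)
            res = two_way_anova(y, age, diet)
            oracle = regression_type3_oracle(y, age, diet)
            for term in ("age", "diet", "age:diet", "residual"):
                assert res[term].ss == pytest.approx(oracle[term], rel=1e-8)

    def test_unbalanced_type3_matches_statsmodels(self, rng):
        # cell sizes like the screen's 16/16/23/23 design, scaled down
        age = ["young"] * 9 + ["old"] * 13
        diet = ["AL"] * 4 + ["EOD"] * 5 + ["AL"] * 6 + ["EOD"] * 7
        for _ in range(10):
            y = rng.normal(size=22) + (np.asarray(age) == "old") * 0.5
            res = two_way_anova(y, age, diet)
            oracle = regression_type3_oracle(y, age, diet)
            for term in ("age", "diet", "age:diet"):
                assert res[term].ss == pytest.approx(oracle[term], rel=1e-6)
            assert res["age"].p == pytest.approx(oracle["p_age"], rel=1e-6)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                ["young", "young", "young", "young", "old", "old"],
                ["AL", "AL", "EOD", "EOD", "AL", "AL"],
            )


class TestTukey:
    def test_identical_groups_p_near_one(self):
        g = {k: np.array([1.0, 2.0, 3.0]) for k in "abcd"}
        res = tukey_hsd(g)
        assert (res["p_adj"] > 0.999).all()

    def test_matches_independent_implementation(self, rng):
        # scipy's tukey_hsd computes the same adjustment through its own
        # confidence-interval machinery; agreement validates the
        # Tukey-Kramer statistic and the range-distribution lookup
        sizes = {"a": 6, "b": 6, "c": 9, "d": 7}
        samples = {k: rng.normal(size=n) for k, n in sizes.items()}
        mine = tukey_hsd(samples)
        ref = stats.tukey_hsd(*samples.values())
        order = list(samples)
        for r in mine.itertuples():
            i, j = order.index(r.group_a), order.index(r.group_b)
            assert r.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-3)

    def test_approx_tail_matches_exact(self, rng):
        samples = {k: rng.normal(size=8) for k in "abcd"}
        exact = tukey_hsd(samples)
        fast = tukey_hsd(samples, approx=True)
        assert np.allclose(exact["p_adj"], fast["p_adj"], atol=1e-4)

    def test_adjusted_p_conservative_vs_pairwise_t(self, rng):
        y = {k: rng.normal(loc=i * 0.5, size=8) for i, k in enumerate("abcd")}
        res = tukey_hsd(y)
        for r in res.itertuples():
            t_p = stats.ttest_ind(y[r.group_a], y[r.group_b]).pvalue
            assert r.p_adj >= t_p - 1e-12

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full enumeration at fixed margins (exact rationals)."""
    from math import comb

    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x) * comb(r2, c1 - x)
    obs = probs[a]
    return sum(v for v in probs.values() if v <= obs) / denom


class TestFisher:
    def test_perfect_separation_hand_value(self):
        odds, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)
        assert odds == np.inf

    def test_independence_p_one(self):
        _, p = fisher_exact_2x2([[4, 7], [4, 7]])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_tables(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        tab = [[a, b], [c, d]]
                        if (a + b == 0 and c + d == 0) or n == 0:
                            continue
                        _, p = fisher_exact_2x2(tab)
                        assert p == pytest.approx(
                            min(fisher_enumeration_oracle(tab), 1.0), rel=1e-9
                        ), tab

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 5
        S = 2.0 * ((1 - 0.4) * np.eye(k) + 0.4 * np.ones((k, k)))
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_rank_one_contrast_covariance_hits_lower_bound(self):
        v = np.array([3.0, -1.0, -1.0, -1.0])
        assert gg_epsilon(np.outer(v, v)) == pytest.approx(1 / 3)

    def test_scale_invariance(self, rng):
        A = rng.normal(size=(4, 4))
        S = A @ A.T
        assert gg_epsilon(S) == pytest.approx(gg_epsilon(17.0 * S))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]))


def _rm_dataset(rng, n_per_cell=6, k=4, level_effect=0.0, subj_sd=1.0, noise=0.5):
    rows = []
    s = 0
    for age in ("young", "old"):
        for diet in ("AL", "EOD"):
            for _ in range(n_per_cell):
                base = rng.normal(0, subj_sd)
                for level in range(k):
                    rows.append(
                        dict(
                            subject=f"s{s}", age=age, diet=diet, level=level,
                            value=base + level_effect * level + rng.normal(0, noise),
                        )
                    )
                s += 1
    return pd.DataFrame(rows)


class TestMixedRmAnova:
    def test_within_identical_responses_zero_f(self, rng):
        df = _rm_dataset(rng, k=3, noise=0.0, level_effect=0.0)
        res = mixed_rm_anova(df)
        assert res["level"].F == pytest.approx(0.0, abs=1e-9)

    def test_single_level_collapses_to_two_way(self, rng):
        df = _rm_dataset(rng, k=1, noise=0.3)
        res = mixed_rm_anova(df)
        direct = two_way_anova(
            df["value"], df["age"], df["diet"]
        )
        for term in ("age", "diet", "age:diet"):
            assert res[term].F == pytest.approx(direct[term].F, rel=1e-9)

    def test_missing_level_rejected(self, rng):
        df = _rm_dataset(rng, k=3)
        df = df[~((df["subject"] == "s0") & (df["level"] == 2))]
        with pytest.raises(ValueError, match="s0"):
            mixed_rm_anova(df)

    def test_compound_symmetric_data_epsilon_near_one(self, rng):
        df = _rm_dataset(rng, n_per_cell=250, k=4, subj_sd=1.0, noise=1.0)
        res = mixed_rm_anova(df)
        assert res["level"].epsilon == pytest.approx(1.0, abs=0.02)

    def test_gg_correction_raises_p_of_large_f(self, rng):
        # df deflation is conservative in the rejection-relevant tail; for
        # middling F (p near 0.3) the two tails can cross, so the check
        # conditions on the uncorrected p being small
        for _ in range(8):
            df = _rm_dataset(rng, k=4, level_effect=0.3)
            res = mixed_rm_anova(df)
            for t in res.terms:
                if t.p_gg is not None and np.isfinite(t.F) and t.p <= 0.1:
                    assert t.p_gg >= t.p - 1e-12

    def test_matches_pingouin_on_combined_between_factor(self, rng):
        # pingouin handles one between factor; a combined 4-level cell factor
        # spans the same between-subject space, so the within main effect,
        # its epsilon, and the summed between/interaction SS must agree.
        pg = pytest.importorskip("pingouin")
        df = _rm_dataset(rng, n_per_cell=5, k=3, level_effect=0.4)
        df["cell"] = df["age"] + "/" + df["diet"]
        aov = pg.mixed_anova(
            dv="value", within="level", between="cell", subject="subject",
            data=df, correction=True,
        ).set_index("Source")
        res = mixed_rm_anova(df)
        assert res["level"].F == pytest.approx(float(aov.loc["level", "F"]), rel=1e-6)
        # epsilon oracle: pingouin's estimator on cell-mean-centered scores
        # (the pooled within-cell covariance both should be using)
        wide = df.pivot_table(index=["cell", "subject"], columns="level", values="value")
        centered = wide - wide.groupby(level="cell").transform("mean")
        eps_oracle = float(pg.epsilon(centered.reset_index(drop=True), correction="gg"))
        assert res["level"].epsilon == pytest.approx(eps_oracle, rel=1e-6)
        my_between = res["age"].ss + res["diet"].ss + res["age:diet"].ss
        assert my_between == pytest.approx(float(aov.loc["cell", "SS"]), rel=1e-6)
        my_inter = sum(res[f"level:{t}"].ss for t in ("age", "diet", "age:diet"))
        assert my_inter == pytest.approx(float(aov.loc["Interaction", "SS"]), rel=1e-6)


class TestLongitudinalMixed:
    def test_noise_free_collapses_to_arm_mean_difference(self):
        w = generate_longitudinal_weights(4, 2, 5, -5.0, 0.0, 0.0, seed=0)
        res = fit_longitudinal_mixed(w)
        assert res.dr_effect == pytest.approx(-5.0, abs=1e-3)

    def test_linearity_in_response(self):
        w = generate_longitudinal_weights(6, 2, 8, -4.0, 1.0, 0.5, seed=1)
        r1 = fit_longitudinal_mixed(w)
        w2 = w.assign(weight_g=2 * w["weight_g"])
        r2 = fit_longitudinal_mixed(w2)
        assert r2.dr_effect == pytest.approx(2 * r1.dr_effect, rel=1e-6)

    def test_recovers_diet_effect_and_variance_components(self):
        hits = 0
        for seed in range(10):
            w = generate_longitudinal_weights(20, 2, 15, -5.0, 2.0, 1.0, seed=seed)
            res = fit_longitudinal_mixed(w)
            if abs(res.dr_effect + 5.0) < 1.5:
                hits += 1
        assert hits >= 9

    def test_too_few_cages_rejected(self):
        w = generate_longitudinal_weights(1, 2, 5, 0.0, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            fit_longitudinal_mixed(w)
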