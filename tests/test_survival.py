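"""Lifespan statistics: KM vs brute force, log-rank, lifespan summaries, Gompertz."""

import itertools

import numpy as np
import pandas as pd
import pytest

from drphenome import (
    endpoint_summaries,
    fit_gompertz,
    generate_survival_cohort,
    km_estimate,
    logrank_test,
    max_lifespan,
    mean_lifespan,
    mortality_doubling_time,
)
from drphenome.simulate import gompertz_a_for_mean


def product_limit_oracle(times, events):
    """Independent brute-force product-limit computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    curve = {0.0: 1.0}
    for t in sorted(set(times)):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        if d:
            s *= 1 - d / n_at_risk
        curve[t] = s
    return curve


class TestKaplanMeier:
    def test_first_death_step(self, survival_frame):
        rec = survival_frame([100, 150, 200, 250], [1, 1, 1, 1])
        km = km_estimate(rec)
        assert km.set_index("time").loc[100.0, "survival"] == pytest.approx(0.75)

    def test_all_censored_flat_at_one(self, survival_frame):
        rec = survival_frame([100, 200], [0, 0])
        km = km_estimate(rec)
        assert (km["survival"] == 1.0).all()

    def test_uncensored_km_equals_one_minus_ecdf(self, survival_frame, rng):
        t = rng.gamma(5, 100, size=40)
        km = km_estimate(survival_frame(t, np.ones_like(t)))
        srt = np.sort(t)
        for time, surv in zip(km["time"], km["survival"]):
            assert surv == pytest.approx(1 - (srt <= time).mean(), abs=1e-12)

    def test_matches_brute_force_on_all_censoring_patterns(self, survival_frame, rng):
        # every censoring pattern of an 8-animal cohort, ties included
        times = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        for pattern in itertools.product([0, 1], repeat=8):
            km = km_estimate(survival_frame(times, pattern))
            oracle = product_limit_oracle(times, pattern)
            for time, surv in zip(km["time"], km["survival"]):
                assert surv == pytest.approx(oracle[time], abs=1e-12), pattern

    def test_empty_input_rejected(self, survival_frame):
        with pytest.raises(ValueError):
            km_estimate(survival_frame([], []))


class TestLogrank:
    def test_identical_arms_null(self, survival_frame):
        rec = survival_frame([100, 200, 300], [1, 1, 1])
        chi2, p = logrank_test(rec, rec.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_singleton_arms_hand_value(self, survival_frame):
        # O-E = 0.5, V = 0.25 -> chi2 = 1, p = 0.3173
        chi2, p = logrank_test(
            survival_frame([1.0], [1]), survival_frame([2.0], [1])
        )
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(0.31731, abs=1e-4)

    def test_symmetric_in_arm_order(self, survival_frame, rng):
        a = survival_frame(rng.exponential(100, 30), rng.integers(0, 2, 30))
        b = survival_frame(rng.exponential(120, 25), rng.integers(0, 2, 25))
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_invariant_under_monotone_time_relabeling(self, survival_frame, rng):
        t = rng.exponential(100, 30).round(0) + 1
        e = rng.integers(0, 2, 30)
        a, b = survival_frame(t[:15], e[:15]), survival_frame(t[15:], e[15:])
        chi2 = logrank_test(a, b)[0]
        a2, b2 = a.copy(), b.copy()
        a2["time_days"], b2["time_days"] = np.sqrt(a["time_days"]), np.sqrt(b["time_days"])
        assert logrank_test(a2, b2)[0] == pytest.approx(chi2, rel=1e-9)

    def test_no_event_arm_warns(self, survival_frame):
        with pytest.warns(UserWarning):
            logrank_test(
                survival_frame([5.0, 6.0], [0, 0]), survival_frame([1.0, 2.0], [1, 1])
            )


class TestLifespanSummaries:
    def test_mean_of_death_times(self, survival_frame):
        assert mean_lifespan(survival_frame([700, 800, 900], [1, 1, 1])) == 800.0

    def test_censored_records_excluded(self, survival_frame):
        base = survival_frame([700, 800, 900], [1, 1, 1])
        plus = survival_frame([700, 800, 900, 650], [1, 1, 1, 0])
        assert mean_lifespan(plus) == mean_lifespan(base)

    def test_no_deaths_undefined(self, survival_frame):
        with pytest.raises(ValueError):
            mean_lifespan(survival_frame([100.0], [0]))

    def test_ceiling_rule_reproduces_cohort_subset_sizes(self, survival_frame, rng):
        # 43 and 37 deaths -> longest-living 20% subsets of 9 and 8 animals
        a = survival_frame(rng.normal(800, 100, 43), np.ones(43))
        b = survival_frame(rng.normal(900, 100, 37), np.ones(37))
        res = max_lifespan(a, b, fraction=0.2)
        assert (res["k_a"], res["k_b"]) == (9, 8)

    def test_single_animal_subset(self, survival_frame):
        a = survival_frame([1, 2, 3, 4, 5], [1] * 5)
        res = max_lifespan(a, a.copy(), fraction=0.2)
        assert res["k_a"] == 1 and res["mean_a"] == 5.0

    def test_fraction_bounds(self, survival_frame):
        a = survival_frame([1.0], [1])
        with pytest.raises(ValueError):
            max_lifespan(a, a, fraction=0.0)


class TestGompertz:
    def test_boundary_exponential_data_gives_near_zero_slope(self):
        rec = generate_survival_cohort(800, a=1 / 800, b=0.0, seed=5)
        fit = fit_gompertz(rec)
        assert fit.b < 1e-3  # hazard essentially flat
        assert fit.mdt > 600  # doubling time far beyond the observed range

    def test_mdt_b_identity(self):
        b = np.log(2) / 83.6
        rec = generate_survival_cohort(300, a=gompertz_a_for_mean(800, b), b=b, seed=6)
        fit = fit_gompertz(rec)
        assert mortality_doubling_time(fit) * fit.b == pytest.approx(np.log(2))

    def test_mdt_halves_when_slope_doubles(self):
        f1 = fit_gompertz(
            generate_survival_cohort(
                400, gompertz_a_for_mean(800, np.log(2) / 90), np.log(2) / 90, seed=7
            )
        )
        fake = type(f1)(
            a=f1.a, b=2 * f1.b, mdt=np.log(2) / (2 * f1.b), loglik=0.0,
            se_a=0.0, se_b=0.0, converged=True,
        )
        assert mortality_doubling_time(fake) == pytest.approx(
            mortality_doubling_time(f1) / 2
        )

    def test_loglik_local_optimum_on_grid(self):
        b = np.log(2) / 85
        rec = generate_survival_cohort(400, gompertz_a_for_mean(850, b), b, seed=8)
        fit = fit_gompertz(rec)
        t = rec["time_days"].to_numpy()
        e = rec["event"].to_numpy()

        def ll(a, bb):
            return np.sum(e * (np.log(a) + bb * t)) - np.sum((a / bb) * np.expm1(bb * t))

        for fa in np.linspace(0.8, 1.2, 20):
            for fb in np.linspace(0.8, 1.2, 20):
                assert fit.loglik >= ll(fit.a * fa, fit.b * fb) - 1e-6

    def test_censoring_enters_likelihood(self):
        b = np.log(2) / 85
        rec = generate_survival_cohort(
            400, gompertz_a_for_mean(850, b), b, censor_time=900.0, seed=9
        )
        fit = fit_gompertz(rec)
        assert fit.n_censored > 0
        assert fit.mdt == pytest.approx(85.0, rel=0.25)

    def test_too_few_deaths_rejected(self, survival_frame):
        with pytest.raises(ValueError):
            fit_gompertz(survival_frame([100, 200, 300], [1, 1, 0]))


class TestEndpointSummaries:
    def test_cause_proportions(self, survival_frame):
        a = survival_frame([1, 2, 3], [1, 1, 1])
        a["cause"] = ["neoplastic", "neoplastic", "other"]
        a["tumor_count"] = [2, 1, 0]
        b = survival_frame([1, 2], [1, 1])
        b["cause"] = ["other", "other"]
        b["tumor_count"] = [0, 1]
        res = endpoint_summaries(a, b)
        assert res["causes"]["a"]["neoplastic"] == pytest.approx(2 / 3)
        assert res["causes"]["b"]["other"] == 1.0
        assert res["tumor_mean"]["a"] == pytest.approx(1.0)

    def test_degenerate_tumor_comparison_reports_p_one(self, survival_frame):
        a = survival_frame([1, 2], [1, 1])
        a["cause"] = "other"
        a["tumor_count"] = [0, 0]
        with pytest.warns(UserWarning, match="degenerate"):
            res = endpoint_summaries(a, a.copy())
        assert res["tumor_test"][1] == 1.0
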