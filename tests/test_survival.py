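"""Survival evaluation against hand-computed oracles: product-limit curve,
horizon mortality, log-rank O-E formula, and Cox summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from rmkllpp.simulate import SurvivalSpec, generate_clinical, generate_survival
from rmkllpp.survival import (
    cox_arithmetic,
    cox_fit,
    km_estimate,
    logrank_test,
    mortality_at,
)

# 6 subjects: event times 2, 4, 4 and censorings at 3, 5, 6.
# Risk sets: t=2 n=6 d=1 -> S=5/6; t=4 n=4 d=2 -> S=(5/6)(2/4)=5/12
HAND_TIMES = np.array([2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
HAND_EVENTS = np.array([1, 0, 1, 1, 0, 0])


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        surv = km_estimate(np.arange(1.0, 6.0), np.zeros(5, dtype=int))
        assert surv(4.9) == pytest.approx(1.0)

    def test_all_events_closed_form(self):
        surv = km_estimate(np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=int))
        np.testing.assert_allclose(
            surv(np.array([1.0, 2.0, 3.0])), [2 / 3, 1 / 3, 0.0], atol=1e-12
        )

    def test_hand_computed_product_limit(self):
        surv = km_estimate(HAND_TIMES, HAND_EVENTS)
        assert surv(2.5) == pytest.approx(5 / 6)
        assert surv(4.5) == pytest.approx(5 / 12)

    def test_invariant_to_censoring_placement_after_last_event(self):
        # the censorings at t=5 and t=6 fall after the last event (t=4);
        # moving them further out cannot change any risk set at an event
        s1 = km_estimate(HAND_TIMES, HAND_EVENTS)
        times2 = HAND_TIMES.copy()
        times2[HAND_TIMES >= 5.0] = [50.0, 60.0]
        s2 = km_estimate(times2, HAND_EVENTS)
        for t in (1.0, 2.5, 4.5):
            assert s1(t) == pytest.approx(s2(t))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([-1.0, 2.0]), np.array([1, 1]))


class TestMortalityAt:
    def test_no_events_before_horizon_is_zero(self):
        assert mortality_at(np.array([10.0, 20.0]), np.array([0, 0]), 5.0) == 0.0

    def test_all_dead_before_horizon_is_hundred(self):
        assert mortality_at(np.array([1.0, 2.0]), np.array([1, 1]), 5.0) == pytest.approx(100.0)

    def test_hand_example_at_two_and_a_half(self):
        got = mortality_at(HAND_TIMES, HAND_EVENTS, 2.5)
        assert got == pytest.approx(100 * (1 - 5 / 6))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.tile(HAND_TIMES, 2)
        events = np.tile(HAND_EVENTS, 2)
        groups = np.repeat([0, 1], 6)
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_hand_observed_minus_expected_formula(self):
        # two groups, all events, no ties across groups
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=int)
        groups = np.array([0, 1, 0, 1, 0, 1])
        o_minus_e = 0.0
        var = 0.0
        order = np.argsort(times)
        at_risk = list(order)
        for idx in order:
            n = len(at_risk)
            n1 = sum(groups[i] == 0 for i in at_risk)
            d = 1
            o_minus_e += (groups[idx] == 0) - n1 / n
            if n > 1:
                var += (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
            at_risk.remove(idx)
        expected_chi2 = o_minus_e**2 / var
        stat, _ = logrank_test(times, events, groups)
        assert stat == pytest.approx(expected_chi2, rel=1e-10)

    def test_invariant_to_group_relabeling(self, rng):
        times = rng.exponential(100, size=40)
        events = rng.integers(0, 2, size=40)
        groups = np.repeat([0, 1, 2, 3], 10)
        s1, p1 = logrank_test(times, events, groups)
        remap = np.array([3, 0, 2, 1])[groups]
        s2, p2 = logrank_test(times, events, remap)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(HAND_TIMES, HAND_EVENTS, np.zeros(6))


class TestCox:
    def test_reported_quantities_internally_consistent(self):
        labels = np.repeat([0, 1], 150)
        clin = generate_clinical(
            labels,
            SurvivalSpec(log_hazard_per_subtype=(0.0, 1.0), censoring_rate=0.2),
            seed=0,
        )
        clin["subtype"] = labels + 1
        fit = cox_fit(clin)
        t = fit.table
        np.testing.assert_allclose(t["hr"], np.exp(t["coefficient"]), rtol=1e-12)
        np.testing.assert_allclose(t["wald_z"], t["coefficient"] / t["se"], rtol=1e-12)
        np.testing.assert_allclose(
            t["ci_lower"], np.exp(t["coefficient"] - 1.96 * t["se"]), rtol=1e-12
        )
        np.testing.assert_allclose(
            t["ci_upper"], np.exp(t["coefficient"] + 1.96 * t["se"]), rtol=1e-12
        )

    def test_published_style_row_arithmetic(self):
        # a reported Cox row with coefficient 1.214 and SE 0.323 implies
        # HR ~ 3.37 with 95% CI ~ (1.79, 6.34)
        derived = cox_arithmetic(1.214, 0.323)
        assert derived["hr"] == pytest.approx(3.369, rel=5e-3)
        assert derived["wald_z"] == pytest.approx(3.756, rel=5e-3)
        assert derived["ci_lower"] == pytest.approx(1.787, rel=5e-3)
        assert derived["ci_upper"] == pytest.approx(6.349, rel=5e-3)

    def test_null_subtype_coefficient_near_zero(self):
        coefs = []
        for r in range(10):
            labels = np.repeat([0, 1], 150)
            clin = generate_clinical(
                labels, SurvivalSpec(censoring_rate=0.2, log_hazard_per_subtype=(0.0, 0.0)),
                seed=200 + r,
            )
            clin["subtype"] = labels + 1
            fit = cox_fit(clin)
            coefs.append(fit.table.loc["subtype", "coefficient"])
        assert abs(np.mean(coefs)) < 0.15

    def test_recovers_planted_subtype_log_hazard(self):
        coefs = []
        for r in range(10):
            labels = np.repeat([0, 1], 300)
            clin = generate_clinical(
                labels, SurvivalSpec(log_hazard_per_subtype=(0.0, 1.2), censoring_rate=0.2),
                seed=400 + r,
            )
            clin["subtype"] = labels + 1
            coefs.append(cox_fit(clin).table.loc["subtype", "coefficient"])
        assert abs(np.mean(coefs) - 1.2) < 0.2

    def test_stage_treatment_coded_against_stage_one(self):
        labels = np.repeat([0, 1], 200)
        clin = generate_clinical(
            labels, SurvivalSpec(log_hazard_per_subtype=(0.0, 0.8), censoring_rate=0.2), seed=9
        )
        clin["subtype"] = labels + 1
        fit = cox_fit(clin)
        terms = set(fit.table.index)
        assert "stage_I" not in terms
        assert {"stage_II", "stage_III", "stage_IV"} <= terms

    def test_missing_covariates_rejected(self):
        labels = np.repeat([0, 1], 20)
        clin = generate_clinical(
            labels, SurvivalSpec(censoring_rate=0.1, log_hazard_per_subtype=(0.0, 0.0)), seed=1
        )
        clin["subtype"] = labels + 1
        clin.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cox_fit(clin)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            cox_arithmetic(1.0, 0.0)
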