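import numpy as np
import pandas as pd
import pytest

from omniscreen import survival as sv
from omniscreen import synthetic as syn

# product-limit fixture computed by hand (and cross-checked against
# R survival::survfit): times/events below give S = .875, .75, .6, .4, 0
# at event times 1, 2, 3, 5, 7
PL_TIMES = [1, 2, 2, 3, 4, 5, 6, 7]
PL_EVENTS = [1, 0, 1, 1, 0, 1, 0, 1]
PL_EXPECTED = {1: 0.875, 2: 0.75, 3: 0.6, 5: 0.4, 7: 0.0}


class TestKMCurve:
    def test_no_censoring_equals_empirical_survival(self):
        c = sv.km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        # property at larger n: S(t) = fraction of times > t
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=200)
        c = sv.km_curve(t, np.ones(200))
        for q in (1.0, 5.0, 20.0):
            assert sv.survival_at(c, q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_no_events_curve_never_drops(self):
        c = sv.km_curve([1, 2, 3], [0, 0, 0])
        assert np.allclose(c.survival, 1.0)

    def test_hand_computed_product_limit_fixture(self):
        c = sv.km_curve(PL_TIMES, PL_EVENTS)
        got = {t: s for t, s in zip(c.times, c.survival)}
        for t, expected in PL_EXPECTED.items():
            assert got[t] == pytest.approx(expected, abs=1e-12)

    def test_at_risk_and_events_bookkeeping(self):
        c = sv.km_curve(PL_TIMES, PL_EVENTS)
        assert list(c.at_risk) == [8, 7, 5, 4, 3, 2, 1]
        assert list(c.n_events) == [1, 1, 1, 0, 1, 0, 1]


class TestSurvivalAt:
    def test_time_zero_is_one(self):
        c = sv.km_curve([1, 2, 3], [1, 1, 1])
        assert sv.survival_at(c, 0) == 1.0

    def test_between_event_times_takes_value_after_first_drop(self):
        c = sv.km_curve([1, 2, 3], [1, 1, 1])
        assert sv.survival_at(c, 1.5) == pytest.approx(2 / 3)
        assert sv.survival_at(c, 2.0) == pytest.approx(1 / 3)  # right-continuous

    def test_right_continuous_and_non_increasing(self):
        c = sv.km_curve(PL_TIMES, PL_EVENTS)
        grid = np.linspace(0, 8, 100)
        vals = [sv.survival_at(c, t) for t in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_exponential_simulation_matches_closed_form_within_greenwood_ci(self):
        t, e = syn.simulate_survival(n=2000, hazard=0.05, censor_rate=0.0, seed=21)
        c = sv.km_curve(t, e)
        s20 = sv.survival_at(c, 20.0)
        # Greenwood variance at t=20
        upto = c.times <= 20.0
        var = s20**2 * np.sum(
            c.n_events[upto] / (c.at_risk[upto] * (c.at_risk[upto] - c.n_events[upto])))
        half = 1.96 * np.sqrt(var)
        assert abs(s20 - np.exp(-1.0)) <= half

    def test_greenwood_variance_zero_before_first_event(self):
        c = sv.km_curve([5, 6, 7], [1, 1, 1])
        assert sv.survival_at(c, 1.0) == 1.0


class TestLogRank:
    def test_duplicated_group_gives_zero_chi_square(self):
        t = [1, 2, 3, 4, 5] * 2
        e = [1, 1, 0, 1, 1] * 2
        g = ["a"] * 5 + ["b"] * 5
        res = sv.logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert res.df == 1

    def test_two_group_fixture_matches_independent_reference(self):
        # frozen from R survival::survdiff on the same data
        t = [2, 4, 5, 7, 9, 1, 3, 6, 8, 10]
        e = [1, 1, 0, 1, 1, 1, 1, 1, 0, 1]
        g = ["a"] * 5 + ["b"] * 5
        res = sv.logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.129196515343, abs=1e-9)
        assert res.p_value == pytest.approx(0.719266578104, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_separated_hazards_detected(self):
        t1, e1 = syn.simulate_survival(100, 0.12, censor_rate=0.1, seed=1)
        t2, e2 = syn.simulate_survival(100, 0.03, censor_rate=0.1, seed=2)
        res = sv.logrank_test(np.r_[t1, t2], np.r_[e1, e2],
                              ["hi"] * 100 + ["lo"] * 100)
        assert res.p_value < 1e-6


class TestSplitByExpression:
    def test_median_split_ties_to_lower(self):
        out = sv.split_by_expression(pd.Series([1, 2, 3, 4],
                                               index=list("abcd")), "median")
        assert list(out) == ["low", "low", "high", "high"]

    def test_tertile_split_on_nine_distinct_values(self):
        out = sv.split_by_expression(pd.Series(range(9)), "tertile")
        assert list(out) == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sv.split_by_expression(pd.Series([2.0, 2.0, 2.0]), "median")

    def test_prognostic_split_detected(self):
        """High-expression samples planted with lower hazard separate on
        the log-rank test."""
        t_hi, e_hi = syn.simulate_survival(150, 0.03, censor_rate=0.1, seed=31)
        t_lo, e_lo = syn.simulate_survival(150, 0.10, censor_rate=0.1, seed=32)
        rng = np.random.default_rng(33)
        expr = np.r_[rng.normal(10, 1, 150), rng.normal(5, 1, 150)]
        split = sv.split_by_expression(pd.Series(expr), "median")
        res = sv.logrank_test(np.r_[t_hi, t_lo], np.r_[e_hi, e_lo], split)
        assert res.p_value < 0.01


class TestMethylationCalls:
    @pytest.mark.parametrize("beta,status", [
        (0.5, "methylated"),
        (0.1, "unmethylated"),
        (0.3, "unmethylated"),  # boundary goes to unmethylated
    ])
    def test_cutoff_rule(self, beta, status):
        call = sv.call_methylation(beta, marker="M", sample_id="s")
        assert call.status == status

    def test_missing_beta_gives_no_call(self):
        assert sv.call_methylation(float("nan")) is None
        calls = sv.call_methylation_series(pd.Series({"s1": 0.5, "s2": np.nan}))
        assert set(calls) == {"s1"}


class TestJointStrata:
    def test_four_combinations_map_to_four_labels(self):
        betas_a = pd.Series({"s1": 0.1, "s2": 0.1, "s3": 0.6, "s4": 0.6})
        betas_b = pd.Series({"s1": 0.1, "s2": 0.6, "s3": 0.1, "s4": 0.6})
        strata = sv.joint_strata(sv.call_methylation_series(betas_a, "A"),
                                 sv.call_methylation_series(betas_b, "B"))
        assert strata["s1"] == "A_unmeth+B_unmeth"
        assert strata["s2"] == "A_unmeth+B_meth"
        assert strata["s3"] == "A_meth+B_unmeth"
        assert strata["s4"] == "A_meth+B_meth"
        assert strata.nunique() == 4

    def test_samples_missing_one_marker_dropped(self):
        calls_a = sv.call_methylation_series(pd.Series({"s1": 0.5, "s2": 0.5}))
        calls_b = sv.call_methylation_series(pd.Series({"s1": 0.1}))
        strata = sv.joint_strata(calls_a, calls_b)
        assert list(strata.index) == ["s1"]
        with pytest.raises(ValueError):
            sv.joint_strata(calls_a, sv.call_methylation_series(pd.Series({"s9": 0.1})))

    def test_ordered_hazards_give_ordered_survival(self):
        """Across the four planted strata with decreasing hazards, S(20)
        increases and the 4-group log-rank separates."""
        meth, clin = syn.simulate_two_marker_cohort(n_per_stratum=60, seed=17)
        calls_a = sv.call_methylation_series(meth.beta.loc["markerA.p1"], "markerA")
        calls_b = sv.call_methylation_series(meth.beta.loc["markerB.p1"], "markerB")
        strata = sv.joint_strata(calls_a, calls_b, "markerA", "markerB")
        tab = clin.table.loc[strata.index]
        s20 = []
        for label in sv.stratum_labels("markerA", "markerB"):
            sub = strata.index[strata == label]
            curve = sv.km_curve(tab.loc[sub, "os_months"], tab.loc[sub, "os_event"])
            s20.append(sv.survival_at(curve, 20.0))
        assert all(a < b for a, b in zip(s20, s20[1:]))
        res = sv.logrank_test(tab["os_months"], tab["os_event"], strata)
        assert res.df == 3
        assert res.p_value < 0.01
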