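import numpy as np
import pytest

import dpccn
from dpccn import (
    SurvivalDataset,
    aiken_west,
    combine_risk,
    kaplan_meier,
    log_rank,
    risk_classify,
)


class TestAikenWest:
    def test_matches_textbook_ols_inference(self):
        # fixed small dataset; compare against statsmodels run explicitly here
        import statsmodels.api as sm

        rng = np.random.default_rng(50)
        xk = rng.standard_normal(30)
        xl = rng.standard_normal(30)
        y = 0.5 * xk - 0.2 * xl + 0.8 * xk * xl + rng.standard_normal(30)
        res = aiken_west(xk, xl, y)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([xk, xl, xk * xl]))).fit()
        assert res.beta_kl == pytest.approx(ref.params[3], abs=1e-10)
        assert res.p_kl == pytest.approx(ref.pvalues[3], abs=1e-10)

    def test_power_on_strong_interaction(self):
        rng = np.random.default_rng(51)
        xk = rng.standard_normal(200)
        xl = rng.standard_normal(200)
        y = xk * xl + rng.normal(0, 0.1, 200)
        res = aiken_west(xk, xl, y)
        assert res.relevant
        assert res.p_kl < 1e-6

    def test_null_mostly_irrelevant(self):
        rng = np.random.default_rng(52)
        hits = 0
        runs = 200
        for _ in range(runs):
            xk = rng.standard_normal(200)
            xl = rng.standard_normal(200)
            y = rng.standard_normal(200)
            hits += aiken_west(xk, xl, y).relevant
        assert hits / runs <= 0.10

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            aiken_west(x, 2 * x, np.random.default_rng(1).standard_normal(10))


class TestRiskClassify:
    def test_positive_sign_type7_quantile(self):
        # values 1..9, q = 2/3: type-7 quantile is 6.33, so six low / three high
        g = risk_classify(np.arange(1.0, 10.0), "+", q=2 / 3)
        assert (g.assignment == "low_risk").sum() == 6
        assert (g.assignment == "high_risk").sum() == 3
        assert g.assignment[-1] == "high_risk"

    def test_negative_sign_mirrors(self):
        pos = risk_classify(np.arange(1.0, 10.0), "+", q=2 / 3)
        neg = risk_classify(-np.arange(1.0, 10.0), "-", q=2 / 3)
        np.testing.assert_array_equal(pos.assignment, neg.assignment)

    def test_group_sizes_deterministic_in_q(self):
        vals = np.random.default_rng(2).standard_normal(300)
        for q in (0.25, 0.5, 2 / 3, 0.9):
            g = risk_classify(vals, "+", q=q)
            # continuous values: low group = #{v < q-quantile} = floor-ish of q*n
            assert (g.assignment == "low_risk").sum() == (
                vals < np.quantile(vals, q)
            ).sum()

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            risk_classify(np.full(10, 1.0), "+")


class TestCombineRisk:
    def test_identical_inputs_no_exclusion(self):
        g = risk_classify(np.arange(1.0, 10.0), "+", q=2 / 3)
        c = combine_risk(g, g)
        np.testing.assert_array_equal(c.assignment, g.assignment)

    def test_fully_discordant_all_excluded(self):
        g1 = risk_classify(np.arange(1.0, 9.0), "+", q=0.5)
        g2 = risk_classify(-np.arange(1.0, 9.0), "+", q=0.5)
        assert not np.any(g1.assignment == g2.assignment)
        c = combine_risk(g1, g2)
        assert (c.assignment == "excluded").all()

    def test_intersection_semantics_by_enumeration(self):
        from dpccn.validate import RiskGroups

        labels = ["low_risk", "high_risk"]
        a1 = np.array([labels[i] for i in (0, 0, 1, 1, 0, 1)], dtype="<U9")
        a2 = np.array([labels[i] for i in (0, 1, 1, 0, 0, 1)], dtype="<U9")
        c = combine_risk(
            RiskGroups(a1, q=0.5, direction=1), RiskGroups(a2, q=0.5, direction=1)
        )
        expected = ["low_risk", "excluded", "high_risk", "excluded", "low_risk", "high_risk"]
        np.testing.assert_array_equal(c.assignment, expected)


def _groups(labels):
    from dpccn.validate import RiskGroups

    return RiskGroups(np.array(labels, dtype="<U9"), q=0.5, direction=1)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        data = SurvivalDataset(
            time=np.array([1.0, 2, 3, 4, 2, 5, 6, 7]), event=np.ones(8, int)
        )
        groups = _groups(["low_risk"] * 4 + ["high_risk"] * 4)
        km = kaplan_meier(data, groups)
        low = km["low_risk"]
        # times 1,2,3,4 all observed: S drops by 1/4 each
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            i = np.searchsorted(low.timeline, t)
            assert low.survival[i] == pytest.approx(s)

    def test_all_censored_flat_curve(self):
        data = SurvivalDataset(
            time=np.array([1.0, 2, 3, 4, 5, 6, 7, 8]),
            event=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        )
        groups = _groups(["low_risk"] * 4 + ["high_risk"] * 4)
        km = kaplan_meier(data, groups)
        assert np.all(km["low_risk"].survival == 1.0)
        assert np.isinf(km["low_risk"].median)

    def test_hand_computed_product_limit_with_censoring(self):
        # times 1,2,3+,4,5 (censor at 3):
        # S(1)=4/5, S(2)=4/5*3/4=3/5, S(4)=3/5*1/2=3/10, S(5)=0; median=4
        data = SurvivalDataset(
            time=np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]),
            event=np.array([1, 1, 0, 1, 1, 1, 1, 1, 1, 1]),
        )
        groups = _groups(["low_risk"] * 5 + ["high_risk"] * 5)
        km = kaplan_meier(data, groups)
        low = km["low_risk"]
        expected = {1.0: 0.8, 2.0: 0.6, 4.0: 0.3, 5.0: 0.0}
        for t, s in expected.items():
            i = np.searchsorted(low.timeline, t)
            assert low.survival[i] == pytest.approx(s)
        assert low.median == pytest.approx(4.0)

    def test_empty_group_rejected(self):
        data = SurvivalDataset(time=np.arange(1.0, 5.0), event=np.ones(4, int))
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier(data, _groups(["low_risk"] * 4))


class TestLogRank:
    def test_identical_groups_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4, 5])
        data = SurvivalDataset(time=np.r_[t, t], event=np.ones(10, int))
        groups = _groups(["low_risk"] * 5 + ["high_risk"] * 5)
        chi2, p = log_rank(data, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_hand_computed_o_minus_e(self):
        # direct O-E/V computation on distinct event times, no censoring
        t1 = np.array([1.0, 3, 5])
        t2 = np.array([2.0, 4, 6])
        data = SurvivalDataset(time=np.r_[t1, t2], event=np.ones(6, int))
        groups = _groups(["low_risk"] * 3 + ["high_risk"] * 3)

        # oracle: iterate event times, accumulate observed-expected and variance
        times = np.r_[t1, t2]
        grp1 = np.array([True] * 3 + [False] * 3)
        o_minus_e = 0.0
        var = 0.0
        for t in np.sort(times):
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & grp1).sum()
            d = 1  # one event per time here
            o1 = 1 if (times == t)[grp1.nonzero()[0]].any() else 0
            e1 = d * n1 / n
            o_minus_e += o1 - e1
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var

        chi2, p = log_rank(data, groups)
        assert chi2 == pytest.approx(expected_chi2, abs=1e-8)

    def test_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 20)
        e = (rng.random(20) < 0.8).astype(int)
        data1 = SurvivalDataset(time=t, event=e)
        data2 = SurvivalDataset(time=7.3 * t, event=e)
        groups = _groups(["low_risk"] * 10 + ["high_risk"] * 10)
        chi2_1, _ = log_rank(data1, groups)
        chi2_2, _ = log_rank(data2, groups)
        assert chi2_1 == pytest.approx(chi2_2, abs=1e-10)

    def test_single_group_rejected(self):
        data = SurvivalDataset(time=np.arange(1.0, 5.0), event=np.ones(4, int))
        with pytest.raises(ValueError):
            log_rank(data, _groups(["low_risk"] * 4))
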