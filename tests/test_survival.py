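"""Kaplan-Meier, log-rank, cut-point search, Cox regression, Harrell's C."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from lifelines.utils import concordance_index as lifelines_c

from mzlprog import survival as sv

from _oracles import brute_concordance, brute_cutpoint, random_censored_fixture


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        km = sv.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        km = sv.km_estimate([5.0, 8.0, 2.0], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0

    def test_single_subject_step(self):
        km = sv.km_estimate([5.0], [1])
        assert km.survival_at(4.999) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_censoring_does_not_drop_curve(self):
        km = sv.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert np.all(np.diff(km.survival) <= 0)
        assert km.times.tolist() == [1.0, 3.0]

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.integers(1, 15, size=60).astype(float)
        km = sv.km_estimate(t, np.ones(60, dtype=int))
        for u in np.unique(t):
            assert km.survival_at(u) == pytest.approx((t > u).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sv.km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 3.0, 5.0, 1.0, 3.0, 5.0]
        e = [1, 0, 1, 1, 0, 1]
        chi2, p = sv.logrank_test(t, e, [0, 0, 0, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        g = rng.integers(0, 2, size=40)
        a = sv.logrank_test(t, e, g)
        b = sv.logrank_test(t, e, 1 - g)
        assert a == pytest.approx(b)

    def test_six_subject_fixture_matches_hand_tabulation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        g = np.array([0, 1, 0, 1, 0, 1])
        # hand tabulation of sum(O - E) and hypergeometric variance, group 1
        o_minus_e = v = 0.0
        for u in np.unique(t[e == 1]):
            at = t >= u
            n_at, n1 = at.sum(), (at & (g == 1)).sum()
            d = ((t == u) & (e == 1)).sum()
            d1 = ((t == u) & (e == 1) & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n_at
            if n_at > 1:
                v += d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1)
        chi2, _ = sv.logrank_test(t, e, g)
        assert chi2 == pytest.approx(o_minus_e**2 / v)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            sv.logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_null_p_values_are_uniform(self, rng):
        # under exchangeable groups the p-value should be ~U(0,1)
        pvals = []
        for _ in range(400):
            t = rng.exponential(10, size=60)
            e = (rng.random(60) < 0.7).astype(int)
            g = rng.permutation(np.repeat([0, 1], 30))
            pvals.append(sv.logrank_test(t, e, g)[1])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCutpointSearch:
    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        marker = np.round(rng.uniform(0, 100, size=n), 0)
        t = rng.exponential(20, size=n)
        e = (rng.random(n) < 0.7).astype(int)
        if e.sum() < 2:
            e[:2] = 1
        res = sv.cutpoint_search(marker, t, e, minprop=0.1)
        c_oracle, z_oracle = brute_cutpoint(marker, t, e, minprop=0.1)
        assert res.cutoff == pytest.approx(c_oracle)
        assert res.standardized_statistic == pytest.approx(z_oracle)

    def test_minprop_excludes_single_subject_splits(self):
        marker = np.arange(10, dtype=float)
        t = np.arange(1, 11, dtype=float)
        e = np.ones(10, dtype=int)
        res = sv.cutpoint_search(marker, t, e, minprop=0.1)
        assert min(res.n_low, res.n_high) >= 2
        assert min(res.n_low, res.n_high) / 10 > 0.1

    def test_deterministic_given_data(self, null_cohort):
        df = null_cohort
        a = sv.cutpoint_search(df["CD21"], df["os_months"], df["os_event"])
        b = sv.cutpoint_search(df["CD21"], df["os_months"], df["os_event"])
        assert a == b

    def test_direction_recorded_for_adverse_marker(self, mature_cohort_spec):
        from mzlprog import synthetic as syn

        df, _ = syn.generate_cohort(mature_cohort_spec(seed=5))
        res = sv.cutpoint_search(df["CD21"], df["os_months"], df["os_event"])
        assert res.direction_high_is_adverse is False  # planted protective step

    def test_no_admissible_split_rejected(self):
        marker = np.array([1.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="minprop"):
            sv.cutpoint_search(marker, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], minprop=0.4)


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        n = 1500
        df = pd.DataFrame(
            {
                "t": rng.exponential(10, size=n),
                "e": np.ones(n, dtype=int),
                "x": rng.integers(0, 2, size=n),
            }
        )
        rep = sv.fit_cox(df, "t", "e", ["x"])
        assert abs(np.log(rep.table.loc["x", "hazard_ratio"])) < 0.2
        assert rep.converged

    def test_stratification_removes_confounding_by_baseline(self, rng):
        # stratum shifts both the baseline hazard and the covariate prevalence;
        # the stratified fit is unbiased for the shared covariate effect
        n = 4000
        s = rng.integers(0, 2, size=n)
        x = (rng.random(n) < 0.2 + 0.6 * s).astype(int)
        lam = 0.01 * np.exp(1.5 * s + 0.7 * x)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame({"t": t, "e": 1, "x": x, "s": s})
        strat = sv.fit_cox(df, "t", "e", ["x"], strata=["s"])
        naive = sv.fit_cox(df, "t", "e", ["x"])
        b_strat = np.log(strat.table.loc["x", "hazard_ratio"])
        b_naive = np.log(naive.table.loc["x", "hazard_ratio"])
        assert abs(b_strat - 0.7) < 0.15
        assert abs(b_naive - 0.7) > abs(b_strat - 0.7)

    def test_reports_c_index_in_unit_interval(self, null_cohort):
        rep = sv.fit_cox(null_cohort, "os_months", "os_event", ["age_ge_60"])
        assert 0.0 <= rep.c_index <= 1.0
        assert rep.events == int(null_cohort["os_event"].sum())


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert sv.concordance_index([4, 3, 2, 1], t, [1, 1, 1, 1]) == 1.0

    def test_all_tied_risks_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert sv.concordance_index([2, 2, 2, 2], t, [1, 1, 1, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        risk, t, e = random_censored_fixture(rng, int(rng.integers(10, 100)))
        assert sv.concordance_index(risk, t, e) == pytest.approx(
            brute_concordance(risk, t, e)
        )

    def test_agrees_with_lifelines_on_ties_free_data(self, rng):
        t = rng.exponential(10, size=80)
        e = (rng.random(80) < 0.6).astype(int)
        risk = rng.normal(size=80)
        ours = sv.concordance_index(risk, t, e)
        # lifelines orders by predicted survival time (higher = longer)
        assert ours == pytest.approx(1.0 - lifelines_c(t, risk, e))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st_hyp.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_risk_transform(self, seed):
        rng = np.random.default_rng(seed)
        risk, t, e = random_censored_fixture(rng, 30)
        c1 = sv.concordance_index(risk, t, e)
        c2 = sv.concordance_index(np.exp(risk / 3.0) + 7.0, t, e)
        assert c1 == pytest.approx(c2)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            sv.concordance_index([1, 2], [3.0, 4.0], [0, 0])
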