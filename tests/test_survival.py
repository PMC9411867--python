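import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from apakit.model import APAError, ClinicalTable
from apakit.survival import (
    km_estimate,
    km_points_table,
    logrank,
    median_split,
    survival_by_apa,
    survival_table,
)
from apakit.synthetic import gen_coupled_survival


def clinical_from(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(table=pd.DataFrame(
        {"time": times, "event": events}, index=ids))


class TestMedianSplit:
    def test_even_split(self):
        row = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        g = median_split(row)
        assert sorted(g.samples("low")) == ["a", "b"]
        assert sorted(g.samples("high")) == ["c", "d"]

    def test_tie_at_median_goes_low(self):
        row = pd.Series([0.1, 0.5, 0.9, 0.95], index=list("abcd"))
        g = median_split(row)
        # 0.5 < median 0.7 -> low; exact-median values also go low
        row2 = pd.Series([0.1, 0.5, 0.5, 0.9], index=list("abcd"))
        g2 = median_split(row2)
        assert sorted(g2.samples("low")) == ["a", "b", "c"]
        assert g2.samples("high") == ["d"]
        assert sorted(g.samples("low")) == ["a", "b"]

    def test_constant_values_error(self):
        with pytest.raises(APAError, match="constant|undefined"):
            median_split(pd.Series([0.3, 0.3, 0.3, 0.3], index=list("abcd")))

    def test_too_few_values(self):
        with pytest.raises(APAError):
            median_split(pd.Series([0.1, 0.9], index=list("ab")))


class TestKMEstimate:
    def test_no_censoring_steps(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        got = dict(zip(km.curve["time"], km.curve["survival"]))
        assert got[1.0] == pytest.approx(2 / 3)
        assert got[2.0] == pytest.approx(1 / 3)
        assert got[3.0] == pytest.approx(0.0)
        assert km.median == pytest.approx(2.0)

    def test_all_censored_flat_curve_undefined_median(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert np.allclose(km.curve["survival"], 1.0)
        assert np.isnan(km.median)

    def test_censored_sample_reduces_risk_set(self):
        # hand product over risk sets: t=1 (3 at risk, 1 event) -> 2/3;
        # censor at 2; t=3 (1 at risk, 1 event) -> 2/3 * 0 = 0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=40)
        km = km_estimate(t, np.ones_like(t))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_empty_input_error(self):
        with pytest.raises(APAError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        res = logrank(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0)

    def test_hand_tabulated_small_case(self):
        # low: events at 1, 3; high: events at 2, 4
        # risk-set tabulation over event times gives O_high=2, E_high=8/3,
        # V = 1/4 + 2/9 + 1/4 = 13/18 -> chi2 = (2 - 8/3)^2 / (13/18)
        res = logrank([1, 3], [1, 1], [2, 4], [1, 1])
        assert res.chi_square == pytest.approx((2 - 8 / 3) ** 2 / (13 / 18))

    def test_matches_lifelines_chi_square(self):
        rng = np.random.default_rng(9)
        t1 = rng.exponential(10, 30)
        t2 = rng.exponential(5, 30)
        e1 = (rng.random(30) > 0.2).astype(int)
        e2 = (rng.random(30) > 0.2).astype(int)
        res = logrank(t1, e1, t2, e2)
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-6)
        assert res.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_invariant_under_label_swap(self):
        rng = np.random.default_rng(10)
        t1 = rng.exponential(10, 20)
        t2 = rng.exponential(6, 25)
        e1 = np.ones(20)
        e2 = np.ones(25)
        a = logrank(t1, e1, t2, e2)
        b = logrank(t2, e2, t1, e1)
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.p == pytest.approx(b.p)
        assert a.hr == pytest.approx(1 / b.hr)

    def test_zero_event_group_flagged_unstable(self):
        res = logrank([1, 2, 3], [0, 0, 0], [1, 2, 3], [1, 1, 1])
        assert res.hr_unstable
        assert np.isnan(res.hr)
        assert res.chi_square >= 0

    def test_hr_recovery_under_true_hazard_ratio_two(self):
        # two exponential groups, hazard ratio 2, 20% censoring
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            t_low = rng.exponential(10, n)
            t_high = rng.exponential(5, n)
            c_low = rng.exponential(40, n)
            c_high = rng.exponential(20, n)
            res = logrank(np.minimum(t_low, c_low), (t_low <= c_low).astype(int),
                          np.minimum(t_high, c_high), (t_high <= c_high).astype(int))
            ok += 1.6 <= res.hr <= 2.5
        assert ok >= 9


class TestSurvivalByApa:
    def test_extreme_separation_small_p(self):
        # usage deterministically orders survival: low usage dies early
        ids = [f"s{i:02d}" for i in range(20)]
        usage = pd.Series(np.linspace(0.1, 0.9, 20), index=ids, name="G")
        clin = clinical_from(times=list(range(1, 21)), events=[1] * 20, ids=ids)
        res = survival_by_apa(usage, clin)
        assert res.p < 0.01
        assert res.n_low == res.n_high == 10

    def test_constant_usage_propagates_split_error(self):
        ids = list("abcd")
        usage = pd.Series([0.5] * 4, index=ids, name="G")
        clin = clinical_from([1, 2, 3, 4], [1, 1, 1, 1], ids=ids)
        with pytest.raises(APAError, match="constant|undefined"):
            survival_by_apa(usage, clin)

    def test_dropped_samples_recorded(self):
        ids = [f"s{i}" for i in range(8)]
        usage = pd.Series([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, np.nan],
                          index=ids, name="G")
        clin = clinical_from(list(range(1, 8)), [1] * 7, ids=ids[:7])
        res = survival_by_apa(usage, clin)
        assert "s7" in res.dropped_samples

    def test_coupled_survival_detects_strong_usage_effect(self):
        ids = [f"s{i:03d}" for i in range(120)]
        rng = np.random.default_rng(0)
        usage = pd.Series(rng.uniform(0.1, 0.9, 120), index=ids, name="G")
        surv = gen_coupled_survival(usage, hr=3.0, censor_rate=0.1, seed=1)
        clin = ClinicalTable(table=surv)
        res = survival_by_apa(usage, clin)
        assert res.p < 0.01
        assert res.hr > 1  # higher usage -> higher hazard by construction

    def test_tables_flatten(self):
        ids = [f"s{i:02d}" for i in range(20)]
        usage = pd.Series(np.linspace(0.1, 0.9, 20), index=ids, name="G")
        clin = clinical_from(list(range(1, 21)), [1] * 20, ids=ids)
        res = survival_by_apa(usage, clin)
        tab = survival_table([res])
        assert list(tab.columns) == ["feature_id", "n_low", "n_high",
                                     "events_low", "events_high", "median_low",
                                     "median_high", "chi_square", "p", "hr"]
        pts = km_points_table(res)
        assert set(pts["group"]) == {"low", "high"}
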