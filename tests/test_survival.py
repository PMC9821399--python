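"""Kaplan-Meier, log-rank and Mantel-Haenszel hazard ratio."""

import itertools

import numpy as np
import pytest
from scipy import stats

from layerstrata import (LayerSpec, SurvivalLinkSpec, as_records,
                         generate_dataset, hazard_ratio, km_estimate,
                         logrank_test)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate(as_records([5, 10, 15], [1, 0, 1]))
        assert km.times.tolist() == [5.0, 15.0]
        assert km.survival == pytest.approx([2 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        km = km_estimate(as_records([3, 6, 9], [0, 0, 0]))
        assert len(km.times) == 0
        assert km.at(100) == 1.0

    def test_single_event_steps_to_zero(self):
        km = km_estimate(as_records([4], [1]))
        assert km.at(3.9) == 1.0 and km.at(4) == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=50)
        km = km_estimate(as_records(times, np.ones(50, dtype=int)))
        for t in np.quantile(times, [0.25, 0.5, 0.75]):
            assert km.at(t) == pytest.approx((times > t).mean())

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = rng.exponential(10, size=60)
        events = rng.integers(0, 2, size=60)
        events[0] = 1
        km = km_estimate(as_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(as_records([-1], [1]))


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        g = as_records([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test([g, g.copy()])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_two_group_table(self):
        """A events at {1,2}, B at {3,4}: O=2, E=5/6, V=17/36, chi2=49/17."""
        a = as_records([1, 2], [1, 1])
        b = as_records([3, 4], [1, 1])
        res = logrank_test([a, b])
        assert res.observed[0] == 2
        assert res.expected[0] == pytest.approx(5 / 6)
        assert res.variance[0, 0] == pytest.approx(17 / 36)
        assert res.chi2 == pytest.approx(49 / 17)
        assert res.expected.sum() == pytest.approx(res.observed.sum())

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test
        times = rng.exponential(5, size=90)
        events = rng.integers(0, 2, size=90)
        events[:3] = 1
        groups = rng.integers(0, 3, size=90)
        parts = [as_records(times[groups == g], events[groups == g])
                 for g in range(3)]
        res = logrank_test(parts)
        ll = multivariate_logrank_test(times, groups, events)
        assert res.chi2 == pytest.approx(ll.test_statistic, rel=1e-9)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([as_records([1, 2], [0, 0]), as_records([3], [0])])

    def test_chi2_p_agrees_with_exhaustive_permutation(self, rng):
        """On tiny cohorts the chi-square and relabeling p agree in rejection."""
        agree = 0
        trials = 40
        for _ in range(trials):
            times = rng.exponential(5, size=8).round(2)
            events = np.ones(8, dtype=int)
            labels = np.array([0] * 4 + [1] * 4)
            obs = logrank_test([as_records(times[labels == g], events[labels == g])
                                for g in (0, 1)]).chi2
            null = []
            for combo in itertools.combinations(range(8), 4):
                lab = np.ones(8, dtype=int)
                lab[list(combo)] = 0
                null.append(logrank_test(
                    [as_records(times[lab == g], events[lab == g])
                     for g in (0, 1)]).chi2)
            perm_p = np.mean([c >= obs - 1e-12 for c in null])
            chi_p = stats.chi2.sf(obs, 1)
            agree += (perm_p < 0.05) == (chi_p < 0.05)
        assert agree / trials >= 0.95


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        g = as_records([1, 2, 3], [1, 1, 1])
        assert hazard_ratio(g, g.copy()).hr == pytest.approx(1.0)

    def test_inversion_symmetry(self, rng):
        a = as_records(rng.exponential(5, 20), rng.integers(0, 2, 20) | 1)
        b = as_records(rng.exponential(10, 20), rng.integers(0, 2, 20) | 1)
        assert hazard_ratio(a, b).hr * hazard_ratio(b, a).hr == pytest.approx(
            1.0, abs=1e-12)

    def test_zero_expected_events_reported_unbounded(self):
        a = as_records([1, 2], [1, 1])
        b = as_records([0.1, 0.2], [0, 0])   # leaves risk set before any event
        res = hazard_ratio(a, b)
        assert res.unbounded

    def test_simulated_design_recovered(self):
        """True HR 4 with clinical-style censoring: estimate in [3, 5.3]."""
        vals = []
        for seed in range(5):
            ds = generate_dataset(
                [LayerSpec("L", 5, 2, (0.5, 0.5), 0.0, 1.0)], 800, 0,
                survival=SurvivalLinkSpec("L", 0.05, (1.0, 4.0), 8.0),
                seed=300 + seed)
            sv = ds.survival
            g1 = sv[sv["group"] == 1][["time", "event"]]
            g0 = sv[sv["group"] == 0][["time", "event"]]
            vals.append(hazard_ratio(g1, g0).hr)
        assert 3.0 <= np.median(vals) <= 5.3

    def test_ci_brackets_estimate(self, rng):
        a = as_records(rng.exponential(2, 50), np.ones(50, dtype=int))
        b = as_records(rng.exponential(6, 50), np.ones(50, dtype=int))
        res = hazard_ratio(a, b)
        assert res.ci_low < res.hr < res.ci_high
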