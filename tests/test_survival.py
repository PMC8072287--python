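import numpy as np
import pytest

from cytoratio.models import auc
from cytoratio.survival import (
    dichotomize,
    hazard_ratio,
    km_estimate,
    logrank_test,
    roc_curve,
    stratified_survival,
    subgroup_run,
)


class TestRoc:
    def test_separable_case(self):
        roc = roc_curve([2.0, 3.0, 0.0, 1.0], [1, 1, 0, 0])
        assert roc.youden_optimal == pytest.approx(1.5)
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.auc == pytest.approx(1.0)

    def test_auc_equals_rank_definition(self, rng):
        for _ in range(30):
            n = rng.integers(6, 60)
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_random_scores_give_small_j(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_curve(scores, labels).youden_j < 0.1

    def test_degenerate_all_tied_scores(self):
        with pytest.warns(UserWarning, match="identical"):
            roc = roc_curve([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert roc.youden_j == pytest.approx(0.0)
        assert roc.youden_optimal == -np.inf

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_sentinel_thresholds_and_monotonicity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = 0, 1
        roc = roc_curve(scores, labels)
        assert roc.thresholds[0] == -np.inf and roc.thresholds[-1] == np.inf
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()


class TestDichotomize:
    def test_strict_cutoff(self):
        high, counts = dichotomize([1.8, 1.753, 1.7], 1.753)
        assert list(high) == [True, False, False]
        assert counts == {"high": 1, "low": 2}

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning, match="empty group"):
            dichotomize([0.1, 0.2], 5.0)

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            dichotomize([1.0], np.inf)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set(self):
        # censor at 1, deaths at 2 and 3: risk sets 2 then 1
        km = km_estimate([1.0, 2.0, 3.0], [0, 1, 1])
        np.testing.assert_allclose(km.times, [2.0, 3.0])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_all_censored_flat_curve(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate([5.0, 6.0], [0, 0])
        assert km.at(100.0) == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(100, size=80)
        events = rng.integers(0, 2, size=80)
        events[0] = 1
        km = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.survival, ref, atol=1e-10)

    def test_greenwood_variance_positive_and_bounded(self, rng):
        times = rng.exponential(50, size=60)
        km = km_estimate(times, np.ones(60, dtype=int))
        inner = km.variance[:-1]  # variance collapses with the curve at 0
        assert (inner >= 0).all()
        assert (np.sqrt(inner) < 1.0).all()

    def test_step_function_query(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.at(0.5) == 1.0
        assert km.at(1.0) == pytest.approx(2 / 3)
        assert km.at(2.5) == pytest.approx(1 / 3)


class TestLogrank:
    def test_identical_groups_no_signal(self):
        times = np.r_[1.0, 2, 3, 4, 1, 2, 3, 4]
        events = np.ones(8, dtype=int)
        groups = np.r_[np.zeros(4), np.ones(4)].astype(int)
        result = logrank_test(times, events, groups)
        assert result.chi2 == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_tabulated_oracle(self):
        # group A events at {1,2}, group B at {3,4}, no censoring:
        # summing (O-E) and hypergeometric V over the four event times gives
        # O-E = 7/6 and V = 17/36, hence chi2 = 49/17
        result = logrank_test([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 0, 1, 1])
        assert result.chi2 == pytest.approx(49 / 17, abs=1e-12)

    def test_group_swap_invariance(self, rng):
        times = rng.exponential(100, size=50)
        events = rng.integers(0, 2, size=50)
        events[0] = 1
        groups = rng.integers(0, 2, size=50)
        a = logrank_test(times, events, groups)
        b = logrank_test(times, events, 1 - groups)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        times = rng.exponential(100, size=100)
        events = rng.integers(0, 2, size=100)
        events[0] = 1
        groups = rng.integers(0, 2, size=100)
        ours = logrank_test(times, events, groups)
        ref = ll_logrank(times[groups == 0], times[groups == 1],
                         events[groups == 0], events[groups == 1])
        assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], [0, 1])


class TestHazardRatio:
    def test_identical_groups_hr_near_one(self, rng):
        times = rng.exponential(100, size=400)
        events = np.ones(400, dtype=int)
        groups = np.r_[np.zeros(200), np.ones(200)].astype(int)
        result = hazard_ratio(times, events, groups)
        assert 0.8 < result.hazard_ratio < 1.25
        assert result.ci_lower < 1.0 < result.ci_upper

    def test_all_events_in_one_group_unbounded(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 0]
        groups = [1, 1, 0, 0]
        with pytest.warns(UserWarning, match="unbounded"):
            result = hazard_ratio(times, events, groups)
        assert result.unbounded
        assert result.hazard_ratio in (0.0, np.inf)

    def test_rate_ratio_two_recovered(self):
        groups = np.r_[np.zeros(500), np.ones(500)].astype(int)
        estimates = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            times = np.r_[r.exponential(100, size=500), r.exponential(50, size=500)]
            estimates.append(
                hazard_ratio(times, np.ones(1000, dtype=int), groups).hazard_ratio)
        assert 1.7 <= float(np.median(estimates)) <= 2.3


class TestStrataAndSubgroups:
    def test_stratified_survival_structure(self, rng):
        times = rng.exponential(100, size=60)
        events = np.ones(60, dtype=int)
        high = rng.random(60) < 0.5
        high[:2] = [True, False]
        strata = stratified_survival(times, events, high, outcome="pfs")
        d = strata.to_dict()
        assert d["n_high"] + d["n_low"] == 60
        assert 0 <= d["logrank_p"] <= 1

    def test_identity_filter_matches_full_cohort(self, default_cohort, default_features):
        cohort, _ = default_cohort
        disc, _ = cohort.split()
        X = default_features.values.iloc[:disc.n_patients]
        scores = (X["IP-10@S2/S0"] - X["IL-8@S2/S0"]).to_numpy()
        cutoff = float(np.median(scores))
        full = subgroup_run(disc, scores, cutoff, {"cohort": "discovery"})
        assert full["n"] == disc.n_patients
        direct = stratified_survival(disc.df["pfs_days"], disc.df["pfs_event"],
                                     scores > cutoff, outcome="pfs")
        assert full["pfs"].logrank.chi2 == pytest.approx(direct.logrank.chi2)

    def test_histology_filter_subset_size(self, default_cohort, default_features):
        cohort, _ = default_cohort
        disc, _ = cohort.split()
        X = default_features.values.iloc[:disc.n_patients]
        scores = (X["IP-10@S2/S0"] - X["IL-8@S2/S0"]).to_numpy()
        n_sq = int((disc.df["histology"] == "squamous").sum())
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = subgroup_run(disc, scores, float(np.median(scores)),
                               {"histology": "squamous"})
        assert rep["n"] == n_sq

    def test_empty_filter_rejected(self, default_cohort, default_features):
        cohort, _ = default_cohort
        disc, _ = cohort.split()
        scores = np.zeros(disc.n_patients)
        with pytest.raises(ValueError, match="histology"):
            subgroup_run(disc, scores, 0.0, {"histology": "missing-type"})
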