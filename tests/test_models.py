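import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from cytoratio.models import (
    LogisticIRLS,
    PooledCovLDA,
    auc,
    cv_auc,
    fit_lda,
    fit_logistic,
    lda_apparent_error,
    stepwise_aic,
)


def pairwise_auc(scores, labels):
    """O(n^2) oracle: fraction of concordant positive-negative pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0]) == 1.0

    def test_half_concordant_pairs(self):
        # pos {0.9, 0.4}, neg {0.7, 0.6}: 2 of 4 pairs concordant
        assert auc([0.9, 0.4, 0.7, 0.6], [1, 1, 0, 0]) == 0.5

    def test_all_ties(self):
        assert auc([1.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(4, 50)
            scores = rng.integers(0, 10, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)

    def test_monotone_invariance_and_complement(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auc(scores, 1 - labels) == pytest.approx(1.0 - a, abs=1e-12)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(9), np.zeros(21)]
        model = fit_logistic(np.empty((30, 0)), y)
        assert model.intercept_ == pytest.approx(logit(0.3), abs=1e-8)

    def test_gradient_norm_at_optimum(self, rng):
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        model = fit_logistic(X, y)
        assert model.converged_
        assert model.gradient_norm_ <= 1e-6

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 1 / (1 + np.exp(-(0.5 + X[:, 0])))).astype(int)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.intercept_, ref.params[0], rtol=1e-5)
        np.testing.assert_allclose(ours.coef_, ref.params[1:], rtol=1e-5)
        np.testing.assert_allclose(
            ours.pvalues_, ref.pvalues[1:], rtol=1e-4, atol=1e-10)
        np.testing.assert_allclose(ours.loglik_, ref.llf, rtol=1e-8)

    def test_null_coefficient_within_sampling_band(self, rng):
        X = rng.normal(size=(400, 1))
        y = rng.integers(0, 2, size=400)
        model = fit_logistic(X, y)
        assert abs(model.coef_[0]) <= 3 * model.se_[0]

    def test_perfect_separation_flagged(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            model = fit_logistic(X, y)
        assert not model.converged_

    def test_ridge_stabilizes_separation(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_logistic(X, y, penalty="ridge", alpha=1.0)
        assert model.converged_
        assert np.isfinite(model.pvalues_).all()

    def test_aic_definition(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, size=60)
        m = fit_logistic(X, y)
        assert m.aic_ == pytest.approx(2 * 3 - 2 * m.loglik_)


def exhaustive_min_aic(X, y):
    """All-subsets oracle for the stepwise search."""
    best = np.inf
    cols = list(X.columns)
    for r in range(len(cols) + 1):
        for subset in itertools.combinations(cols, r):
            m = fit_logistic(X[list(subset)], y)
            best = min(best, m.aic_)
    return best


class TestStepwise:
    @pytest.fixture
    def planted(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        eta = 2.0 * X["f0"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y

    def test_informative_feature_selected_first(self, planted):
        X, y = planted
        result = stepwise_aic(X, y)
        assert result.selected[0] == "f0"

    def test_accepted_steps_strictly_decrease_aic(self, planted):
        X, y = planted
        result = stepwise_aic(X, y)
        assert all(b < a for a, b in zip(result.aic_trace, result.aic_trace[1:]))

    def test_greedy_bounded_by_exhaustive_optimum(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(60, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = rng.integers(0, 2, size=60)
            result = stepwise_aic(X, y)
            assert result.aic_trace[-1] >= exhaustive_min_aic(X, y) - 1e-9

    def test_max_features_zero_is_intercept_only(self, planted):
        X, y = planted
        result = stepwise_aic(X, y, max_features=0)
        assert result.selected == []
        assert len(result.aic_trace) == 1

    def test_both_direction_can_drop(self, planted):
        X, y = planted
        result = stepwise_aic(X, y, direction="both")
        assert result.selected  # still finds the informative feature
        assert "f0" in result.selected


class TestLDA:
    def test_separated_1d_classes(self, rng):
        X = np.r_[rng.normal(0, 1, 200), rng.normal(10, 1, 200)][:, None]
        y = np.r_[np.zeros(200), np.ones(200)].astype(int)
        model = fit_lda(X, y)
        boundary = model.threshold_ / model.coef_[0]
        assert boundary == pytest.approx(5.0, abs=0.5)
        assert lda_apparent_error(model, X, y) <= 0.01

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(120, 4))
        X[:60] += 1.0
        y = np.r_[np.ones(60), np.zeros(60)].astype(int)
        ours = fit_lda(X, y)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        assert (ours.predict(X) == ref.predict(X)).mean() == 1.0

    def test_single_point_per_class(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1])
        with pytest.warns(UserWarning, match="singular"):
            model = fit_lda(X, y)
        assert lda_apparent_error(model, X, y) == 0.0

    def test_fitted_structure(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        model = fit_lda(X, y)
        assert model.priors_.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(model.pooled_covariance_,
                                   model.pooled_covariance_.T, atol=1e-12)

    def test_identical_distributions_error_near_minority_rate(self, rng):
        X = rng.normal(size=(400, 2))
        y = np.r_[np.ones(120), np.zeros(280)].astype(int)
        model = fit_lda(X, y)
        err = lda_apparent_error(model, X, y)
        # Bayes rate for identical classes is min(prior); resubstitution
        # on noise stays in its neighborhood and never below zero
        assert 0.0 <= err <= 0.45


class TestCvAuc:
    def test_separable_feature_gives_unit_auc(self, rng):
        X = pd.DataFrame({"x": np.r_[rng.normal(5, 0.1, 30), rng.normal(-5, 0.1, 30)]})
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        result = cv_auc(X, y, seed=0)
        assert result.mean_auc == 1.0

    def test_seed_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)))
        y = rng.integers(0, 2, size=60)
        y[:5] = 1, 0, 1, 0, 1
        a = cv_auc(X, y, seed=7)
        b = cv_auc(X, y, seed=7)
        assert a.fold_aucs == b.fold_aucs
        c = cv_auc(X, y, seed=8)
        assert a.fold_aucs != c.fold_aucs

    def test_permuted_labels_center_at_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 2)))
        means = []
        for seed in range(20):
            y = np.random.default_rng(seed).permutation(
                np.r_[np.ones(40), np.zeros(40)]).astype(int)
            means.append(cv_auc(X, y, seed=seed).mean_auc)
        assert abs(np.mean(means) - 0.5) < 0.06

    def test_unstratified_small_class_skips_folds(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 1)))
        y = np.zeros(20, dtype=int)
        y[:2] = 1
        with pytest.warns(UserWarning, match="single class"):
            result = cv_auc(X, y, n_folds=5, stratified=False, seed=3)
        assert result.skipped_folds
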