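import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from lamina.estimators import (
    ProgressionClassifier,
    RandomInterceptTrend,
    StepwiseRegressor,
    UnivariateRegression,
)


class TestSklearnProtocol:
    @pytest.mark.parametrize("estimator", [
        ProgressionClassifier(), RandomInterceptTrend(),
        UnivariateRegression(), StepwiseRegressor(),
    ])
    def test_get_set_params_and_clone(self, estimator):
        params = estimator.get_params()
        rebuilt = clone(estimator).set_params(**params)
        assert rebuilt.get_params() == params


class TestProgressionClassifier:
    def test_threshold_and_predictions(self):
        clf = ProgressionClassifier().fit()
        assert clf.threshold_ == pytest.approx(-0.9908)
        labels = clf.predict([[-2.8], [-0.6], [clf.threshold_]])
        assert list(labels) == ["progressive", "non-progressive",
                                "non-progressive"]

    def test_decision_function_sign(self):
        clf = ProgressionClassifier().fit()
        margin = clf.decision_function([-5.0, 0.0])
        assert margin[0] > 0 > margin[1]

    def test_custom_criterion(self):
        clf = ProgressionClassifier(aging_mean=-1.0, aging_sd=0.5, z=2.0).fit()
        assert clf.threshold_ == pytest.approx(-2.0)


class TestRandomInterceptTrend:
    def test_noise_free_identical_trajectories(self):
        t = np.tile([0.0, 0.5, 1.0, 1.5], 4)
        groups = np.repeat(list("abcd"), 4)
        y = 100.0 - 5.0 * t
        with pytest.warns(UserWarning, match="degenerate"):
            est = RandomInterceptTrend().fit(t, y, groups=groups)
        assert est.beta0_ == pytest.approx(100.0, abs=1e-9)
        assert est.beta1_ == pytest.approx(-5.0, abs=1e-9)
        assert est.random_intercept_sd_ == 0.0
        assert est.residual_sd_ == pytest.approx(0.0, abs=1e-9)

    def test_single_subject_equals_ols(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 2, 8)
        y = 40 - 3 * t + rng.normal(0, 1, 8)
        with pytest.warns(UserWarning, match="degenerate"):
            est = RandomInterceptTrend().fit(t, y, groups=np.zeros(8))
        slope, intercept = np.polyfit(t, y, 1)
        assert est.beta1_ == pytest.approx(slope)
        assert est.beta0_ == pytest.approx(intercept)

    def test_forced_pooled_fit_is_ols(self):
        rng = np.random.default_rng(1)
        t = np.tile([0.0, 0.5, 1.0], 10)
        groups = np.repeat(np.arange(10), 3)
        y = 50 - 4 * t + rng.normal(0, 2, 30) + np.repeat(
            rng.normal(0, 5, 10), 3)
        est = RandomInterceptTrend(random_intercept=False).fit(
            t, y, groups=groups)
        slope, intercept = np.polyfit(t, y, 1)
        assert est.beta1_ == pytest.approx(slope)
        assert est.beta0_ == pytest.approx(intercept)
        assert est.random_intercept_sd_ == 0.0

    def test_recovers_slope_with_random_intercepts(self):
        rng = np.random.default_rng(2)
        n_subj, times = 40, np.array([0.0, 0.25, 0.5, 1.0, 1.5])
        intercepts = rng.normal(400, 100, n_subj)
        t = np.tile(times, n_subj)
        groups = np.repeat(np.arange(n_subj), len(times))
        y = np.repeat(intercepts, len(times)) - 50 * t + rng.normal(0, 10, len(t))
        est = RandomInterceptTrend().fit(t, y, groups=groups)
        assert est.beta1_ == pytest.approx(-50, rel=0.1)
        assert est.beta1_ci_[0] < est.beta1_ < est.beta1_ci_[1]
        assert est.random_intercept_sd_ == pytest.approx(100, rel=0.35)
        assert est.n_subjects_ == n_subj
        # fixed-effects prediction
        assert est.predict([[0.0]])[0] == pytest.approx(est.beta0_)


class TestUnivariateRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        est = UnivariateRegression().fit(x, 2 * x)
        assert est.beta_ == pytest.approx(2.0)
        assert est.r_ == pytest.approx(1.0)
        assert est.beta_ci_[1] - est.beta_ci_[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        est = UnivariateRegression().fit([1, 2, 3], [1, 3, 2])
        assert est.beta_ == pytest.approx(0.5)
        assert est.r_ == pytest.approx(0.5)

    def test_r_squared_equals_pearson_squared(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        est = UnivariateRegression().fit(x, y)
        assert est.r_ ** 2 == pytest.approx(sps.pearsonr(x, y)[0] ** 2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            UnivariateRegression().fit([1.0, 1.0, 1.0], [1, 2, 3])
        with pytest.raises(ValueError, match="complete pairs"):
            UnivariateRegression().fit([1.0, 2.0], [1.0, 2.0])

    def test_ci_coverage_near_nominal(self):
        # ~95% slope-CI coverage over simulated Gaussian data
        rng = np.random.default_rng(4)
        n_sims, n, true_slope = 1000, 15, 1.5
        x = rng.normal(size=(n_sims, n))
        y = 2.0 + true_slope * x + rng.normal(size=(n_sims, n))
        covered = 0
        for i in range(n_sims):
            est = UnivariateRegression().fit(x[i], y[i])
            covered += est.beta_ci_[0] <= true_slope <= est.beta_ci_[1]
        assert 0.93 <= covered / n_sims <= 0.97


class TestStepwiseRegressor:
    def test_single_strong_candidate_is_in(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=29)
        y = 1.2 * x + rng.normal(0, 0.5, 29)
        est = StepwiseRegressor().fit(pd.DataFrame({"x": x}), y)
        status, p = est.status_["x"]
        assert status == "In" and p < 0.01
        assert est.selected_ == ["x"]

    def test_exact_duplicate_is_dropped(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=29)
        y = x + rng.normal(0, 0.3, 29)
        with pytest.warns(UserWarning, match="functionally dependent"):
            est = StepwiseRegressor().fit(
                pd.DataFrame({"a": x, "b": x.copy()}), y)
        assert est.selected_ == ["a"]
        assert est.status_["b"][0] == "Out"

    def test_never_in_with_final_p_above_removal(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(29, 4)),
                             columns=list("abcd"))
            y = 0.8 * X["a"].to_numpy() + rng.normal(size=29)
            est = StepwiseRegressor().fit(X, y)
            for name in est.selected_:
                assert est.status_[name][1] <= est.p_remove + 1e-12

    def test_selection_consistency_simulation(self):
        a_in = b_out = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            A, B = rng.normal(size=29), rng.normal(size=29)
            y = A + rng.normal(0, 0.5, 29)
            est = StepwiseRegressor().fit(pd.DataFrame({"A": A, "B": B}), y)
            a_in += est.status_.get("A", ("", 0))[0] == "In"
            b_out += est.status_.get("B", ("Out", 0))[0] == "Out" or \
                "B" not in est.status_
        assert a_in >= 95
        assert b_out >= 85

    def test_predict_uses_selected_model(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 3.0 + 2.0 * x + rng.normal(0, 0.1, 40)
        frame = pd.DataFrame({"x": x, "noise": rng.normal(size=40)})
        est = StepwiseRegressor().fit(frame, y)
        pred = est.predict(frame)
        assert np.corrcoef(pred, y)[0, 1] > 0.99
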