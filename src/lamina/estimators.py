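"""Scikit-learn-style estimators for the cohort-level statistical models.

Four estimators cover the inferential core of the analysis:

* :class:`ProgressionClassifier` — the aging-adjusted RNFL progression rule
  as a classifier over annualized global-RNFL rates.
* :class:`RandomInterceptTrend` — the random-intercept linear mixed-effects
  trend ``y_ij = (beta0 + b0_i) + beta1 * t_ij + eps_ij`` fitted by REML.
* :class:`UnivariateRegression` — simple least-squares regression with the
  Pearson correlation and a t-based 95% slope CI.
* :class:`StepwiseRegressor` — bidirectional stepwise multiple regression
  with a univariate pre-screen, reporting an In/Out status per candidate.

All follow the fit/predict + ``get_params``/``set_params`` protocol and
expose fitted attributes with a trailing underscore, so they compose with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ProgressionClassifier",
    "RandomInterceptTrend",
    "UnivariateRegression",
    "StepwiseRegressor",
]


def _column(X) -> np.ndarray:
    X = check_array(X, ensure_2d=False, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError(f"expected a single column, got shape {X.shape}")
        X = X[:, 0]
    return X


class ProgressionClassifier(ClassifierMixin, BaseEstimator):
    """Aging-adjusted structural progression rule for RNFL thinning rates.

    An eye is *progressive* when its annualized global-RNFL rate is
    strictly below ``aging_mean - z * aging_sd``, i.e. it thins faster than
    the one-sided normal range of age-related loss. With the normative
    defaults (-0.54 +/- 0.23 um/year, z = 1.96) the threshold is
    -0.9908 um/year.

    ``fit`` only materializes the threshold (the rule has no free
    parameters to learn); it accepts and ignores training data so the
    estimator drops into sklearn pipelines.
    """

    _estimator_type = "classifier"

    def __init__(self, aging_mean: float = -0.54, aging_sd: float = 0.23,
                 z: float = 1.96):
        self.aging_mean = aging_mean
        self.aging_sd = aging_sd
        self.z = z

    def fit(self, X=None, y=None):
        if self.aging_sd < 0:
            raise ValueError("aging_sd must be >= 0")
        self.threshold_ = self.aging_mean - self.z * self.aging_sd
        self.classes_ = np.array(["non-progressive", "progressive"])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Margin below the threshold; positive values are progressive."""
        check_is_fitted(self, "threshold_")
        rates = _column(X)
        return self.threshold_ - rates

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        rates = _column(X)
        if not np.isfinite(rates).all():
            raise ValueError(
                "non-finite rate; use lamina.rates.classify_progression for "
                "missing-value handling"
            )
        return np.where(rates < self.threshold_, "progressive", "non-progressive")


class RandomInterceptTrend(RegressorMixin, BaseEstimator):
    """Random-intercept linear mixed-effects trend over time.

    Fits ``y_ij = (beta0 + b0_i) + beta1 * t_ij + eps_ij`` with subject
    random intercepts ``b0_i ~ N(0, sigma_b^2)`` by restricted maximum
    likelihood (statsmodels ``MixedLM``). Confidence intervals for the
    fixed effects use normal quantiles on the estimated covariance.

    Degenerate inputs are handled rather than rejected: a single subject,
    or data with (near-)zero residual variance, collapse to ordinary least
    squares with a zero variance component and a warning.

    Attributes
    ----------
    beta0_, beta1_ : fixed intercept and slope (units, units per year).
    beta0_ci_, beta1_ci_ : 95% confidence intervals (lo, hi).
    p_beta1_ : two-sided p-value of the slope.
    random_intercept_sd_, residual_sd_ : variance components.
    n_subjects_, n_observations_ : fitted sample sizes.
    """

    def __init__(self, alpha: float = 0.05, reml: bool = True,
                 random_intercept: bool = True):
        self.alpha = alpha
        self.reml = reml
        self.random_intercept = random_intercept

    def fit(self, X, y, groups=None):
        t = _column(X)
        y = np.asarray(y, dtype=float)
        if groups is None:
            raise ValueError("groups (subject identifiers) are required")
        groups = np.asarray(groups)
        if not (len(t) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        if len(y) < 2 or len(np.unique(t)) < 2:
            raise ValueError("need >= 2 observations at >= 2 time points")
        unique_groups = np.unique(groups)
        self.n_subjects_ = len(unique_groups)
        self.n_observations_ = len(y)

        design = np.column_stack([np.ones_like(t), t])
        beta_ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta_ols
        pooled_resid_var = float(resid @ resid) / max(len(y) - 2, 1)

        if (
            not self.random_intercept
            or self.n_subjects_ < 2
            or pooled_resid_var < 1e-12 * max(1.0, float(y.var()))
        ):
            self._fit_degenerate(t, y, design, beta_ols, resid,
                                 warn=self.random_intercept)
            return self

        import statsmodels.api as sm

        result = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, design, groups=groups)
            for method in ("lbfgs", "powell", "nm", "bfgs"):
                try:
                    result = model.fit(reml=self.reml, method=[method])
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if result.converged and np.isfinite(result.bse_fe).all():
                    break
        if result is None or not (
            np.isfinite(np.asarray(result.fe_params, dtype=float)).all()
            and np.isfinite(np.asarray(result.bse_fe, dtype=float)).all()
        ):
            # every optimizer failed outright; report the pooled OLS trend
            self._fit_degenerate(t, y, design, beta_ols, resid)
            return self
        params = np.asarray(result.fe_params, dtype=float)
        bse = np.asarray(result.bse_fe, dtype=float)
        zq = sps.norm.ppf(1 - self.alpha / 2)
        self.beta0_, self.beta1_ = float(params[0]), float(params[1])
        self.beta0_ci_ = (self.beta0_ - zq * bse[0], self.beta0_ + zq * bse[0])
        self.beta1_ci_ = (self.beta1_ - zq * bse[1], self.beta1_ + zq * bse[1])
        zstat = self.beta1_ / bse[1] if bse[1] > 0 else np.inf
        self.p_beta1_ = float(2 * sps.norm.sf(abs(zstat)))
        cov_re = float(np.asarray(result.cov_re).ravel()[0])
        self.random_intercept_sd_ = float(np.sqrt(max(cov_re, 0.0)))
        self.residual_sd_ = float(np.sqrt(max(result.scale, 0.0)))
        if self.random_intercept_sd_ == 0.0:
            warnings.warn(
                "singular fit: between-subject intercept variance is zero",
                stacklevel=2,
            )
        self.converged_ = bool(result.converged)
        return self

    def _fit_degenerate(self, t, y, design, beta_ols, resid, warn=True):
        """Pooled-OLS collapse: single subject, noise-free data, or an
        explicitly disabled random intercept."""
        if warn:
            warnings.warn(
                "degenerate mixed-model input; falling back to ordinary "
                "least squares with a zero random-intercept variance",
                stacklevel=3,
            )
        n = len(y)
        dof = max(n - 2, 1)
        sigma2 = float(resid @ resid) / dof
        sxx = float(((t - t.mean()) ** 2).sum())
        se_slope = np.sqrt(sigma2 / sxx) if sxx > 0 else np.inf
        se_inter = np.sqrt(sigma2 * (1.0 / n + t.mean() ** 2 / sxx)) if sxx > 0 else np.inf
        zq = sps.norm.ppf(1 - self.alpha / 2)
        self.beta0_, self.beta1_ = float(beta_ols[0]), float(beta_ols[1])
        self.beta0_ci_ = (self.beta0_ - zq * se_inter, self.beta0_ + zq * se_inter)
        self.beta1_ci_ = (self.beta1_ - zq * se_slope, self.beta1_ + zq * se_slope)
        if sigma2 == 0.0:
            self.p_beta1_ = 0.0 if self.beta1_ != 0 else 1.0
        else:
            zstat = self.beta1_ / se_slope
            self.p_beta1_ = float(2 * sps.norm.sf(abs(zstat)))
        self.random_intercept_sd_ = 0.0
        self.residual_sd_ = float(np.sqrt(sigma2))
        self.converged_ = True

    def predict(self, X) -> np.ndarray:
        """Population-level (fixed-effects) prediction at times ``X``."""
        check_is_fitted(self, "beta1_")
        t = _column(X)
        return self.beta0_ + self.beta1_ * t


class UnivariateRegression(RegressorMixin, BaseEstimator):
    """Simple linear regression with Pearson R and a t-based slope CI.

    The slope CI uses the t distribution with ``n - 2`` degrees of freedom;
    the two-sided p-value tests a zero slope (equivalently, zero
    correlation).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        x, y = x[mask], y[mask]
        n = len(x)
        if n < 3:
            raise ValueError(f"need >= 3 complete pairs, got {n}")
        if np.ptp(x) == 0:
            raise ValueError("predictor has zero variance")
        fit = sps.linregress(x, y)
        tq = sps.t.ppf(1 - self.alpha / 2, df=n - 2)
        self.n_ = n
        self.beta_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.r_ = float(fit.rvalue)
        self.p_value_ = float(fit.pvalue)
        self.stderr_ = float(fit.stderr)
        self.beta_ci_ = (self.beta_ - tq * self.stderr_, self.beta_ + tq * self.stderr_)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        return self.intercept_ + self.beta_ * _column(X)


class StepwiseRegressor(RegressorMixin, BaseEstimator):
    """Bidirectional stepwise multiple regression with In/Out reporting.

    Candidates are first screened univariately at ``screen_p`` (<= 0.10 by
    convention) and for functional dependence (a candidate that is an exact
    linear image of an earlier one — |r| above ``dependence_r`` — is
    dropped with a warning). Selection then alternates forward entry at
    ``p_enter`` and backward removal at ``p_remove`` until stable.

    After fitting, ``results_`` holds one row per screened candidate:
    predictors in the final model are labelled ``In`` with their
    final-model p-value; the rest are ``Out`` with the p-value they would
    attain if added to the final model (the conventional
    p-to-enter-at-last-step report).
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 screen_p: float = 0.10, dependence_r: float = 0.9999,
                 pre_screened: bool = False):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.screen_p = screen_p
        self.dependence_r = dependence_r
        self.pre_screened = pre_screened

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = check_array(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    @staticmethod
    def _ols_pvalues(Xc: np.ndarray, y: np.ndarray):
        """OLS coefficient p-values for a design with intercept prepended."""
        import statsmodels.api as sm

        design = sm.add_constant(Xc, has_constant="add")
        res = sm.OLS(y, design).fit()
        return res, np.asarray(res.pvalues[1:], dtype=float)

    def fit(self, X, y):
        frame = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(frame) != len(y):
            raise ValueError("X and y length mismatch")
        if frame.shape[1] < 1:
            raise ValueError("need at least one candidate predictor")
        mask = np.isfinite(y) & np.isfinite(frame.to_numpy()).all(axis=1)
        frame, y = frame.loc[mask], y[mask]

        # univariate screen
        self.univariate_ = {}
        candidates = []
        for name in frame.columns:
            uni = UnivariateRegression(alpha=self.p_enter)
            uni.fit(frame[name].to_numpy(), y)
            self.univariate_[name] = uni
            if self.pre_screened or uni.p_value_ <= self.screen_p:
                candidates.append(name)

        # functional-dependence / collinearity screen
        kept: list[str] = []
        self.dropped_dependent_ = []
        for name in candidates:
            dependent = False
            for prior in kept:
                r = np.corrcoef(frame[name], frame[prior])[0, 1]
                if abs(r) >= self.dependence_r:
                    warnings.warn(
                        f"candidate {name!r} is functionally dependent on "
                        f"{prior!r} (|r| = {abs(r):.6f}); dropped",
                        stacklevel=2,
                    )
                    self.dropped_dependent_.append(name)
                    dependent = True
                    break
            if not dependent:
                kept.append(name)
        candidates = kept

        selected: list[str] = []
        changed = True
        guard = 0
        while changed and guard < 100:
            changed = False
            guard += 1
            # forward entry
            best_name, best_p = None, np.inf
            for name in candidates:
                if name in selected:
                    continue
                _, pvals = self._ols_pvalues(
                    frame[selected + [name]].to_numpy(), y
                )
                if pvals[-1] < best_p:
                    best_name, best_p = name, pvals[-1]
            if best_name is not None and best_p <= self.p_enter:
                selected.append(best_name)
                changed = True
            # backward removal
            while selected:
                _, pvals = self._ols_pvalues(frame[selected].to_numpy(), y)
                worst = int(np.argmax(pvals))
                if pvals[worst] > self.p_remove:
                    selected.pop(worst)
                    changed = True
                else:
                    break

        self.selected_ = list(selected)
        self.feature_names_in_ = np.asarray(frame.columns)
        if selected:
            final, final_p = self._ols_pvalues(frame[selected].to_numpy(), y)
            self.final_model_ = final
            self.coef_ = np.asarray(final.params[1:], dtype=float)
            self.intercept_ = float(final.params[0])
            in_p = dict(zip(selected, final_p))
        else:
            self.final_model_ = None
            self.coef_ = np.zeros(0)
            ybar = float(y.mean())
            self.intercept_ = ybar
            in_p = {}

        status = {}
        for name in candidates:
            if name in selected:
                status[name] = ("In", float(in_p[name]))
            else:
                _, pvals = self._ols_pvalues(frame[selected + [name]].to_numpy(), y)
                status[name] = ("Out", float(pvals[-1]))
        for name in self.dropped_dependent_:
            status[name] = ("Out", np.nan)
        self.status_ = status
        self._selected_frame_columns = selected
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_")
        frame = self._as_frame(X)
        if not self.selected_:
            return np.full(len(frame), self.intercept_)
        Z = frame[self.selected_].to_numpy()
        return self.intercept_ + Z @ self.coef_
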