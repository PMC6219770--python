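"""Cohort-level inference: mixed-effects trends, rank tests, regression.

The rank tests are two-sided throughout. For small samples the null
distributions are computed *exactly* — including in the presence of ties,
via midranks — with a shift-convolution over integer doubled ranks
(signed-rank) or a count-and-sum dynamic program over group assignments
(rank-sum). Larger samples fall back to the tie-corrected normal
approximation. The two-sided p-value is the doubled smaller tail, capped
at 1.

The mixed-effects trend and the regression operations are thin wrappers
over the estimators in :mod:`lamina.estimators`, returning frozen result
records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import RandomInterceptTrend, StepwiseRegressor, UnivariateRegression
from .io import SubjectSeries, VISIT_LABELS

__all__ = [
    "LMEFit",
    "RegressionResult",
    "TestResult",
    "fit_lme",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "univariate_regression",
    "stepwise_multivariate",
    "visitwise_summary",
    "holm_adjust",
]

#: Largest sample sizes handled by the exact null distributions.
EXACT_SIGNED_RANK_N = 25
EXACT_RANK_SUM_N = 20


@dataclass(frozen=True)
class LMEFit:
    """Fixed effects of a random-intercept linear trend, with 95% CIs."""

    parameter: str
    beta0: float
    beta0_ci: tuple
    beta1: float
    beta1_ci: tuple
    p_beta1: float
    random_intercept_sd: float
    residual_sd: float
    n_subjects: int
    n_observations: int

    def __post_init__(self) -> None:
        if not (self.beta0_ci[0] <= self.beta0 <= self.beta0_ci[1]):
            raise ValueError("intercept CI does not bracket the estimate")
        if not (self.beta1_ci[0] <= self.beta1 <= self.beta1_ci[1]):
            raise ValueError("slope CI does not bracket the estimate")
        if self.n_observations < self.n_subjects:
            raise ValueError("n_observations < n_subjects")


@dataclass(frozen=True)
class RegressionResult:
    """One response-predictor association from the regression analyses."""

    response: str
    predictor: str
    beta: float
    beta_ci: tuple
    r: float
    p: float
    n: int
    stepwise_status: str | None = None  # "In" / "Out" / None (not screened in)
    stepwise_p: float | None = None

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|R| must be <= 1")
        if self.beta != 0 and self.r != 0 and math.copysign(1, self.beta) != math.copysign(1, self.r):
            raise ValueError("sign(R) must match sign(beta)")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test."""

    name: str
    statistic: float
    p_value: float
    n: int
    paired: bool
    method: str  # "exact" or "approx"
    n1: int | None = None
    n2: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# exact rank-test machinery


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks times two, as exact integers (midranks are halves)."""
    ranks = sps.rankdata(values)
    doubled = np.rint(2 * ranks).astype(np.int64)
    return doubled


def _two_sided_from_counts(c_le: int, c_ge: int, total: int) -> float:
    return min(1.0, 2.0 * min(c_le, c_ge) / total)


def _signed_rank_exact(diffs: np.ndarray) -> tuple:
    """Exact two-sided p for the signed-rank statistic, ties allowed.

    The null distribution of the doubled positive-rank sum is built by
    shift-convolution over the 2^n equiprobable sign assignments.
    """
    doubled = _doubled_midranks(np.abs(diffs))
    w2 = int(doubled[diffs > 0].sum())
    total_sum = int(doubled.sum())
    counts = np.zeros(total_sum + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    c_le = int(counts[: w2 + 1].sum())
    c_ge = int(counts[w2:].sum())
    total = 2 ** len(diffs)
    return w2 / 2.0, _two_sided_from_counts(c_le, c_ge, total)


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> tuple:
    """Exact two-sided p for the rank-sum statistic, ties allowed.

    Dynamic program over (group size, doubled rank sum): ``table[k][s]``
    counts subsets of size ``k`` of the pooled doubled midranks summing to
    ``s``; the row ``k = n1`` is the exact null distribution of group A's
    rank sum over all C(n, n1) equiprobable assignments.
    """
    pooled = np.concatenate([a, b])
    doubled = _doubled_midranks(pooled)
    n1, n = len(a), len(pooled)
    total_sum = int(doubled.sum())
    table = np.zeros((n1 + 1, total_sum + 1), dtype=object)
    table[0, 0] = 1
    for r in doubled:
        r = int(r)
        for k in range(n1, 0, -1):
            shifted = np.zeros(total_sum + 1, dtype=object)
            shifted[r:] = table[k - 1, : total_sum + 1 - r]
            table[k] = table[k] + shifted
    dist = table[n1]
    r2_obs = int(doubled[:n1].sum())
    c_le = int(dist[: r2_obs + 1].sum())
    c_ge = int(dist[r2_obs:].sum())
    total = math.comb(n, n1)
    u_obs = r2_obs / 2.0 - n1 * (n1 + 1) / 2.0
    return u_obs, _two_sided_from_counts(c_le, c_ge, total)


def wilcoxon_signed_rank(x: Sequence, y: Sequence | None = None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired data or differences.

    Zero differences are dropped (Wilcoxon's convention). The exact null
    distribution is used for up to 25 nonzero pairs, ties included; beyond
    that the tie-corrected normal approximation applies. All differences
    zero is reported as p = 1 with a warning, not an error.
    """
    x = np.asarray(x, dtype=float)
    diffs = x - np.asarray(y, dtype=float) if y is not None else x
    diffs = diffs[np.isfinite(diffs)]
    nonzero = diffs[diffs != 0]
    n = len(nonzero)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult("wilcoxon-signed-rank", 0.0, 1.0, 0, True, "exact")
    if n <= EXACT_SIGNED_RANK_N:
        stat, p = _signed_rank_exact(nonzero)
        method = "exact"
    else:
        res = sps.wilcoxon(nonzero, alternative="two-sided",
                           correction=False, method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
        method = "approx"
    return TestResult("wilcoxon-signed-rank", float(stat), float(p), n, True, method)


def mann_whitney(a: Sequence, b: Sequence) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test between two groups.

    Exact (enumeration-equivalent, ties included) for pooled sizes up to
    20; tie-corrected normal approximation with continuity correction
    otherwise. The statistic is U for the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    if n1 + n2 <= EXACT_RANK_SUM_N:
        stat, p = _rank_sum_exact(a, b)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        method = "approx"
    return TestResult("mann-whitney", float(stat), float(p), n1 + n2, False,
                      method, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# trends and regression


def fit_lme(observations, parameter: str = "value",
            reml: bool = True, random_intercept: bool = True) -> LMEFit:
    """Random-intercept linear trend over (subject, t_years, value) triplets.

    ``observations`` is an iterable of triplets or a DataFrame with columns
    ``subject``, ``t_years``, ``value``. Time must be in years so the slope
    is in units per year.
    """
    if isinstance(observations, pd.DataFrame):
        frame = observations[["subject", "t_years", "value"]]
    else:
        frame = pd.DataFrame(list(observations),
                             columns=["subject", "t_years", "value"])
    frame = frame.dropna()
    est = RandomInterceptTrend(reml=reml, random_intercept=random_intercept)
    est.fit(frame[["t_years"]].to_numpy(), frame["value"].to_numpy(),
            groups=frame["subject"].to_numpy())
    return LMEFit(
        parameter=parameter,
        beta0=est.beta0_,
        beta0_ci=est.beta0_ci_,
        beta1=est.beta1_,
        beta1_ci=est.beta1_ci_,
        p_beta1=est.p_beta1_,
        random_intercept_sd=est.random_intercept_sd_,
        residual_sd=est.residual_sd_,
        n_subjects=est.n_subjects_,
        n_observations=est.n_observations_,
    )


def univariate_regression(x: Sequence, y: Sequence,
                          response: str = "y",
                          predictor: str = "x") -> RegressionResult:
    """Least-squares slope with 95% t-based CI, Pearson R, two-sided p."""
    est = UnivariateRegression().fit(np.asarray(x, dtype=float),
                                     np.asarray(y, dtype=float))
    return RegressionResult(
        response=response,
        predictor=predictor,
        beta=est.beta_,
        beta_ci=est.beta_ci_,
        r=est.r_,
        p=est.p_value_,
        n=est.n_,
    )


def stepwise_multivariate(y: Sequence, candidates: pd.DataFrame,
                          response: str = "y",
                          p_enter: float = 0.05, p_remove: float = 0.10,
                          screen_p: float = 0.10,
                          pre_screened: bool = False) -> list:
    """Univariate screen + bidirectional stepwise selection.

    Returns one :class:`RegressionResult` per candidate column that passes
    the univariate screen (p <= ``screen_p``), carrying the univariate
    slope/CI/R/p alongside the stepwise ``In``/``Out`` status and the
    final-step p-value. Candidates failing the screen are returned with
    ``stepwise_status=None``. Functionally dependent candidates (exact
    linear images of an earlier candidate) are dropped from selection.
    """
    est = StepwiseRegressor(p_enter=p_enter, p_remove=p_remove,
                            screen_p=screen_p, pre_screened=pre_screened)
    est.fit(candidates, np.asarray(y, dtype=float))
    results = []
    for name in candidates.columns:
        uni = est.univariate_[name]
        status = est.status_.get(name)
        results.append(
            RegressionResult(
                response=response,
                predictor=str(name),
                beta=uni.beta_,
                beta_ci=uni.beta_ci_,
                r=uni.r_,
                p=uni.p_value_,
                n=uni.n_,
                stepwise_status=None if status is None else status[0],
                stepwise_p=None if status is None else status[1],
            )
        )
    return results


def holm_adjust(p_values: Sequence) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


# ---------------------------------------------------------------------------
# visit-wise cohort summary


def visitwise_summary(cohort: Iterable[SubjectSeries], parameter: str,
                      adjust: str = "none") -> pd.DataFrame:
    """Per-visit mean +/- SD with paired tests against baseline and the
    previous visit.

    Wilcoxon signed-rank tests are computed on the subjects measured at
    both visits of each comparison. ``adjust='holm'`` applies Holm
    correction across the reported p-values.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    values: dict[str, dict[str, float]] = {lbl: {} for lbl in VISIT_LABELS}
    t_mean: dict[str, list] = {lbl: [] for lbl in VISIT_LABELS}
    for series in cohort:
        for visit in series.visits:
            v = visit.value(parameter)
            if v is not None:
                values[visit.visit_label][series.subject_id] = v
                t_mean[visit.visit_label].append(visit.t_months)
    columns = ["visit", "t_months_mean", "n", "mean", "sd",
               "p_vs_base", "p_vs_prev"]
    rows = []
    labels = [lbl for lbl in VISIT_LABELS if values[lbl]]
    if not labels:
        return pd.DataFrame(columns=columns).set_index("visit")
    for i, lbl in enumerate(labels):
        sample = np.array(list(values[lbl].values()))
        row = {
            "visit": lbl,
            "t_months_mean": float(np.mean(t_mean[lbl])),
            "n": len(sample),
            "mean": float(sample.mean()),
            "sd": float(sample.std(ddof=1)) if len(sample) > 1 else math.nan,
            "p_vs_base": math.nan,
            "p_vs_prev": math.nan,
        }
        for target, key in ((labels[0], "p_vs_base"),
                            (labels[i - 1] if i > 0 else None, "p_vs_prev")):
            if i == 0 or target is None:
                continue
            shared = sorted(set(values[lbl]) & set(values[target]))
            if len(shared) >= 1:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    test = wilcoxon_signed_rank(
                        [values[lbl][s] for s in shared],
                        [values[target][s] for s in shared],
                    )
                row[key] = test.p_value
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("visit")
    if adjust == "holm":
        for col in ("p_vs_base", "p_vs_prev"):
            mask = frame[col].notna()
            if mask.any():
                frame.loc[mask, col] = holm_adjust(frame.loc[mask, col].to_numpy())
    elif adjust != "none":
        raise ValueError(f"unknown adjust {adjust!r}")
    return frame
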