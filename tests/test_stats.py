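import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from lamina.simulate import CohortGeneratorConfig, generate_cohort
from lamina.stats import (
    LMEFit,
    fit_lme,
    holm_adjust,
    mann_whitney,
    stepwise_multivariate,
    univariate_regression,
    visitwise_summary,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the package's DP implementations)


def signed_rank_p_oracle(diffs: np.ndarray) -> float:
    """Brute force over all 2^n sign assignments, midranks for ties."""
    d = diffs[diffs != 0]
    ranks2 = np.rint(2 * rankdata(np.abs(d))).astype(int)
    n = len(d)
    w2_obs = int(ranks2[d > 0].sum())
    bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
    sums = bits @ ranks2
    c_le = int((sums <= w2_obs).sum())
    c_ge = int((sums >= w2_obs).sum())
    return min(1.0, 2.0 * min(c_le, c_ge) / 2 ** n)


def rank_sum_p_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Brute force over all C(n, n1) group assignments, midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)
    n1 = len(a)
    r_obs = int(ranks2[:n1].sum())
    c_le = c_ge = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = int(ranks2[list(combo)].sum())
        total += 1
        c_le += s <= r_obs
        c_ge += s >= r_obs
    return min(1.0, 2.0 * min(c_le, c_ge) / total)


class TestWilcoxonSignedRank:
    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0

    def test_six_one_sided_differences(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p_value == 2 / 64
        assert res.method == "exact"

    @pytest.mark.parametrize("n", [5, 8, 12, 15])
    @pytest.mark.parametrize("ties", [False, True])
    def test_agrees_with_enumeration_oracle(self, n, ties):
        rng = np.random.default_rng(100 * n + ties)
        for _ in range(5):
            if ties:
                d = rng.integers(-4, 5, n).astype(float)
                d = d[d != 0]
                if len(d) == 0:
                    continue
            else:
                d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            assert res.p_value == signed_rank_p_oracle(d)

    def test_large_sample_uses_approximation(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 1.0, 60)
        res = wilcoxon_signed_rank(d)
        assert res.method == "approx"
        assert 0 <= res.p_value <= 1


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5  # midpoint of the U range
        assert res.p_value == 1.0

    def test_fully_separated_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (8, 8)])
    @pytest.mark.parametrize("ties", [False, True])
    def test_agrees_with_enumeration_oracle(self, n1, n2, ties):
        rng = np.random.default_rng(10 * n1 + n2 + ties)
        for _ in range(5):
            if ties:
                a = rng.integers(0, 5, n1).astype(float)
                b = rng.integers(0, 5, n2).astype(float)
            else:
                a, b = rng.normal(size=n1), rng.normal(size=n2)
            res = mann_whitney(a, b)
            assert res.p_value == rank_sum_p_oracle(a, b)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFitLME:
    def test_triplet_and_dataframe_inputs_agree(self):
        rng = np.random.default_rng(1)
        triplets = [
            (f"s{i}", t, 100 + rng.normal() - 10 * t)
            for i in range(6) for t in (0.0, 0.5, 1.0)
        ]
        frame = pd.DataFrame(triplets, columns=["subject", "t_years", "value"])
        fit_a = fit_lme(triplets)
        fit_b = fit_lme(frame)
        assert fit_a.beta1 == pytest.approx(fit_b.beta1)

    def test_result_invariants(self):
        rng = np.random.default_rng(2)
        triplets = [
            (f"s{i}", t, 400 + rng.normal(0, 50) - 50 * t + rng.normal(0, 10))
            for i in range(10) for t in (0.0, 0.25, 0.5, 1.0)
        ]
        fit = fit_lme(triplets, parameter="LCD")
        assert fit.beta1_ci[0] <= fit.beta1 <= fit.beta1_ci[1]
        assert fit.n_observations >= fit.n_subjects == 10
        assert fit.random_intercept_sd >= 0

    def test_invalid_result_construction_rejected(self):
        with pytest.raises(ValueError):
            LMEFit("x", 0.0, (1.0, 2.0), 0.0, (-1.0, 1.0), 0.5, 0.0, 1.0, 2, 4)


class TestRegressionWrappers:
    def test_univariate_result_fields(self):
        res = univariate_regression([1, 2, 3], [1, 3, 2],
                                    response="RNFL", predictor="LCD")
        assert (res.beta, res.r) == (pytest.approx(0.5), pytest.approx(0.5))
        assert res.response == "RNFL" and res.predictor == "LCD"
        assert np.sign(res.beta) == np.sign(res.r)

    def test_stepwise_labels_every_screened_candidate(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=29)
        B = rng.normal(size=29)
        y = A + rng.normal(0, 0.4, 29)
        results = stepwise_multivariate(
            y, pd.DataFrame({"A": A, "B": B}), response="y")
        by_name = {r.predictor: r for r in results}
        assert by_name["A"].stepwise_status == "In"
        assert by_name["B"].stepwise_status in ("Out", None)

    def test_holm_adjustment_is_monotone_and_conservative(self):
        raw = np.array([0.001, 0.01, 0.04, 0.2])
        adj = holm_adjust(raw)
        assert (adj >= raw - 1e-15).all()
        assert (np.diff(adj) >= -1e-15).all()


class TestVisitwiseSummary:
    def test_constant_cohort(self):
        from lamina.io import SectorProfile, SubjectSeries, VisitRecord

        months = {"base": 0.0, "1pv": 1.0, "3pv": 3.0, "6pv": 6.0, "FUpv": 15.0}
        cohort = [
            SubjectSeries(f"s{i}", tuple(
                VisitRecord(f"s{i}", lbl, t, rnfl=SectorProfile(G=60.0))
                for lbl, t in months.items()))
            for i in range(6)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = visitwise_summary(cohort, "RNFL.G")
        assert (table["mean"] == 60.0).all()
        assert (table["p_vs_base"].dropna() == 1.0).all()
        assert (table["p_vs_prev"].dropna() == 1.0).all()

    def test_transient_swelling_recovered_at_large_n(self):
        config = CohortGeneratorConfig(n_subjects=500)
        cohort, _ = generate_cohort(config, seed=21)
        table = visitwise_summary(cohort, "RNFL.G")
        swelling = table.loc["1pv", "mean"] - table.loc["base", "mean"]
        assert swelling == pytest.approx(5.6, abs=0.5)
        assert table.loc["1pv", "p_vs_base"] < 0.001

    def test_summary_shape(self, default_cohort):
        cohort, _ = default_cohort
        table = visitwise_summary(cohort, "LCD")
        assert list(table.index) == ["base", "1pv", "3pv", "6pv", "FUpv"]
        assert np.isnan(table.loc["base", "p_vs_base"])
        assert table["n"].eq(29).all()
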