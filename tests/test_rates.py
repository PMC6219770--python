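import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamina.io import SectorProfile, SubjectSeries, VisitRecord
from lamina.rates import (
    ProgressionCriterion,
    classify_progression,
    cohort_rate_table,
    group_split,
    monthly_change,
    progression_threshold,
    rate,
)


def _series(sid, values, fu_months=20.0, parameter="rnfl", **base_kw):
    """Series with global-RNFL or LCD values at base/1pv/3pv/6pv/FUpv."""
    months = {"base": 0.0, "1pv": 1.0, "3pv": 3.0, "6pv": 6.0, "FUpv": fu_months}
    visits = []
    for lbl, value in values.items():
        kw = dict(subject_id=sid, visit_label=lbl, t_months=months[lbl], **base_kw)
        if parameter == "rnfl":
            kw["rnfl"] = SectorProfile(G=value)
        else:
            kw["lcd"] = value
        visits.append(VisitRecord(**kw))
    return SubjectSeries(subject_id=sid, visits=tuple(visits))


class TestRateArithmetic:
    def test_worked_example_rates(self):
        assert rate(61, 47, 0, 20) == pytest.approx(-8.4, abs=1e-12)
        assert round(rate(86, 64, 0, 21), 1) == -12.6

    def test_no_change_is_zero(self):
        assert rate(50.0, 50.0, 0, 13) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0, 100, 2)
            t0, t1 = sorted(rng.uniform(0, 30, 2))
            if t1 - t0 < 1e-6:
                continue
            assert rate(a, b, t0, t1) == pytest.approx(-rate(b, a, t0, t1))

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(-1000, 1000),
        b=st.floats(-1000, 1000),
        t0=st.floats(0, 28),
        gap=st.floats(0.01, 29),
    )
    def test_rate_antisymmetry_and_scaling(self, a, b, t0, gap):
        forward = rate(a, b, t0, t0 + gap)
        assert forward == pytest.approx(-rate(b, a, t0, t0 + gap), abs=1e-9)
        # rate over a doubled gap is half the rate over the original gap
        assert rate(a, b, t0, t0 + 2 * gap) == pytest.approx(
            forward / 2, rel=1e-9, abs=1e-12)

    def test_nonpositive_gap_is_an_error(self):
        with pytest.raises(ValueError):
            rate(1.0, 2.0, 6.0, 6.0)
        with pytest.raises(ValueError):
            rate(1.0, 2.0, 6.0, 3.0)

    def test_missing_value_yields_marker_not_zero(self):
        assert rate(None, 2.0, 0, 6) is None
        assert rate(1.0, math.nan, 0, 6) is None

    def test_monthly_change(self):
        assert abs(monthly_change(-187.4)) == pytest.approx(15.6167, abs=1e-4)
        assert abs(monthly_change(-748.6)) == pytest.approx(62.3833, abs=1e-4)
        assert monthly_change(0.0) == 0.0

    def test_baseline_rate_telescopes_consecutive_rates(self):
        # baseline-anchored rate at v = time-weighted mean of consecutive rates
        rng = np.random.default_rng(3)
        times = [0.0, 1.0, 3.0, 6.0, 19.0]
        values = rng.uniform(30, 90, len(times))
        target = rate(values[0], values[-1], times[0], times[-1])
        weighted = sum(
            rate(values[i], values[i + 1], times[i], times[i + 1])
            * (times[i + 1] - times[i])
            for i in range(len(times) - 1)
        ) / (times[-1] - times[0])
        assert weighted == pytest.approx(target, rel=1e-12)


class TestProgressionRule:
    def test_threshold_defaults(self):
        assert progression_threshold() == pytest.approx(-0.9908, abs=1e-12)

    def test_threshold_collapses_without_z_or_sd(self):
        assert progression_threshold(ProgressionCriterion(z=0.0)) == -0.54
        assert progression_threshold(ProgressionCriterion(aging_sd=0.0)) == -0.54

    def test_threshold_below_mean(self):
        crit = ProgressionCriterion()
        assert crit.threshold < crit.aging_mean

    def test_classification_examples(self):
        assert classify_progression(-2.8) == "progressive"
        assert classify_progression(-0.6) == "non-progressive"
        # strict inequality: the boundary itself is non-progressive
        assert classify_progression(ProgressionCriterion().threshold) == \
            "non-progressive"
        assert classify_progression(None) is None
        assert classify_progression(math.nan) is None

    def test_classification_is_monotone(self):
        rng = np.random.default_rng(1)
        rates = np.sort(rng.uniform(-15, 10, 200))
        labels = [classify_progression(r) for r in rates]
        flips = [i for i in range(1, 200) if labels[i] != labels[i - 1]]
        assert len(flips) <= 1  # a single progressive -> non-progressive switch
        assert labels[0] == "progressive" and labels[-1] == "non-progressive"


class TestCohortRates:
    def test_constant_slope_noise_free(self):
        cohort = []
        slope = -3.0  # per year
        for i in range(5):
            values = {lbl: 60.0 + slope * t / 12.0 for lbl, t in
                      (("base", 0), ("1pv", 1), ("3pv", 3), ("6pv", 6),
                       ("FUpv", 18))}
            cohort.append(_series(f"s{i}", values, fu_months=18.0))
        records, summary = cohort_rate_table(cohort, "RNFL.G", anchor="baseline")
        assert all(r.rate == pytest.approx(slope, rel=1e-12) for r in records)
        assert summary["mean"].to_numpy() == pytest.approx([slope] * 4)

    def test_two_subject_summary(self):
        a = _series("a", {"base": 60.0, "FUpv": 60.0 - 4 * 20 / 12}, 20.0)
        b = _series("b", {"base": 60.0, "FUpv": 60.0 - 2 * 20 / 12}, 20.0)
        _, summary = cohort_rate_table([a, b], "RNFL.G", anchor="baseline")
        row = summary.iloc[0]
        assert row["mean"] == pytest.approx(-3.0)
        assert row["sd"] == pytest.approx(math.sqrt(2))
        assert (row["min"], row["max"]) == (pytest.approx(-4.0), pytest.approx(-2.0))

    def test_printed_case_lcd_rates(self):
        lcd = _series("case_a", {"base": 641.0, "6pv": 522.0, "FUpv": 388.0},
                      20.0, parameter="lcd")
        records, _ = cohort_rate_table([lcd], "LCD", anchor="baseline")
        by_visit = {r.to_visit: r.rate for r in records}
        assert by_visit["6pv"] == pytest.approx(-238.0, abs=1e-9)
        records, _ = cohort_rate_table([lcd], "LCD", anchor="fu-vs-6m")
        assert records[0].rate == pytest.approx((388 - 522) / (14 / 12), abs=1e-9)

    def test_missing_endpoint_excluded_not_imputed(self):
        a = _series("a", {"base": 60.0, "FUpv": 50.0}, 20.0)
        b = _series("b", {"base": 60.0}, 20.0)
        records, summary = cohort_rate_table([a, b], "RNFL.G", anchor="baseline")
        assert {r.subject_id for r in records} == {"a"}
        assert summary.iloc[0]["n"] == 1


class TestGroupSplit:
    def _cohort(self, n_prog=21, n_non=8):
        cohort = []
        for i in range(n_prog):
            drop = 3.0 * 20 / 12
            cohort.append(_series(
                f"p{i}", {"base": 60.0, "FUpv": 60.0 - drop}, 20.0,
                surgery="trabeculectomy", age=65.0))
        for i in range(n_non):
            gain = 1.0 * 20 / 12
            cohort.append(_series(
                f"n{i}", {"base": 50.0, "FUpv": 50.0 + gain}, 20.0,
                surgery="NPDS", age=66.0))
        return cohort

    def test_constructed_21_8_split(self):
        split = group_split(self._cohort())
        assert split.sizes == (21, 8)
        summary = split.baseline_summary
        assert summary.loc["progressive", "rnfl_G_um_mean"] == pytest.approx(60.0)
        assert summary.loc["non-progressive", "n_NPDS"] == 8

    def test_all_above_threshold(self):
        split = group_split(self._cohort(n_prog=0, n_non=5))
        assert split.sizes == (0, 5)

    def test_partition_sizes_sum_to_classifiable(self):
        cohort = self._cohort(n_prog=3, n_non=2)
        cohort.append(_series("lost", {"base": 55.0}, 20.0))  # no follow-up
        split = group_split(cohort)
        assert sum(split.sizes) == 5
        assert len(split.unclassified) == 1
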