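"""Per-subject annualized rates of change and RNFL progression grouping.

Rates are the ratio of the parameter difference between two visits to the
elapsed time in years (1 month = 1/12 year exactly, matching the convention
used for first-month reductions such as 187.4/12 mmHg). Global-RNFL rates
are compared against an aging-adjusted threshold, ``aging_mean - z *
aging_sd`` with normative aging thinning -0.54 +/- 0.23 um/year and
z = 1.96: eyes thinning strictly faster than the threshold are labelled
*progressive*, the rest (no change or improvement beyond normal aging)
*non-progressive*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SECTOR_CODES, SubjectSeries, VisitRecord

__all__ = [
    "PARAMETERS",
    "MONTHS_PER_YEAR",
    "RateRecord",
    "ProgressionCriterion",
    "GroupSplit",
    "rate",
    "monthly_change",
    "cohort_rate_table",
    "progression_threshold",
    "classify_progression",
    "group_split",
]

logger = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12.0

#: Parameters for which rates are defined.
PARAMETERS = ("IOP", "LCD") + tuple(f"RNFL.{c}" for c in SECTOR_CODES)

#: Named anchoring schemes for cohort rate tables.
ANCHORS = ("baseline", "consecutive", "fu-vs-6m")


@dataclass(frozen=True)
class RateRecord:
    """Annualized rate of change of one parameter over one visit pair."""

    subject_id: str
    parameter: str
    from_visit: str
    to_visit: str
    delta_t_years: float
    rate: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not self.delta_t_years > 0:
            raise ValueError("delta_t_years must be > 0")


@dataclass(frozen=True)
class ProgressionCriterion:
    """Aging-adjusted RNFL progression rule.

    ``threshold = aging_mean - z * aging_sd``: the lower bound of the
    one-sided normal range of age-related thinning. Defaults encode the
    normative -0.54 +/- 0.23 um/year with a 1.96 multiplier, i.e. a
    threshold of -0.9908 um/year.
    """

    aging_mean: float = -0.54
    aging_sd: float = 0.23
    z: float = 1.96

    def __post_init__(self) -> None:
        if self.aging_sd < 0:
            raise ValueError("aging_sd must be >= 0")

    @property
    def threshold(self) -> float:
        return self.aging_mean - self.z * self.aging_sd


def rate(value_from, value_to, t_from_months: float, t_to_months: float):
    """Annualized rate ``(value_to - value_from) / ((t_to - t_from)/12)``.

    Returns ``None`` (a missing-rate marker, never zero) when either value
    is missing; raises for a non-positive time gap.
    """
    if not t_to_months > t_from_months:
        raise ValueError(
            f"time gap must be positive, got {t_from_months} -> {t_to_months} months"
        )
    if value_from is None or value_to is None:
        return None
    if isinstance(value_from, float) and math.isnan(value_from):
        return None
    if isinstance(value_to, float) and math.isnan(value_to):
        return None
    delta_t_years = (t_to_months - t_from_months) / MONTHS_PER_YEAR
    return (value_to - value_from) / delta_t_years


def monthly_change(annual_rate: float) -> float:
    """Convert an annualized rate into the change accrued in one month."""
    if not math.isfinite(annual_rate):
        raise ValueError("rate must be finite")
    return annual_rate / MONTHS_PER_YEAR


def _pair_rate(series: SubjectSeries, parameter: str,
               v_from: VisitRecord, v_to: VisitRecord):
    r = rate(v_from.value(parameter), v_to.value(parameter),
             v_from.t_months, v_to.t_months)
    if r is None:
        return None
    return RateRecord(
        subject_id=series.subject_id,
        parameter=parameter,
        from_visit=v_from.visit_label,
        to_visit=v_to.visit_label,
        delta_t_years=(v_to.t_months - v_from.t_months) / MONTHS_PER_YEAR,
        rate=r,
    )


def _visit_pairs(series: SubjectSeries, anchor: str):
    if anchor == "baseline":
        base = series.baseline
        if base is None:
            return
        for v in series.visits:
            if v.visit_label != "base":
                yield base, v
    elif anchor == "consecutive":
        for v0, v1 in zip(series.visits, series.visits[1:]):
            yield v0, v1
    elif anchor == "fu-vs-6m":
        v6, vfu = series.visit("6pv"), series.visit("FUpv")
        if v6 is not None and vfu is not None:
            yield v6, vfu
    else:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")


def cohort_rate_table(
    cohort: Iterable[SubjectSeries],
    parameter: str,
    anchor: str = "baseline",
):
    """Per-subject rate records plus a per-interval summary table.

    Returns ``(records, summary)`` where ``summary`` is a DataFrame indexed
    by the interval's target visit with columns ``n``, ``mean``, ``sd``,
    ``min``, ``max`` — the mean +/- SD (range) presentation used for
    published rate tables. Subjects missing either endpoint of an interval
    are excluded from that row (and logged), never imputed.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    records: list[RateRecord] = []
    for series in cohort:
        for v_from, v_to in _visit_pairs(series, anchor):
            rec = _pair_rate(series, parameter, v_from, v_to)
            if rec is None:
                logger.info(
                    "subject %s: missing %s at %s or %s; excluded",
                    series.subject_id, parameter,
                    v_from.visit_label, v_to.visit_label,
                )
                continue
            records.append(rec)
    rows = []
    keys = sorted({(r.from_visit, r.to_visit) for r in records},
                  key=lambda k: ("base", "1pv", "3pv", "6pv", "FUpv").index(k[1]))
    for key in keys:
        values = np.array([r.rate for r in records
                           if (r.from_visit, r.to_visit) == key])
        rows.append(
            {
                "from_visit": key[0],
                "to_visit": key[1],
                "n": len(values),
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                "min": float(values.min()),
                "max": float(values.max()),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["from_visit", "to_visit", "n", "mean", "sd", "min", "max"]
    )
    return records, summary


def progression_threshold(criterion: ProgressionCriterion | None = None) -> float:
    """Aging-adjusted progression threshold in um/year."""
    return (criterion or ProgressionCriterion()).threshold


def classify_progression(rate_value, criterion: ProgressionCriterion | None = None):
    """Label a global-RNFL rate as ``progressive`` or ``non-progressive``.

    Progression requires thinning *strictly faster* than the threshold
    (``rate < threshold``); the boundary value itself is non-progressive.
    Accepts a :class:`RateRecord` or a bare rate; a missing rate returns
    ``None`` (unclassified).
    """
    criterion = criterion or ProgressionCriterion()
    value = rate_value.rate if isinstance(rate_value, RateRecord) else rate_value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return "progressive" if value < criterion.threshold else "non-progressive"


@dataclass(frozen=True)
class GroupSplit:
    """Progressive / non-progressive partition with baseline summaries."""

    progressive: tuple
    non_progressive: tuple
    unclassified: tuple
    baseline_summary: pd.DataFrame = field(compare=False)

    @property
    def sizes(self) -> tuple:
        return len(self.progressive), len(self.non_progressive)


_BASELINE_FIELDS = {
    "age_years": lambda v: v.age,
    "lcd_um": lambda v: v.lcd,
    "rnfl_G_um": lambda v: v.rnfl.G,
    "iop_mmHg": lambda v: v.iop,
}


def group_split(
    cohort: Iterable[SubjectSeries],
    criterion: ProgressionCriterion | None = None,
    anchor: str = "baseline",
) -> GroupSplit:
    """Partition a cohort by aging-adjusted global-RNFL progression.

    The decision uses the baseline-to-final-follow-up global RNFL rate by
    default (``anchor='baseline'``); ``anchor='fu-vs-6m'`` performs the
    6-month-to-follow-up sensitivity variant. Subjects without a computable
    rate are kept apart as ``unclassified``.
    """
    criterion = criterion or ProgressionCriterion()
    prog, nonprog, unclass = [], [], []
    for series in cohort:
        if anchor == "baseline":
            v_from, v_to = series.baseline, series.visit("FUpv")
        elif anchor == "fu-vs-6m":
            v_from, v_to = series.visit("6pv"), series.visit("FUpv")
        else:
            raise ValueError(f"unsupported anchor {anchor!r} for group_split")
        rec = None
        if v_from is not None and v_to is not None:
            rec = _pair_rate(series, "RNFL.G", v_from, v_to)
        label = classify_progression(rec, criterion) if rec else None
        if label == "progressive":
            prog.append(series)
        elif label == "non-progressive":
            nonprog.append(series)
        else:
            unclass.append(series)
    rows = []
    for name, members in (("progressive", prog), ("non-progressive", nonprog)):
        row = {"group": name, "n": len(members)}
        baselines = [s.baseline for s in members if s.baseline is not None]
        for field_name, getter in _BASELINE_FIELDS.items():
            values = np.array([getter(v) for v in baselines
                               if getter(v) is not None], dtype=float)
            row[f"{field_name}_mean"] = float(values.mean()) if values.size else math.nan
            row[f"{field_name}_sd"] = (
                float(values.std(ddof=1)) if values.size > 1 else math.nan
            )
        surgeries = [v.surgery for v in baselines if v.surgery is not None]
        row["n_trabeculectomy"] = surgeries.count("trabeculectomy")
        row["n_NPDS"] = surgeries.count("NPDS")
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("group")
    return GroupSplit(
        progressive=tuple(prog),
        non_progressive=tuple(nonprog),
        unclassified=tuple(unclass),
        baseline_summary=summary,
    )
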