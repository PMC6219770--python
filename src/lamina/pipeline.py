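"""End-to-end orchestration: cohort -> rates -> classification -> statistics.

``run_pipeline`` reads (or simulates) a longitudinal cohort and emits a
report bundle of CSV tables plus a text summary:

* ``rates_rnfl.csv`` — per-location annualized RNFL thinning rates per
  anchoring interval (mean +/- SD, range), with the follow-up-vs-6-month
  paired comparison for the whole cohort and the progressive subgroup;
* ``rates_<param>.csv`` — the same summaries for LCD and IOP;
* ``classification.csv`` — per-subject global-RNFL rate and the
  aging-adjusted progressive / non-progressive label;
* ``visitwise_<param>.csv`` — per-visit mean +/- SD with paired tests
  against baseline and the previous visit;
* ``lme.csv`` — random-intercept trend fits (intercept, slope, CIs) for
  IOP, LCD and global RNFL;
* ``regression.csv`` — univariate screen + stepwise multivariate status
  for the factors associated with RNFL thickness and its rate of change;
* ``summary.txt`` — the headline numbers, presentation-rounded.

Every table is stamped with the seed and a configuration hash, so a bundle
is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rates as rates_mod
from . import stats as stats_mod
from .io import SECTOR_CODES, cohort_to_frame, ingest_supplementary, read_cohort
from .rates import ProgressionCriterion, classify_progression, group_split
from .simulate import CohortGeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "rnfl_rate_table", "association_analysis"]

_SECTOR_NAMES = {
    "G": "Average", "TS": "Temporal Superior", "T": "Temporal",
    "TI": "Temporal Inferior", "NS": "Nasal Superior", "N": "Nasal",
    "NI": "Nasal Inferior",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and output location of a full pipeline run."""

    cohort_csv: str | None = None
    supplementary_xlsx: str | None = None
    column_mapping: str | None = None
    out_dir: str = "lamina_report"
    seed: int = 0
    simulate_if_missing: bool = True
    aging_mean: float = -0.54
    aging_sd: float = 0.23
    z: float = 1.96
    p_enter: float = 0.05
    p_remove: float = 0.10
    screen_p: float = 0.10

    @property
    def criterion(self) -> ProgressionCriterion:
        return ProgressionCriterion(self.aging_mean, self.aging_sd, self.z)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        location does not change what is computed)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class PipelineResult:
    """Handles to everything a pipeline run produced."""

    config: PipelineConfig
    cohort: tuple
    tables: dict = field(compare=False)
    files: dict = field(compare=False)


def _subject_rates(cohort, parameter: str) -> pd.DataFrame:
    """Baseline-anchored rate of ``parameter`` per subject x target visit."""
    records, _ = rates_mod.cohort_rate_table(cohort, parameter, anchor="baseline")
    frame = pd.DataFrame(
        [{"subject_id": r.subject_id, "to_visit": r.to_visit, "rate": r.rate}
         for r in records]
    )
    if frame.empty:
        return pd.DataFrame()
    return frame.pivot(index="subject_id", columns="to_visit", values="rate")


def rnfl_rate_table(cohort, criterion: ProgressionCriterion | None = None) -> pd.DataFrame:
    """Per-location RNFL thinning-rate table with aging-aware comparisons.

    One row per RNFL location (global average plus six sectors); columns
    give mean, SD and range of the baseline-anchored annualized rate at
    each target visit, plus the paired follow-up-vs-6-month rate
    comparison for the whole cohort and for the progressive subgroup.
    """
    criterion = criterion or ProgressionCriterion()
    split = group_split(cohort, criterion)
    progressive_ids = {s.subject_id for s in split.progressive}
    rows = []
    for code in SECTOR_CODES:
        pivot = _subject_rates(cohort, f"RNFL.{code}")
        row = {"location": _SECTOR_NAMES[code], "sector": code}
        for visit in ("1pv", "3pv", "6pv", "FUpv"):
            if visit in pivot.columns:
                vals = pivot[visit].dropna()
                row[f"mean_{visit}"] = float(vals.mean())
                row[f"sd_{visit}"] = float(vals.std(ddof=1))
                row[f"min_{visit}"] = float(vals.min())
                row[f"max_{visit}"] = float(vals.max())
        for label, ids in (("all", None), ("progressive", progressive_ids)):
            if {"6pv", "FUpv"} <= set(pivot.columns):
                paired = pivot[["6pv", "FUpv"]].dropna()
                if ids is not None:
                    paired = paired.loc[paired.index.isin(ids)]
                if len(paired):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        test = stats_mod.wilcoxon_signed_rank(
                            paired["FUpv"], paired["6pv"]
                        )
                    row[f"p_fu_vs_6m_{label}"] = test.p_value
        rows.append(row)
    return pd.DataFrame(rows)


_ASSOCIATION_RESPONSES = (
    ("RNFL base", "base"),
    ("RNFL 1pv", "1pv"),
    ("RNFL 3pv", "3pv"),
    ("RNFL 6pv", "6pv"),
    ("RNFL FUpv", "FUpv"),
)


def association_analysis(cohort, p_enter=0.05, p_remove=0.10, screen_p=0.10) -> pd.DataFrame:
    """Factors associated with RNFL thickness, its rate, and baseline IOP.

    For each response (RNFL at every visit, the 6-month-to-follow-up RNFL
    rate, baseline IOP) the candidate predictors — baseline LCD, the
    baseline-anchored LCD rates at each visit, age and baseline IOP — are
    screened univariately at ``screen_p`` and the survivors run through
    bidirectional stepwise selection. Returns the long-format regression
    table (slope, CI, R, univariate p, In/Out status, stepwise p).
    """
    lcd_rates = _subject_rates(cohort, "LCD")
    rnfl = {}
    base_fields = {}
    for series in cohort:
        for v in series.visits:
            if v.rnfl.G is not None:
                rnfl.setdefault(v.visit_label, {})[series.subject_id] = v.rnfl.G
        b = series.baseline
        if b is not None:
            base_fields[series.subject_id] = {
                "LCD base": b.lcd, "age": b.age, "IOP base": b.iop,
            }
    subjects = sorted(base_fields)
    predictors = pd.DataFrame(index=subjects)
    for name in ("LCD base", "age", "IOP base"):
        predictors[name] = [base_fields[s][name] for s in subjects]
    for visit in ("1pv", "3pv", "6pv", "FUpv"):
        if visit in lcd_rates.columns:
            predictors[f"LCD rate {visit}"] = lcd_rates[visit].reindex(subjects)

    fu6_records, _ = rates_mod.cohort_rate_table(cohort, "RNFL.G", anchor="fu-vs-6m")
    fu6 = pd.Series({r.subject_id: r.rate for r in fu6_records}).reindex(subjects)

    responses = {}
    for label, visit in _ASSOCIATION_RESPONSES:
        responses[label] = pd.Series(rnfl.get(visit, {})).reindex(subjects)
    responses["RNFL rate FUpv-6pv"] = fu6
    responses["IOP base"] = predictors["IOP base"]

    rows = []
    for resp_name, y in responses.items():
        cand = predictors.drop(columns=[resp_name], errors="ignore")
        mask = y.notna() & cand.notna().all(axis=1)
        if mask.sum() < 4:
            continue
        results = stats_mod.stepwise_multivariate(
            y[mask].to_numpy(), cand.loc[mask], response=resp_name,
            p_enter=p_enter, p_remove=p_remove, screen_p=screen_p,
        )
        for res in results:
            if res.stepwise_status is None and res.p > screen_p:
                continue  # mirror the published table: screened-in rows only
            rows.append({
                "response": res.response, "predictor": res.predictor,
                "beta": res.beta, "ci_low": res.beta_ci[0],
                "ci_high": res.beta_ci[1], "R": res.r, "P": res.p,
                "status": res.stepwise_status, "stepwise_P": res.stepwise_p,
                "n": res.n,
            })
    return pd.DataFrame(rows)


def _load_cohort(config: PipelineConfig, stage_errors: list):
    if config.cohort_csv:
        return list(read_cohort(config.cohort_csv)), "csv"
    if config.supplementary_xlsx:
        if not config.column_mapping:
            raise ValueError("supplementary ingestion requires a column mapping")
        return (
            list(ingest_supplementary(config.supplementary_xlsx,
                                      config.column_mapping)),
            "xlsx",
        )
    if config.simulate_if_missing:
        cohort, _ = generate_cohort(CohortGeneratorConfig(), seed=config.seed)
        return cohort, "synthetic"
    raise ValueError("no cohort input configured")


def _stamp_and_write(frame: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"lamina report | seed={config.seed} | config={config.config_hash()}"
    tables: dict = {}
    files: dict = {}

    try:
        cohort, source = _load_cohort(config, [])
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc

    criterion = config.criterion

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r}: {exc}") from exc

    tables["rates_rnfl"] = _run("rates", lambda: rnfl_rate_table(cohort, criterion))
    for param, name in (("LCD", "rates_lcd"), ("IOP", "rates_iop")):
        _, summary = _run(name, lambda p=param: rates_mod.cohort_rate_table(
            cohort, p, anchor="baseline"))
        tables[name] = summary

    def _classification():
        records, _ = rates_mod.cohort_rate_table(cohort, "RNFL.G", anchor="baseline")
        fu = {r.subject_id: r for r in records if r.to_visit == "FUpv"}
        rows = []
        for series in cohort:
            rec = fu.get(series.subject_id)
            rows.append({
                "subject_id": series.subject_id,
                "rnfl_rate_base_to_fu": rec.rate if rec else np.nan,
                "label": classify_progression(rec, criterion) if rec else "unclassified",
            })
        return pd.DataFrame(rows)

    tables["classification"] = _run("classify", _classification)
    split = _run("classify", lambda: group_split(cohort, criterion))
    tables["group_baselines"] = split.baseline_summary.reset_index()

    for param, name in (("IOP", "visitwise_iop"), ("LCD", "visitwise_lcd"),
                        ("RNFL.G", "visitwise_rnfl")):
        tables[name] = _run(name, lambda p=param: stats_mod.visitwise_summary(
            cohort, p).reset_index())

    def _lme_table():
        frame = cohort_to_frame(cohort)
        rows = []
        for param, column in (("IOP", "iop_mmHg"), ("LCD", "lcd_um"),
                              ("RNFL.G", "rnfl_G")):
            obs = frame[["subject_id", "t_months", column]].dropna()
            if len(obs) < 2 or obs["t_months"].nunique() < 2:
                continue  # parameter absent from this cohort
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = stats_mod.fit_lme(
                    pd.DataFrame({
                        "subject": obs["subject_id"],
                        "t_years": obs["t_months"] / 12.0,
                        "value": obs[column],
                    }),
                    parameter=param,
                )
            rows.append({
                "parameter": param, "beta0": fit.beta0,
                "beta0_ci_low": fit.beta0_ci[0], "beta0_ci_high": fit.beta0_ci[1],
                "beta1": fit.beta1,
                "beta1_ci_low": fit.beta1_ci[0], "beta1_ci_high": fit.beta1_ci[1],
                "p_beta1": fit.p_beta1,
                "random_intercept_sd": fit.random_intercept_sd,
                "residual_sd": fit.residual_sd,
                "n_subjects": fit.n_subjects,
                "n_observations": fit.n_observations,
            })
        return pd.DataFrame(rows)

    tables["lme"] = _run("lme", _lme_table)
    tables["regression"] = _run("regression", lambda: association_analysis(
        cohort, config.p_enter, config.p_remove, config.screen_p))

    for name, frame in tables.items():
        path = out / f"{name}.csv"
        _stamp_and_write(frame, path, stamp)
        files[name] = str(path)

    lme = tables["lme"].set_index("parameter")
    n_prog, n_non = split.sizes
    lines = [
        stamp,
        f"cohort source: {source} ({len(cohort)} subjects)",
        f"progressive / non-progressive split: {n_prog} / {n_non} "
        f"(threshold {criterion.threshold:.4f} um/year)",
    ]
    for param in ("IOP", "LCD", "RNFL.G"):
        if param not in lme.index:
            continue
        row = lme.loc[param]
        lines.append(
            f"LME {param}: beta0 = {row['beta0']:.1f} "
            f"({row['beta0_ci_low']:.1f}; {row['beta0_ci_high']:.1f}), "
            f"beta1 = {row['beta1']:.1f} "
            f"({row['beta1_ci_low']:.1f}; {row['beta1_ci_high']:.1f}) per year"
        )
    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    files["summary"] = str(summary_path)

    return PipelineResult(config=config, cohort=tuple(cohort),
                          tables=tables, files=files)
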