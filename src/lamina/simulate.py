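"""Seedable synthetic-cohort and synthetic-eye generators with ground truth.

The cohort generator emulates the longitudinal structure of a ~29-subject
post-glaucoma-surgery cohort: visits at 0, 1, 3 and 6 months plus a final
follow-up drawn uniformly from 12-29 months; a fast post-surgical drop in
intraocular pressure to a plateau with a slow late drift; biphasic anterior
lamina cribrosa displacement (a fast first-month reduction followed by a
slow linear drift); and RNFL thickness with a transient 1-month swelling
that decays by 3 months, followed by thinning. Per-subject (LCD slope,
RNFL slope) pairs are drawn from a bivariate normal with a configurable
negative correlation, and baseline IOP shares a factor with the LCD slope
so that higher preoperative pressure goes with faster postoperative LC
displacement.

Each trajectory follows

    value(t) = plateau + (baseline - plateau) * exp(-t / tau)
               + slope * t_years + swelling(t)        (RNFL only)
               + iid measurement noise,

the simplest form reproducing the fast-then-slow pressure/depth course and
the transient swelling. The ground truth (every latent drawn) is returned
alongside the data so recovery experiments can compare estimates to truth.

The eye generator produces per-B-scan landmark annotations over a circular
optic disc with a paraboloid anterior LC surface: the per-scan apex depth
is known by construction (the apex is always among the sampled LC points),
so the noise-free measured depth equals the true depth exactly, under any
scan tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    BScanAnnotation,
    SECTOR_CODES,
    SectorProfile,
    SubjectSeries,
    VisitRecord,
)

__all__ = [
    "CohortGeneratorConfig",
    "EyeGeometryConfig",
    "CohortTruth",
    "EyeTruth",
    "generate_cohort",
    "generate_eye_annotations",
    "fixture_case_reports",
]

#: Sector mean offsets (um) from the global average, and sector-specific
#: thinning-rate multipliers (temporal-inferior and nasal-inferior fastest).
SECTOR_OFFSETS = {"TS": 10.0, "T": -15.0, "TI": 8.0, "NS": 5.0, "N": -5.0, "NI": 6.0}
SECTOR_RATE_MULTIPLIERS = {
    "TS": 1.46, "T": 0.50, "TI": 1.64, "NS": 1.14, "N": 0.75, "NI": 1.32,
}


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Parameters of the synthetic longitudinal cohort.

    Defaults encode the emulated study conditions: 29 subjects, baseline
    IOP 24.0 +/- 8.9 mmHg relaxing to a ~9 mmHg plateau, baseline LCD
    465.3 +/- 136.4 um with a ~62 um first-month reduction and a
    -53.2 um/year slow drift, baseline RNFL 59.3 +/- 15.8 um with a net
    +5.6 um swelling at 1 month and per-subject thinning of
    -2.8 +/- 4.0 um/year, correlated with the LCD drift at -0.6.
    """

    n_subjects: int = 29
    scheduled_months: tuple = (0.0, 1.0, 3.0, 6.0)
    fu_months_range: tuple = (12.0, 29.0)
    # intraocular pressure (mmHg)
    iop_baseline_mean: float = 24.0
    iop_baseline_sd: float = 8.9
    iop_floor_mean: float = 9.0
    iop_floor_sd: float = 2.0
    iop_tau_months: float = 0.4
    iop_drift_mean: float = 2.2    # mmHg/year late re-rise
    iop_drift_sd: float = 1.0
    # lamina cribrosa depth (um)
    lcd_baseline_mean: float = 465.3
    lcd_baseline_sd: float = 136.4
    lcd_fast_drop_mean: float = 62.0
    lcd_fast_drop_sd: float = 30.0
    lcd_tau_months: float = 0.5
    lcd_slope_mean: float = -53.2  # um/year slow-phase drift
    lcd_slope_sd: float = 25.0
    # RNFL thickness (um)
    rnfl_baseline_mean: float = 59.3
    rnfl_baseline_sd: float = 15.8
    rnfl_swelling_mean: float = 5.6   # net expected 1-month minus baseline
    rnfl_swelling_sd: float = 3.0
    rnfl_swelling_width_months: float = 0.4
    rnfl_slope_mean: float = -2.8
    rnfl_slope_sd: float = 4.0
    # latent correlations
    rate_correlation: float = -0.6       # corr(LCD slope, RNFL slope)
    iop_lcd_correlation: float = -0.4    # corr(baseline IOP, LCD slope)
    # measurement noise
    noise_sd_iop: float = 1.5
    noise_sd_lcd: float = 15.0
    noise_sd_rnfl: float = 2.0
    # covariates and missingness
    age_mean: float = 65.8
    age_sd: float = 10.8
    trabeculectomy_fraction: float = 16 / 29
    n_lost_to_followup: int = 0

    def __post_init__(self) -> None:
        for name in ("iop_baseline_sd", "iop_floor_sd", "iop_drift_sd",
                     "lcd_baseline_sd", "lcd_fast_drop_sd", "lcd_slope_sd",
                     "rnfl_baseline_sd", "rnfl_swelling_sd", "rnfl_slope_sd",
                     "noise_sd_iop", "noise_sd_lcd", "noise_sd_rnfl", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.rate_correlation) <= 1:
            raise ValueError("|rate_correlation| must be <= 1")
        if not abs(self.iop_lcd_correlation) <= 1:
            raise ValueError("|iop_lcd_correlation| must be <= 1")
        lo, hi = self.fu_months_range
        if not (12.0 <= lo <= hi <= 29.0):
            raise ValueError("fu_months_range must lie within [12, 29]")

    def linear_trend(self, lcd_slope_mean: float | None = None,
                     rnfl_slope_mean: float | None = None) -> "CohortGeneratorConfig":
        """Model-matched variant for trend-recovery experiments.

        A parameter-recovery experiment is only well-defined when the
        generating process matches the fitted model, so this variant
        produces exactly the random-intercept linear model: no fast
        exponential phase, no transient swelling, and homogeneous
        (zero-variance) slopes — leaving random intercepts (the baseline
        SDs) and measurement noise as the only stochastic components.
        """
        return replace(
            self,
            lcd_fast_drop_mean=0.0,
            lcd_fast_drop_sd=0.0,
            rnfl_swelling_mean=0.0,
            rnfl_swelling_sd=0.0,
            lcd_slope_sd=0.0,
            rnfl_slope_sd=0.0,
            lcd_slope_mean=(self.lcd_slope_mean if lcd_slope_mean is None
                            else lcd_slope_mean),
            rnfl_slope_mean=(self.rnfl_slope_mean if rnfl_slope_mean is None
                             else rnfl_slope_mean),
        )

    def latent_correlation_matrix(self) -> np.ndarray:
        """Correlation of (LCD slope, RNFL slope, baseline IOP).

        Built from the two configured pairwise correlations with the
        RNFL-IOP entry implied by conditional independence given the LCD
        slope; validated positive semi-definite.
        """
        r1, r2 = self.rate_correlation, self.iop_lcd_correlation
        corr = np.array([
            [1.0, r1, r2],
            [r1, 1.0, r1 * r2],
            [r2, r1 * r2, 1.0],
        ])
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError("latent correlation matrix is not positive semi-definite")
        return corr


@dataclass(frozen=True)
class CohortTruth:
    """Every latent used by the generator, for recovery experiments."""

    subjects: pd.DataFrame      # one row per subject: baselines, slopes, FU time
    trajectories: pd.DataFrame  # noise-free values per subject-visit


def _swelling_amplitude(net_swelling: float, slope: float,
                        width_months: float) -> float:
    """Gaussian-bump amplitude giving an exact net 1-month swelling.

    The bump is centred at 1 month; its residual value at t = 0 and the
    one-month share of the thinning slope are compensated so that the
    noise-free (1pv - baseline) difference equals ``net_swelling``.
    """
    g0 = math.exp(-1.0 / (2.0 * width_months ** 2))
    return (net_swelling - slope / 12.0) / (1.0 - g0)


def generate_cohort(config: CohortGeneratorConfig | None = None,
                    seed: int = 0):
    """Draw a synthetic cohort; returns ``(series_list, CohortTruth)``.

    Reproducible: a fixed ``(config, seed)`` pair yields byte-identical
    output (single fixed-algorithm PCG64 stream, no platform-dependent
    sampling).
    """
    config = config or CohortGeneratorConfig()
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    corr = config.latent_correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    lcd_slope = config.lcd_slope_mean + config.lcd_slope_sd * z[:, 0]
    rnfl_slope = config.rnfl_slope_mean + config.rnfl_slope_sd * z[:, 1]
    iop_base = config.iop_baseline_mean + config.iop_baseline_sd * z[:, 2]

    iop_floor = rng.normal(config.iop_floor_mean, config.iop_floor_sd, n)
    iop_floor = np.clip(iop_floor, 4.0, None)
    iop_base = np.maximum(iop_base, iop_floor + 2.0)
    iop_drift = rng.normal(config.iop_drift_mean, config.iop_drift_sd, n)

    lcd_base = rng.normal(config.lcd_baseline_mean, config.lcd_baseline_sd, n)
    lcd_base = np.clip(lcd_base, 100.0, None)
    lcd_drop = rng.normal(config.lcd_fast_drop_mean, config.lcd_fast_drop_sd, n)

    rnfl_base = rng.normal(config.rnfl_baseline_mean, config.rnfl_baseline_sd, n)
    rnfl_base = np.clip(rnfl_base, 20.0, None)
    swelling = rng.normal(config.rnfl_swelling_mean, config.rnfl_swelling_sd, n)

    fu_months = rng.uniform(*config.fu_months_range, n)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 40.0, 90.0)
    n_trab = int(round(config.trabeculectomy_fraction * n))
    surgeries = np.array(["trabeculectomy"] * n_trab + ["NPDS"] * (n - n_trab))
    rng.shuffle(surgeries)

    sector_base_jitter = rng.normal(0.0, 3.0, (n, len(SECTOR_CODES) - 1))

    width = config.rnfl_swelling_width_months
    subject_rows, traj_rows, series_list = [], [], []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        amp = _swelling_amplitude(swelling[i], rnfl_slope[i], width)
        months = list(config.scheduled_months) + [float(fu_months[i])]
        labels = ["base", "1pv", "3pv", "6pv", "FUpv"]
        visits = []
        for lbl, t in zip(labels, months):
            ty = t / 12.0
            iop_true = (iop_floor[i]
                        + (iop_base[i] - iop_floor[i])
                        * math.exp(-t / config.iop_tau_months)
                        + iop_drift[i] * ty)
            lcd_true = (lcd_base[i]
                        - lcd_drop[i] * (1.0 - math.exp(-t / config.lcd_tau_months))
                        + lcd_slope[i] * ty)
            bump = amp * math.exp(-((t - 1.0) ** 2) / (2.0 * width ** 2))
            rnfl_true = rnfl_base[i] + rnfl_slope[i] * ty + bump
            iop_obs = max(1.0, iop_true + rng.normal(0.0, config.noise_sd_iop))
            lcd_obs = lcd_true + rng.normal(0.0, config.noise_sd_lcd)
            g_obs = max(1.0, rnfl_true + rng.normal(0.0, config.noise_sd_rnfl))
            sectors = {"G": g_obs}
            for j, code in enumerate(c for c in SECTOR_CODES if c != "G"):
                sec_true = (rnfl_base[i] + SECTOR_OFFSETS[code]
                            + sector_base_jitter[i, j]
                            + rnfl_slope[i] * SECTOR_RATE_MULTIPLIERS[code] * ty
                            + bump)
                sectors[code] = max(
                    1.0, sec_true + rng.normal(0.0, config.noise_sd_rnfl)
                )
            visits.append(
                VisitRecord(
                    subject_id=sid,
                    visit_label=lbl,
                    t_months=t,
                    iop=float(iop_obs),
                    rnfl=SectorProfile(**{k: float(v) for k, v in sectors.items()}),
                    lcd=float(lcd_obs),
                    age=float(ages[i]),
                    surgery=str(surgeries[i]),
                )
            )
            traj_rows.append({
                "subject_id": sid, "visit_label": lbl, "t_months": t,
                "iop_true": iop_true, "lcd_true": lcd_true,
                "rnfl_true": rnfl_true,
            })
        if i < config.n_lost_to_followup:
            # mirror early loss to follow-up: last lost subject keeps the
            # 6-month course, the others only the baseline visit
            keep = 4 if i == config.n_lost_to_followup - 1 else 1
            visits = visits[:keep]
        series_list.append(SubjectSeries(subject_id=sid, visits=tuple(visits)))
        subject_rows.append({
            "subject_id": sid, "age": float(ages[i]),
            "surgery": str(surgeries[i]),
            "iop_base_true": float(iop_base[i]),
            "iop_floor_true": float(iop_floor[i]),
            "iop_drift_true": float(iop_drift[i]),
            "lcd_base_true": float(lcd_base[i]),
            "lcd_fast_drop_true": float(lcd_drop[i]),
            "lcd_slope_true": float(lcd_slope[i]),
            "rnfl_base_true": float(rnfl_base[i]),
            "rnfl_slope_true": float(rnfl_slope[i]),
            "rnfl_net_swelling_true": float(swelling[i]),
            "fu_months": float(fu_months[i]),
        })
    truth = CohortTruth(
        subjects=pd.DataFrame(subject_rows),
        trajectories=pd.DataFrame(traj_rows),
    )
    return series_list, truth


# ---------------------------------------------------------------------------
# synthetic eye geometry


@dataclass(frozen=True)
class EyeGeometryConfig:
    """Parameters of the synthetic optic-disc landmark geometry.

    The anterior LC surface is a paraboloid of apex depth
    ``apex_depth_um`` below the BMO plane over a circular disc; each
    horizontal B-scan sees a chord of the disc with a parabolic LC profile
    whose per-scan apex depth follows the paraboloid.
    """

    n_scans: int = 75
    bmo_width_um: float = 1500.0
    apex_depth_um: float = 400.0
    disc_margin_fraction: float = 0.05  # scans extend slightly past the disc
    n_lc_points: int = 8
    landmark_jitter_sd_um: float = 0.0
    tilt_range_deg: float = 0.0
    scan_spacing_um: float = 32.0

    def __post_init__(self) -> None:
        if self.apex_depth_um <= 0:
            raise ValueError("apex_depth_um must be > 0 for a glaucoma-like eye")
        if self.landmark_jitter_sd_um < 0:
            raise ValueError("landmark_jitter_sd_um must be >= 0")
        if not 1 <= self.n_lc_points <= 8:
            raise ValueError("n_lc_points must be within 1..8")


@dataclass(frozen=True)
class EyeTruth:
    """Ground-truth per-scan apex depths of a synthetic eye."""

    apex_depths: np.ndarray  # (n_scans,)

    def mean_lcd(self, scan_indices: Sequence[int] | None = None) -> float:
        """True mean LCD over any scan selection (default: all scans)."""
        idx = (np.arange(len(self.apex_depths)) if scan_indices is None
               else np.asarray(scan_indices, dtype=int))
        return float(self.apex_depths[idx].mean())


def _lc_lateral_positions(half_width: float, n_points: int) -> np.ndarray:
    """LC sampling abscissae spanning the chord, apex included exactly."""
    xs = np.linspace(-0.9 * half_width, 0.9 * half_width, n_points)
    if n_points % 2 == 0:
        xs[np.argmin(np.abs(xs))] = 0.0  # guarantee the apex is sampled
    return xs


def generate_eye_annotations(config: EyeGeometryConfig | None = None,
                             seed: int = 0):
    """Draw per-scan landmark annotations; returns ``(annotations, EyeTruth)``.

    With zero jitter the measured scan LCD equals the true per-scan apex
    depth exactly, for any tilt, because the apex is always among the
    sampled LC points and the measurement is rigid-motion invariant.
    """
    config = config or EyeGeometryConfig()
    rng = np.random.default_rng(seed)
    n = config.n_scans
    center = (n - 1) / 2.0
    disc_radius = center * (1.0 + config.disc_margin_fraction)
    annotations, depths = [], np.zeros(n)
    for j in range(n):
        rel = (j - center) / disc_radius          # -1..1 across the disc
        chord = math.sqrt(max(1e-4, 1.0 - rel ** 2))
        half_width = 0.5 * config.bmo_width_um * chord
        depth = config.apex_depth_um * max(0.05, 1.0 - rel ** 2)
        depths[j] = depth
        xs = _lc_lateral_positions(half_width, config.n_lc_points)
        ys = depth * (1.0 - (xs / half_width) ** 2)
        bmo = np.array([[-half_width, 0.0], [half_width, 0.0]])
        lc = np.column_stack([xs, ys])
        if config.landmark_jitter_sd_um > 0:
            bmo = bmo + rng.normal(0.0, config.landmark_jitter_sd_um, bmo.shape)
            lc = lc + rng.normal(0.0, config.landmark_jitter_sd_um, lc.shape)
        tilt = (rng.uniform(-config.tilt_range_deg, config.tilt_range_deg)
                if config.tilt_range_deg > 0 else 0.0)
        shift = rng.uniform(-500.0, 500.0, 2)
        ann = BScanAnnotation(
            scan_index=j, bmo_points=bmo, lc_points=lc,
            axial_positive_is_posterior=True,
        ).transformed(rotation_deg=tilt, translation=shift)
        annotations.append(ann)
    return annotations, EyeTruth(apex_depths=depths)


# ---------------------------------------------------------------------------
# printed worked-example fixtures


def _case_series(sid, age, surgery, fu_months, lcd, rnfl, iop=None) -> SubjectSeries:
    visits = []
    for lbl, t in (("base", 0.0), ("6pv", 6.0), ("FUpv", fu_months)):
        visits.append(
            VisitRecord(
                subject_id=sid, visit_label=lbl, t_months=t,
                iop=None if iop is None else iop[lbl],
                rnfl=SectorProfile(G=rnfl[lbl]),
                lcd=lcd[lbl], age=age, surgery=surgery,
            )
        )
    return SubjectSeries(subject_id=sid, visits=tuple(visits))


def fixture_case_reports():
    """The two published worked-example eyes, as visit series.

    Case A (trabeculectomy, follow-up at 20 months): LCD 641 -> 522 (6
    months) -> 388 um, global RNFL 61 -> 47 -> 47 um; the
    baseline-to-follow-up RNFL rate works out to -8.4 um/year. Case B
    (deep sclerectomy, follow-up at 21 months): LCD 330 -> 258 -> 232 um,
    RNFL 86 -> 77 -> 64 um; rate -12.6 um/year at one-decimal reporting.
    """
    case_a = _case_series(
        "case-trab", age=62.0, surgery="trabeculectomy", fu_months=20.0,
        lcd={"base": 641.0, "6pv": 522.0, "FUpv": 388.0},
        rnfl={"base": 61.0, "6pv": 47.0, "FUpv": 47.0},
    )
    case_b = _case_series(
        "case-npds", age=81.0, surgery="NPDS", fu_months=21.0,
        lcd={"base": 330.0, "6pv": 258.0, "FUpv": 232.0},
        rnfl={"base": 86.0, "6pv": 77.0, "FUpv": 64.0},
    )
    return case_a, case_b
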