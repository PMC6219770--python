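"""Domain types and file IO for landmark annotations and longitudinal cohorts.

Two on-disk formats are owned by this module:

* **Annotation JSON** — one file per eye, holding per-B-scan landmark sets
  (2 Bruch's-membrane-opening points + up to 8 anterior lamina cribrosa
  points) in physical micrometres::

      {"eye_id": "...", "axial_positive_is_posterior": true,
       "scans": [{"scan_index": 0, "bmo": [[x, y], [x, y]],
                  "lc": [[x, y], ...]}, ...]}

* **Cohort CSV** — long-format visit table with the exact header
  ``subject_id,visit_label,t_months,iop_mmHg,rnfl_G,rnfl_TS,rnfl_T,rnfl_TI,
  rnfl_NS,rnfl_N,rnfl_NI,lcd_um,age_years,cct_um,al_mm,vf_md_db,vf_psd_db,
  surgery,n_meds``; empty cells are missing values.

A supplementary spreadsheet (XLSX) can be ingested through a user-supplied
column mapping, since spreadsheet layouts vary between depositions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationError",
    "CohortError",
    "BScanAnnotation",
    "ReferenceLine",
    "EyeLCDResult",
    "SectorProfile",
    "VisitRecord",
    "SubjectSeries",
    "VISIT_LABELS",
    "SECTOR_CODES",
    "COHORT_COLUMNS",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "ingest_supplementary",
    "read_column_mapping",
]

#: Canonical visit order: preoperative baseline, then 1-, 3-, 6-month and
#: final follow-up postoperative visits.
VISIT_LABELS = ("base", "1pv", "3pv", "6pv", "FUpv")

#: Circumpapillary RNFL sector codes: global average plus the six
#: Garway-Heath-style sectors (temporal superior/temporal/temporal inferior,
#: nasal superior/nasal/nasal inferior).
SECTOR_CODES = ("G", "TS", "T", "TI", "NS", "N", "NI")

#: Exact cohort CSV header, in canonical column order.
COHORT_COLUMNS = (
    "subject_id",
    "visit_label",
    "t_months",
    "iop_mmHg",
    "rnfl_G",
    "rnfl_TS",
    "rnfl_T",
    "rnfl_TI",
    "rnfl_NS",
    "rnfl_N",
    "rnfl_NI",
    "lcd_um",
    "age_years",
    "cct_um",
    "al_mm",
    "vf_md_db",
    "vf_psd_db",
    "surgery",
    "n_meds",
)

#: Nominal months since surgery for the scheduled visits; the final
#: follow-up time is subject-specific (12-29 months in study-like cohorts).
NOMINAL_VISIT_MONTHS = {"base": 0.0, "1pv": 1.0, "3pv": 3.0, "6pv": 6.0}

FU_MONTHS_RANGE = (12.0, 29.0)

SURGERY_TYPES = ("trabeculectomy", "NPDS")


class AnnotationError(ValueError):
    """Raised for malformed or invalid annotation files."""


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort tables."""


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, eq=False)
class BScanAnnotation:
    """Landmarks of a single OCT B-scan, in physical micrometres.

    Parameters
    ----------
    scan_index:
        Zero-based position of the B-scan in the volume raster.
    bmo_points:
        Exactly two distinct (lateral, axial) points marking the Bruch's
        membrane opening.
    lc_points:
        1-8 (lateral, axial) points sampling the anterior lamina cribrosa
        surface.
    axial_positive_is_posterior:
        True when the axial coordinate increases into the eye (the default
        convention); the depth sign is defined relative to this flag.
    """

    scan_index: int
    bmo_points: np.ndarray
    lc_points: np.ndarray
    axial_positive_is_posterior: bool = True

    def __post_init__(self) -> None:
        bmo = np.asarray(self.bmo_points, dtype=float)
        lc = np.asarray(self.lc_points, dtype=float)
        if self.scan_index < 0:
            raise AnnotationError(f"scan_index must be >= 0, got {self.scan_index}")
        if bmo.shape != (2, 2):
            raise AnnotationError(
                f"scan {self.scan_index}: exactly 2 BMO points required, "
                f"got array of shape {bmo.shape}"
            )
        if lc.ndim != 2 or lc.shape[1] != 2 or lc.shape[0] < 1:
            raise AnnotationError(
                f"scan {self.scan_index}: at least 1 anterior-LC point required"
            )
        if lc.shape[0] > 8:
            warnings.warn(
                f"scan {self.scan_index}: {lc.shape[0]} LC points exceeds the "
                "usual 8-point protocol",
                stacklevel=2,
            )
        if not (np.isfinite(bmo).all() and np.isfinite(lc).all()):
            raise AnnotationError(
                f"scan {self.scan_index}: non-finite coordinates"
            )
        if float(np.hypot(*(bmo[1] - bmo[0]))) <= 0.0:
            raise AnnotationError(
                f"scan {self.scan_index}: BMO points coincide"
            )
        object.__setattr__(self, "bmo_points", bmo)
        object.__setattr__(self, "lc_points", lc)

    def transformed(self, rotation_deg: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0),
                    scale: float = 1.0) -> "BScanAnnotation":
        """Return a copy with all landmarks rigidly moved and/or scaled."""
        theta = math.radians(rotation_deg)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        shift = np.asarray(translation, dtype=float)
        return replace(
            self,
            bmo_points=scale * self.bmo_points @ rot.T + shift,
            lc_points=scale * self.lc_points @ rot.T + shift,
        )


@dataclass(frozen=True, eq=False)
class ReferenceLine:
    """The BMO reference line: the segment joining the two BMO landmarks.

    ``alpha`` is the signed angle of the segment to the horizontal, in
    degrees, normalized to (-90, 90].
    """

    point_a: np.ndarray
    point_b: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if not (-90.0 < self.alpha <= 90.0):
            raise ValueError(f"alpha must lie in (-90, 90], got {self.alpha}")
        object.__setattr__(self, "point_a", np.asarray(self.point_a, dtype=float))
        object.__setattr__(self, "point_b", np.asarray(self.point_b, dtype=float))


@dataclass(frozen=True)
class EyeLCDResult:
    """Eye-level lamina cribrosa depth: per-scan values and their mean."""

    per_scan_lcd: tuple  # of (scan_index, lcd_um) pairs
    mean_lcd: float
    n_scans_used: int

    def __post_init__(self) -> None:
        values = [v for _, v in self.per_scan_lcd]
        if len(values) != self.n_scans_used or not values:
            raise ValueError("per_scan_lcd inconsistent with n_scans_used")
        if not (min(values) - 1e-9 <= self.mean_lcd <= max(values) + 1e-9):
            raise ValueError("mean_lcd outside the per-scan range")


@dataclass(frozen=True)
class SectorProfile:
    """Circumpapillary RNFL thickness profile in micrometres.

    ``G`` is the global average; the remaining fields are the six sectors.
    ``None`` marks a missing measurement.
    """

    G: float | None = None
    TS: float | None = None
    T: float | None = None
    TI: float | None = None
    NS: float | None = None
    N: float | None = None
    NI: float | None = None

    def __post_init__(self) -> None:
        for code in SECTOR_CODES:
            v = getattr(self, code)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"RNFL {code} must be finite and > 0, got {v}")

    def missing_sectors(self) -> tuple:
        return tuple(c for c in SECTOR_CODES if getattr(self, c) is None)


@dataclass(frozen=True)
class VisitRecord:
    """One subject-visit: pressure, RNFL profile, LC depth, covariates."""

    subject_id: str
    visit_label: str
    t_months: float
    iop: float | None = None
    rnfl: SectorProfile = field(default_factory=SectorProfile)
    lcd: float | None = None
    age: float | None = None
    cct: float | None = None
    al: float | None = None
    vf_md: float | None = None
    vf_psd: float | None = None
    surgery: str | None = None
    n_medications: float | None = None

    def __post_init__(self) -> None:
        if self.visit_label not in VISIT_LABELS:
            raise CohortError(
                f"unknown visit label {self.visit_label!r}; expected one of "
                f"{VISIT_LABELS}"
            )
        if _is_missing(self.t_months) or self.t_months < 0:
            raise CohortError(
                f"{self.subject_id}/{self.visit_label}: t_months must be >= 0"
            )
        if self.visit_label == "base" and self.t_months != 0:
            raise CohortError(
                f"{self.subject_id}: baseline visit must have t_months = 0"
            )
        if self.visit_label == "FUpv" and not (
            FU_MONTHS_RANGE[0] <= self.t_months <= FU_MONTHS_RANGE[1]
        ):
            warnings.warn(
                f"{self.subject_id}: follow-up at {self.t_months} months is "
                f"outside the usual {FU_MONTHS_RANGE} window",
                stacklevel=2,
            )
        if self.surgery is not None and self.surgery not in SURGERY_TYPES:
            raise CohortError(
                f"{self.subject_id}: unknown surgery type {self.surgery!r}"
            )

    @property
    def t_years(self) -> float:
        return self.t_months / 12.0

    def value(self, parameter: str) -> float | None:
        """Look up a measurement by parameter code (IOP, LCD, RNFL.<sector>)."""
        if parameter == "IOP":
            return self.iop
        if parameter == "LCD":
            return self.lcd
        if parameter.startswith("RNFL."):
            code = parameter.split(".", 1)[1]
            if code not in SECTOR_CODES:
                raise KeyError(f"unknown RNFL sector {code!r}")
            return getattr(self.rnfl, code)
        raise KeyError(f"unknown parameter {parameter!r}")


@dataclass(frozen=True)
class SubjectSeries:
    """The ordered visit history of one subject (one study eye)."""

    subject_id: str
    visits: tuple  # of VisitRecord, ordered by t_months

    def __post_init__(self) -> None:
        labels = [v.visit_label for v in self.visits]
        if len(set(labels)) != len(labels):
            raise CohortError(f"{self.subject_id}: duplicate visit labels")
        times = [v.t_months for v in self.visits]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise CohortError(
                f"{self.subject_id}: t_months not strictly increasing: {times}"
            )
        order = [VISIT_LABELS.index(lbl) for lbl in labels]
        if order != sorted(order):
            raise CohortError(
                f"{self.subject_id}: visit labels out of chronological order"
            )
        object.__setattr__(self, "visits", tuple(self.visits))

    def visit(self, label: str) -> VisitRecord | None:
        for v in self.visits:
            if v.visit_label == label:
                return v
        return None

    @property
    def completeness(self) -> dict:
        """Which of the five scheduled visits are present."""
        present = {v.visit_label for v in self.visits}
        return {lbl: lbl in present for lbl in VISIT_LABELS}

    @property
    def is_complete(self) -> bool:
        return all(self.completeness.values())

    @property
    def baseline(self) -> VisitRecord | None:
        return self.visit("base")


# ---------------------------------------------------------------------------
# annotation JSON


def read_annotations(path) -> list:
    """Read an annotation JSON file into validated :class:`BScanAnnotation`\\ s."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict) or "scans" not in payload:
        raise AnnotationError(f"{path}: missing top-level 'scans' array")
    axial_flag = bool(payload.get("axial_positive_is_posterior", True))
    annotations = []
    for entry in payload["scans"]:
        try:
            annotations.append(
                BScanAnnotation(
                    scan_index=int(entry["scan_index"]),
                    bmo_points=np.asarray(entry["bmo"], dtype=float),
                    lc_points=np.asarray(entry["lc"], dtype=float),
                    axial_positive_is_posterior=axial_flag,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            idx = entry.get("scan_index", "?") if isinstance(entry, dict) else "?"
            if isinstance(exc, AnnotationError):
                raise
            raise AnnotationError(f"{path}: scan {idx}: {exc}") from exc
    return annotations


def write_annotations(path, annotations: Iterable[BScanAnnotation],
                      eye_id: str = "eye") -> None:
    """Write annotations to the JSON dialect read by :func:`read_annotations`."""
    annotations = list(annotations)
    if not annotations:
        raise AnnotationError("cannot write an empty annotation set")
    flags = {a.axial_positive_is_posterior for a in annotations}
    if len(flags) != 1:
        raise AnnotationError("mixed axial conventions within one file")
    payload = {
        "eye_id": eye_id,
        "axial_positive_is_posterior": flags.pop(),
        "scans": [
            {
                "scan_index": int(a.scan_index),
                "bmo": a.bmo_points.tolist(),
                "lc": a.lc_points.tolist(),
            }
            for a in annotations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# cohort CSV


def _opt(row, column) -> float | None:
    v = row.get(column)
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def _row_to_visit(row: Mapping) -> VisitRecord:
    surgery = row.get("surgery")
    if pd.isna(surgery) if not isinstance(surgery, str) else surgery == "":
        surgery = None
    rnfl = SectorProfile(**{c: _opt(row, f"rnfl_{c}") for c in SECTOR_CODES})
    return VisitRecord(
        subject_id=str(row["subject_id"]),
        visit_label=str(row["visit_label"]),
        t_months=float(row["t_months"]),
        iop=_opt(row, "iop_mmHg"),
        rnfl=rnfl,
        lcd=_opt(row, "lcd_um"),
        age=_opt(row, "age_years"),
        cct=_opt(row, "cct_um"),
        al=_opt(row, "al_mm"),
        vf_md=_opt(row, "vf_md_db"),
        vf_psd=_opt(row, "vf_psd_db"),
        surgery=surgery,
        n_medications=_opt(row, "n_meds"),
    )


def frame_to_cohort(frame: pd.DataFrame) -> list:
    """Build :class:`SubjectSeries` from a long-format cohort DataFrame.

    Invariant to the row and column order of the input.
    """
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise CohortError(f"cohort table missing columns: {sorted(missing)}")
    dup = frame.duplicated(subset=["subject_id", "visit_label"])
    if dup.any():
        bad = frame.loc[dup, ["subject_id", "visit_label"]].iloc[0]
        raise CohortError(
            f"duplicate visit row: subject {bad['subject_id']!r} "
            f"label {bad['visit_label']!r}"
        )
    series = []
    order = {lbl: i for i, lbl in enumerate(VISIT_LABELS)}
    for subject_id, grp in frame.groupby("subject_id", sort=True):
        grp = grp.sort_values("visit_label", key=lambda s: s.map(order))
        visits = [_row_to_visit(row) for _, row in grp.iterrows()]
        series.append(SubjectSeries(subject_id=str(subject_id), visits=tuple(visits)))
    return series


def cohort_to_frame(cohort: Iterable[SubjectSeries]) -> pd.DataFrame:
    """Flatten SubjectSeries into the canonical long-format DataFrame."""
    rows = []
    for series in cohort:
        for v in series.visits:
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "visit_label": v.visit_label,
                    "t_months": v.t_months,
                    "iop_mmHg": v.iop,
                    **{f"rnfl_{c}": getattr(v.rnfl, c) for c in SECTOR_CODES},
                    "lcd_um": v.lcd,
                    "age_years": v.age,
                    "cct_um": v.cct,
                    "al_mm": v.al,
                    "vf_md_db": v.vf_md,
                    "vf_psd_db": v.vf_psd,
                    "surgery": v.surgery,
                    "n_meds": v.n_medications,
                }
            )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def read_cohort(path) -> list:
    """Read a cohort CSV into one :class:`SubjectSeries` per subject."""
    frame = pd.read_csv(path, dtype={"subject_id": str, "surgery": str})
    return frame_to_cohort(frame)


def write_cohort(path, cohort: Iterable[SubjectSeries]) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# supplementary XLSX ingestion


def read_column_mapping(source) -> dict:
    """Parse a column-mapping config: JSON object or ``key=value`` lines.

    Keys are spreadsheet column names, values are canonical cohort columns.
    """
    if isinstance(source, Mapping):
        mapping = dict(source)
    else:
        text = Path(source).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            mapping = json.loads(text)
        else:
            mapping = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                mapping[key.strip()] = value.strip()
    unknown = set(mapping.values()) - set(COHORT_COLUMNS)
    if unknown:
        raise CohortError(
            f"mapping targets unknown canonical columns: {sorted(unknown)}"
        )
    return mapping


_REQUIRED_CANONICAL = ("subject_id", "visit_label", "t_months")


def ingest_supplementary(path, mapping, sheet_name=0) -> list:
    """Read a supplementary XLSX visit table through a column mapping.

    ``mapping`` maps spreadsheet column names to canonical cohort columns
    (a dict, a JSON file, or a ``key=value`` text file). Unmapped sheet
    columns are reported with a warning; unmappable *required* columns are
    an error listing the sheet's candidates.
    """
    mapping = read_column_mapping(mapping)
    frame = pd.read_excel(path, sheet_name=sheet_name)
    if frame.empty:
        warnings.warn(f"{path}: supplementary sheet is empty", stacklevel=2)
        return []
    present = [c for c in frame.columns if c in mapping]
    unmapped = [c for c in frame.columns if c not in mapping]
    if unmapped:
        warnings.warn(
            f"{path}: ignoring unmapped columns {unmapped}", stacklevel=2
        )
    frame = frame[present].rename(columns=mapping)
    missing_required = [c for c in _REQUIRED_CANONICAL if c not in frame.columns]
    if missing_required:
        raise CohortError(
            f"{path}: required columns {missing_required} not mapped; "
            f"sheet offers candidates {list(unmapped) + present}"
        )
    for column in COHORT_COLUMNS:
        if column not in frame.columns:
            frame[column] = None if column == "surgery" else math.nan
    frame["subject_id"] = frame["subject_id"].astype(str)
    return frame_to_cohort(frame)
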