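"""Landmark-based lamina cribrosa depth (LCD) morphometry.

The depth of the anterior lamina cribrosa surface in a B-scan is measured
against the *BMO reference line* — the segment joining the two Bruch's
membrane opening landmarks, which sits at an angle ``alpha`` to the image
horizontal. The scan-level LCD is the maximum perpendicular distance from
the marked anterior-LC points to that line (the maximally depressed point),
signed so that posterior displacement is positive. The eye-level LCD is the
arithmetic mean over a set of central B-scans, conventionally 12-16 scans
covering up to three quarters of the optic disc.

The implementation rotates each scan by ``-alpha`` so the reference line is
horizontal and reads the depth as the axial offset — algebraically
equivalent to the perpendicular point-to-line distance, and matching the
rotate-then-measure construction used in practice.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .io import AnnotationError, BScanAnnotation, EyeLCDResult, ReferenceLine

__all__ = [
    "ScanLCD",
    "bmo_reference_line",
    "scan_lcd",
    "mean_lcd",
    "select_central_scans",
]

#: Customary range for the number of central scans averaged per eye.
TYPICAL_SCAN_COUNT = (12, 16)


class ScanLCD(NamedTuple):
    """Scan-level LCD with the index of the maximally depressed LC point."""

    lcd_um: float
    point_index: int


def bmo_reference_line(annotation: BScanAnnotation) -> ReferenceLine:
    """Reference line through the two BMO landmarks.

    The angle ``alpha`` is the signed angle of the segment to the horizontal
    in degrees, normalized to (-90, 90] (the line is undirected).
    """
    a, b = annotation.bmo_points
    dx, dy = b - a
    if math.hypot(dx, dy) <= 0:
        raise AnnotationError(
            f"scan {annotation.scan_index}: degenerate BMO line (coincident points)"
        )
    alpha = math.degrees(math.atan2(dy, dx))
    if alpha <= -90.0:
        alpha += 180.0
    elif alpha > 90.0:
        alpha -= 180.0
    return ReferenceLine(point_a=a, point_b=b, alpha=alpha)


def scan_lcd(annotation: BScanAnnotation) -> ScanLCD:
    """Signed LCD of a single B-scan, in micrometres.

    Rotates all landmarks by ``-alpha`` about the first BMO point so the BMO
    line becomes horizontal, then takes the maximum signed axial offset of
    the anterior-LC points. Positive values lie on the posterior side of the
    line; a scan whose LC points all lie anterior yields a negative depth.
    Ties are broken by the lowest point index.

    Because the sign is pinned to the image axial direction, the measure is
    invariant under exactly those rigid motions that keep the reference
    line's inclination in the principal (-90, 90] range — i.e. that
    preserve which image direction is posterior. Rotating a scan upside
    down is not a meaningful operation under this convention.
    """
    bmo_reference_line(annotation)  # validates the BMO geometry
    bmo = annotation.bmo_points.copy()
    lc = annotation.lc_points.copy()
    if not annotation.axial_positive_is_posterior:
        # normalize to the posterior-positive axial convention
        bmo = bmo * np.array([1.0, -1.0])
        lc = lc * np.array([1.0, -1.0])
    dx, dy = bmo[1] - bmo[0]
    theta = math.atan2(dy, dx)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    c, s = math.cos(-theta), math.sin(-theta)
    rot = np.array([[c, -s], [s, c]])
    origin = bmo[0]
    lc_rot = (lc - origin) @ rot.T
    depths = lc_rot[:, 1]
    idx = int(np.argmax(depths))
    return ScanLCD(lcd_um=float(depths[idx]), point_index=idx)


def select_central_scans(n_total: int, k: int, coverage_fraction: float = 0.75) -> list:
    """Indices of ``k`` equidistant scans centred on the volume midline.

    The covered band is the central ``coverage_fraction`` of the index range
    ``[0, n_total - 1]``, restricted to the integer indices inside it; the
    ``k`` positions are spread evenly across that band and rounded to the
    integer grid, halves rounding away from the central scan.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    span = n_total - 1
    lo_f = (1.0 - coverage_fraction) / 2.0 * span
    hi_f = (1.0 + coverage_fraction) / 2.0 * span
    eps = 1e-9
    lo = math.ceil(lo_f - eps)
    hi = math.floor(hi_f + eps)
    if k > hi - lo + 1:
        raise ValueError(
            f"k={k} exceeds the {hi - lo + 1} scans inside the covered band "
            f"[{lo}, {hi}]"
        )
    center = (lo + hi) / 2.0
    if k == 1:
        positions = [center]
    else:
        positions = [lo + j * (hi - lo) / (k - 1) for j in range(k)]
    indices = []
    for pos in positions:
        frac = pos - math.floor(pos)
        if abs(frac - 0.5) < eps:
            # exact half: round away from the central scan
            rounded = math.floor(pos) if pos < center else math.ceil(pos)
        else:
            rounded = round(pos)
        indices.append(int(rounded))
    return indices


def mean_lcd(
    annotations: Iterable[BScanAnnotation],
    scan_indices: Sequence[int] | None = None,
    k: int | None = None,
    coverage_fraction: float = 0.75,
    n_total: int | None = None,
) -> EyeLCDResult:
    """Eye-level mean LCD over a selection of central B-scans.

    The selection is either an explicit ``scan_indices`` list (which
    overrides the policy — in practice scans are chosen where every landmark
    can be placed without doubt), or ``k`` scans picked equidistantly by
    :func:`select_central_scans` within the central ``coverage_fraction`` of
    the volume, or, by default, every annotated scan. A warning is issued
    when the number of scans used falls outside the customary 12-16 band.
    """
    by_index = {}
    for ann in annotations:
        if ann.scan_index in by_index:
            raise AnnotationError(f"duplicate annotation for scan {ann.scan_index}")
        by_index[ann.scan_index] = ann
    if not by_index:
        raise AnnotationError("no annotations supplied")
    if scan_indices is not None:
        selected = list(scan_indices)
    elif k is not None:
        total = n_total if n_total is not None else max(by_index) + 1
        selected = select_central_scans(total, k, coverage_fraction)
    else:
        selected = sorted(by_index)
    if not selected:
        raise AnnotationError("empty scan selection")
    missing = [i for i in selected if i not in by_index]
    if missing:
        raise AnnotationError(f"selected scans without annotations: {missing}")
    per_scan = tuple(
        (int(i), scan_lcd(by_index[i]).lcd_um) for i in sorted(selected)
    )
    n = len(per_scan)
    if not TYPICAL_SCAN_COUNT[0] <= n <= TYPICAL_SCAN_COUNT[1]:
        warnings.warn(
            f"mean LCD over {n} scans; {TYPICAL_SCAN_COUNT[0]}-"
            f"{TYPICAL_SCAN_COUNT[1]} central scans are customary",
            stacklevel=2,
        )
    values = [v for _, v in per_scan]
    return EyeLCDResult(
        per_scan_lcd=per_scan,
        mean_lcd=float(np.mean(values)),
        n_scans_used=n,
    )
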