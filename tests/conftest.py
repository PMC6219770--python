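import numpy as np
import pytest

from lamina.io import BScanAnnotation
from lamina.simulate import (
    CohortGeneratorConfig,
    fixture_case_reports,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic draw of the default 29-subject synthetic cohort."""
    cohort, truth = generate_cohort(CohortGeneratorConfig(), seed=11)
    return cohort, truth


@pytest.fixture(scope="session")
def case_series():
    """The two published worked-example eyes."""
    return fixture_case_reports()


def random_annotation(rng: np.random.Generator,
                      scan_index: int | None = None,
                      axial_positive_is_posterior: bool | None = None
                      ) -> BScanAnnotation:
    """A random but valid B-scan annotation (shared across test modules)."""
    while True:
        bmo = rng.uniform(-2000, 2000, (2, 2))
        if np.hypot(*(bmo[1] - bmo[0])) > 1.0:
            break
    n_lc = int(rng.integers(1, 9))
    lc = rng.uniform(-2000, 2000, (n_lc, 2))
    return BScanAnnotation(
        scan_index=int(rng.integers(0, 100)) if scan_index is None else scan_index,
        bmo_points=bmo,
        lc_points=lc,
        axial_positive_is_posterior=(
            bool(rng.integers(0, 2)) if axial_positive_is_posterior is None
            else axial_positive_is_posterior),
    )


def orientation_preserving_rotation(annotation: BScanAnnotation,
                                    rng: np.random.Generator) -> float:
    """A random rotation (degrees) that keeps the BMO line's inclination in
    the principal (-90, 90) range, i.e. preserves which image direction is
    posterior. A signed depth pinned to the image axial axis is only
    well-defined — and hence only invariant — under such motions."""
    from lamina.geometry import bmo_reference_line

    alpha = bmo_reference_line(annotation).alpha
    return float(rng.uniform(-89.9 - alpha, 89.9 - alpha))


def signed_point_line_distance_oracle(annotation: BScanAnnotation) -> float:
    """Independent LCD oracle: max signed distance |ax+by+c|/sqrt(a^2+b^2).

    The implicit line through the BMO points is a*x + b*y + c = 0 with
    (a, b) the segment normal; the sign comes from a half-plane test with
    posterior (larger axial coordinate, after normalizing the axial
    convention) positive.
    """
    bmo = annotation.bmo_points.astype(float)
    lc = annotation.lc_points.astype(float)
    if not annotation.axial_positive_is_posterior:
        bmo = bmo * np.array([1.0, -1.0])
        lc = lc * np.array([1.0, -1.0])
    (x1, y1), (x2, y2) = bmo
    a, b = y2 - y1, -(x2 - x1)
    c = -(a * x1 + b * y1)
    norm = np.hypot(a, b)
    signed = (a * lc[:, 0] + b * lc[:, 1] + c) / norm
    # orient so that a point displaced posteriorly (larger y) is positive
    probe = (a * x1 + b * (y1 + 1.0) + c) / norm
    if probe < 0:
        signed = -signed
    return float(signed.max())
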