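"""Tolerance-descent sweeps and closed-form geometric sensitivity.

The detection threshold of a comparison system is measured by starting the
tolerance above the induced error and lowering it in fixed increments
(0.1 mm for the distance test, 0.1% for the dose test) until failing
pixels first appear in the colour map; the last tolerance reached is the
detection threshold, and the absolute difference between it and the
induced error is the system's sensitivity for that error type.

Because equality passes, a noise-free error of magnitude d is first
flagged at the largest grid point strictly below d, so the noise-free
sensitivity of this synthetic system is bounded by the sweep step.

The module also carries the small closed-form geometry results used to
translate collimator rotations and vertical couch errors into apparent
edge displacements on the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .comparison import Category, ComparisonCriteria, dd_map, dta_map
from .dose_image import DoseImage

__all__ = [
    "SweepResult",
    "sweep_dta",
    "sweep_dd",
    "collimator_edge_deviation",
    "vertical_couch_apparent_shift",
    "oblique_couch_projection",
]


@dataclass
class SweepResult:
    """Outcome of one tolerance descent.

    ``detection_threshold`` is the largest tolerance on the descending grid
    with at least ``min_fail_pixels`` failing pixels, or None when the
    descent reached its floor without failures ("not detected").
    ``sensitivity`` is |induced_magnitude - detection_threshold| when both
    are known.  ``trace`` lists (tolerance, n_failing_pixels) for every
    grid point visited.
    """

    mode: str
    detection_threshold: float | None
    induced_magnitude: float | None
    trace: list[tuple[float, int]] = field(default_factory=list)
    step: float = 0.1

    @property
    def detected(self) -> bool:
        return self.detection_threshold is not None

    @property
    def sensitivity(self) -> float | None:
        if self.detection_threshold is None or self.induced_magnitude is None:
            return None
        return abs(self.induced_magnitude - self.detection_threshold)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "detection_threshold": self.detection_threshold,
            "induced_magnitude": self.induced_magnitude,
            "sensitivity": self.sensitivity,
            "step": self.step,
            "trace": [[t, n] for t, n in self.trace],
        }


def _descend(
    metric: np.ndarray,
    evaluated: np.ndarray,
    start: float,
    step: float,
    mode: str,
    induced: float | None,
    min_fail_pixels: int,
    fail_margin: float = 0.0,
) -> SweepResult:
    """Shared descent: count metric > tolerance (+ any numerical allowance)
    among evaluated pixels on a grid start, start - step, ... down to (and
    including) the floor step."""
    if start <= 0 or step <= 0:
        raise ValueError("start and step must be positive")
    tolerances = []
    t = start
    while t > step / 2.0:
        tolerances.append(round(t, 10))
        t -= step
    trace: list[tuple[float, int]] = []
    detection = None
    for tol in tolerances:
        n_fail = int(np.sum(evaluated & (metric > tol + fail_margin)))
        trace.append((tol, n_fail))
        if n_fail >= min_fail_pixels:
            detection = tol
            break
    return SweepResult(mode, detection, induced, trace, step)


def sweep_dta(
    ref: DoseImage,
    eval_img: DoseImage,
    start_mm: float,
    step_mm: float = 0.1,
    threshold_percent: float = 10.0,
    induced_mm: float | None = None,
    min_fail_pixels: int = 1,
    distance_atol_mm: float | None = None,
) -> SweepResult:
    """Descend the DTA tolerance until failing pixels appear.

    The per-pixel DTA map does not depend on the tolerance, only the
    pass/fail classification does, so the map is computed once at the
    search radius implied by the starting tolerance and re-thresholded down
    the grid — identical, tolerance for tolerance, to re-running the
    dta_only comparison.
    """
    criteria = ComparisonCriteria(
        dd_tol_percent=0.0,
        dta_tol_mm=start_mm,
        mode="dta_only",
        threshold_percent=threshold_percent,
        distance_atol_mm=distance_atol_mm,
    )
    result = dta_map(eval_img, ref, criteria)
    evaluated = result.category_map != Category.EXCLUDED
    margin = criteria.resolve_distance_atol_mm(ref.pixel_pitch_mm)
    return _descend(
        result.metric_map,
        evaluated,
        start_mm,
        step_mm,
        "dta",
        induced_mm,
        min_fail_pixels,
        fail_margin=margin,
    )


def sweep_dd(
    ref: DoseImage,
    eval_img: DoseImage,
    start_percent: float,
    step_percent: float = 0.1,
    threshold_percent: float = 10.0,
    induced_percent: float | None = None,
    min_fail_pixels: int = 1,
) -> SweepResult:
    """Descend the dose-difference tolerance until hot/cold pixels appear."""
    criteria = ComparisonCriteria(
        dd_tol_percent=start_percent,
        dta_tol_mm=0.0,
        mode="dd_only",
        threshold_percent=threshold_percent,
    )
    result = dd_map(eval_img, ref, criteria)
    evaluated = result.category_map != Category.EXCLUDED
    return _descend(
        np.abs(result.metric_map),
        evaluated,
        start_percent,
        step_percent,
        "dd",
        induced_percent,
        min_fail_pixels,
        fail_margin=1e-9,
    )


# ---------------------------------------------------------------------------
# closed-form geometry


def collimator_edge_deviation(field_side_mm: float, theta_deg: float) -> float:
    """Maximum apparent jaw-position deviation caused by rotating a square
    field of the given side about its centre: half the field side times the
    tangent of the angle."""
    if field_side_mm <= 0:
        raise ValueError("field_side_mm must be positive")
    if abs(theta_deg) >= 90.0:
        raise ValueError("rotation angle must satisfy |theta| < 90 degrees")
    return field_side_mm / 2.0 * math.tan(math.radians(theta_deg))


def vertical_couch_apparent_shift(
    region_diameter_mm: float, vertical_error_mm: float, sad_mm: float = 1000.0
) -> dict[str, float]:
    """Apparent size change of a centred dose region caused by a vertical
    couch (patient height) error, to first order in v/SAD.

    Moving the patient closer to the source by v magnifies a region of
    diameter D by a factor SAD / (SAD - v) ~ 1 + v/SAD, so the apparent
    diameter changes by D * v / SAD and each edge shifts laterally by half
    that — the signature a purely vertical error leaves on the image.
    """
    if region_diameter_mm <= 0 or sad_mm <= 0:
        raise ValueError("diameter and SAD must be positive")
    diameter_change = region_diameter_mm * vertical_error_mm / sad_mm
    return {
        "diameter_change_mm": diameter_change,
        "edge_shift_mm": diameter_change / 2.0,
    }


def oblique_couch_projection(vertical_error_mm: float, beam_angle_deg: float) -> float:
    """In-image lateral component of a vertical couch error for a beam at
    the given angle from vertical: v * sin(angle).  A lateral beam (90
    degrees) sees the whole error; a vertical beam sees none."""
    if not (0.0 <= beam_angle_deg <= 90.0):
        raise ValueError("beam angle must lie in [0, 90] degrees")
    return vertical_error_mm * math.sin(math.radians(beam_angle_deg))
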