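"""Per-pixel comparison of a fraction image against its baseline.

Three comparison tests are provided, mirroring daily transit-dosimetry QA
practice:

``dd``    dose difference at the same pixel, in percent of the baseline
          maximum (red = too hot, blue = too cold);
``dta``   distance-to-agreement: the distance from a pixel to the nearest
          point of the baseline carrying the same dose (orange = too far);
``gamma`` the combined index: gamma(p) = min over q of
          sqrt(|p - q|^2 / dta_tol^2 + (D_eval(p) - D_ref(q))^2 / dd_abs^2),
          a pixel passing when gamma <= 1.

Equality always passes (|DD| = tol, DTA = tol, gamma = 1 are passes); this
boundary convention is what makes the tolerance-descent sweeps land exactly
one grid step below a noise-free induced error.  Pixels whose baseline dose
falls below the dose threshold are excluded from evaluation and from the
passing rate.  Both DTA and gamma search the baseline continuously
(bilinear sub-pixel interpolation); the search is capped at a radius
``max(3 * dta_tol, 5 mm)`` beyond which "no agreement" means failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from .dose_image import DoseImage

__all__ = [
    "Category",
    "ComparisonCriteria",
    "ComparisonResult",
    "dd_map",
    "dta_map",
    "gamma_map",
    "compare",
    "passing_rate",
    "render_category_map",
]

#: Relative (to the normalization dose) tolerance for "same dose" when
#: matching levels in the DTA search.
LEVEL_MATCH_RTOL = 1e-9


class Category(IntEnum):
    """Per-pixel classification, with the colour semantics of QA colour maps
    (green pass, orange geometric failure, red hot, blue cold, grey
    excluded)."""

    PASS = 0
    FAIL_HOT = 1
    FAIL_COLD = 2
    FAIL_GEOMETRIC = 3
    EXCLUDED = 4


_PALETTE = {
    Category.PASS: (0, 160, 0),
    Category.FAIL_GEOMETRIC: (255, 140, 0),
    Category.FAIL_HOT: (220, 0, 0),
    Category.FAIL_COLD: (0, 0, 220),
    Category.EXCLUDED: (180, 180, 180),
}


@dataclass(frozen=True)
class ComparisonCriteria:
    """Tolerances and evaluation mode for one comparison.

    ``dd_tol_percent`` is a percent of the normalization dose (the baseline
    maximum); ``dta_tol_mm`` a distance; ``threshold_percent`` excludes
    pixels whose baseline dose is below that percent of the normalization
    dose.  ``mode`` selects a pure dose test, a pure distance test, or the
    combined gamma index.
    """

    dd_tol_percent: float = 2.0
    dta_tol_mm: float = 2.0
    mode: str = "gamma"  # "dd_only" | "dta_only" | "gamma"
    threshold_percent: float = 10.0
    normalization: str = "global_max"
    search_radius_mm: float | None = None
    refine_step_mm: float | None = None
    distance_atol_mm: float | None = None
    dose_resolution: float = 2.0 ** -16

    def __post_init__(self) -> None:
        if self.mode not in ("dd_only", "dta_only", "gamma"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dd_tol_percent < 0 or self.dta_tol_mm < 0:
            raise ValueError("tolerances must be >= 0")
        if self.mode == "gamma" and (self.dd_tol_percent == 0 or self.dta_tol_mm == 0):
            raise ValueError(
                "gamma mode needs both tolerances > 0; use mode='dd_only' or "
                "'dta_only' for a single-criterion test"
            )
        if not (0 <= self.threshold_percent < 100):
            raise ValueError("threshold_percent must be in [0, 100)")
        if self.normalization != "global_max":
            raise ValueError("only global_max normalization is implemented")

    @property
    def radius_mm(self) -> float:
        if self.search_radius_mm is not None:
            return self.search_radius_mm
        return max(3.0 * self.dta_tol_mm, 5.0)

    @property
    def step_mm(self) -> float:
        """Sub-pixel refinement step for the DTA / gamma search."""
        if self.refine_step_mm is not None:
            return self.refine_step_mm
        return max(0.1 * self.dta_tol_mm, 1e-3)

    def resolve_distance_atol_mm(self, pitch_mm: float) -> float:
        """Discretization allowance of the sub-pixel distance search.

        The search runs against the bilinearly interpolated baseline, whose
        iso-level lines sit within O(pitch^2 * curvature) of the underlying
        continuous distribution's; a distance flag therefore only fires when
        the tolerance is exceeded by more than this allowance (default
        pitch/8), making geometric failures conservative against
        interpolation artefacts.
        """
        if self.distance_atol_mm is not None:
            return self.distance_atol_mm
        return pitch_mm / 8.0


@dataclass
class ComparisonResult:
    """Per-pixel metric map, classification and summary statistics."""

    metric_map: np.ndarray
    category_map: np.ndarray
    criteria: ComparisonCriteria
    normalization_dose: float
    max_abs_dd: float
    max_dta: float

    @property
    def n_evaluated(self) -> int:
        return int(np.sum(self.category_map != Category.EXCLUDED))

    @property
    def n_pass(self) -> int:
        return int(np.sum(self.category_map == Category.PASS))

    @property
    def n_fail(self) -> int:
        return self.n_evaluated - self.n_pass

    @property
    def passing_rate(self) -> float:
        """Percent of evaluated (non-excluded) pixels that pass."""
        n_eval = self.n_evaluated
        if n_eval == 0:
            raise ValueError("passing rate undefined: zero evaluated pixels")
        return 100.0 * self.n_pass / n_eval


def passing_rate(result: ComparisonResult) -> float:
    return result.passing_rate


def _check_pair(eval_img: DoseImage, ref_img: DoseImage) -> float:
    if not ref_img.same_grid(eval_img):
        raise ValueError(
            "eval and ref must share grid (shape, pitch, plane, origin); "
            "resample first"
        )
    norm = float(ref_img.values.max())
    if norm <= 0:
        raise ValueError("all-zero baseline: normalization dose undefined")
    return norm


# ---------------------------------------------------------------------------
# dose difference


def dd_map(eval_img: DoseImage, ref_img: DoseImage, criteria: ComparisonCriteria) -> ComparisonResult:
    """Signed dose difference, percent of the baseline maximum."""
    norm = _check_pair(eval_img, ref_img)
    dd = 100.0 * (eval_img.values - ref_img.values) / norm
    evaluated = ref_img.values >= criteria.threshold_percent / 100.0 * norm

    cat = np.full(dd.shape, Category.EXCLUDED, dtype=np.int8)
    # Tiny absolute guard so exact-ratio scalings sit on the pass side of
    # the boundary regardless of floating-point rounding direction.
    tol = criteria.dd_tol_percent + 1e-9
    cat[evaluated] = Category.PASS
    cat[evaluated & (dd > tol)] = Category.FAIL_HOT
    cat[evaluated & (dd < -tol)] = Category.FAIL_COLD
    max_abs_dd = float(np.abs(dd[evaluated]).max()) if evaluated.any() else 0.0
    return ComparisonResult(dd, cat, criteria, norm, max_abs_dd, 0.0)


# ---------------------------------------------------------------------------
# distance to agreement


def _dist_to_polylines(
    point: np.ndarray, contours: list[np.ndarray]
) -> tuple[float, np.ndarray | None]:
    """Min distance (pixel units) from a point to marching-squares
    polylines, and the nearest polyline point."""
    best = np.inf
    best_q: np.ndarray | None = None
    for poly in contours:
        if len(poly) == 1:
            d = float(np.hypot(*(poly[0] - point)))
            if d < best:
                best, best_q = d, poly[0]
            continue
        a = poly[:-1]
        b = poly[1:]
        ab = b - a
        ap = point - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", ap, ab) / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((proj - point) ** 2, axis=1)
        k = int(np.argmin(d2))
        d = float(np.sqrt(d2[k]))
        if d < best:
            best, best_q = d, proj[k]
    return best, best_q


def _bilinear_with_grad(win: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Bilinear value and gradient (per pixel unit) of a window at q."""
    nr, nc = win.shape
    i = int(np.clip(np.floor(q[0]), 0, nr - 2))
    j = int(np.clip(np.floor(q[1]), 0, nc - 2))
    fr = q[0] - i
    fc = q[1] - j
    f00, f01 = win[i, j], win[i, j + 1]
    f10, f11 = win[i + 1, j], win[i + 1, j + 1]
    f = f00 * (1 - fr) * (1 - fc) + f01 * (1 - fr) * fc + f10 * fr * (1 - fc) + f11 * fr * fc
    dfr = (f10 - f00) * (1 - fc) + (f11 - f01) * fc
    dfc = (f01 - f00) * (1 - fr) + (f11 - f10) * fr
    return f, dfr, dfc


def _polish_on_level(
    win: np.ndarray, point: np.ndarray, q0: np.ndarray, level: float, scale: float
) -> float:
    """Refine a nearest-level-point estimate on the bilinear surface.

    Marching squares joins exact cell-edge crossings with straight chords;
    within a cell the true bilinear iso-line is a hyperbola arc, so the
    chord distance errs for tightly curved contours.  Alternate Newton
    projection onto the level set with a tangential slide towards the
    query point; the result is a genuine point of the interpolated level
    set, whose distance replaces the chord distance when smaller.
    """
    q = q0.astype(float).copy()
    nr, nc = win.shape
    for _ in range(12):
        f, gr, gc = _bilinear_with_grad(win, q)
        g2 = gr * gr + gc * gc
        if g2 < 1e-30:
            break
        step_r = (level - f) / g2 * gr
        step_c = (level - f) / g2 * gc
        norm_t = math.sqrt(g2)
        tr, tc = -gc / norm_t, gr / norm_t
        slide = (point[0] - q[0]) * tr + (point[1] - q[1]) * tc
        slide = float(np.clip(slide, -1.0, 1.0))
        q[0] = np.clip(q[0] + step_r + slide * tr, 0.0, nr - 1.0)
        q[1] = np.clip(q[1] + step_c + slide * tc, 0.0, nc - 1.0)
    f, _, _ = _bilinear_with_grad(win, q)
    if abs(f - level) <= 1e-7 * scale:
        return float(np.hypot(q[0] - point[0], q[1] - point[1]))
    return np.inf


def dta_map(eval_img: DoseImage, ref_img: DoseImage, criteria: ComparisonCriteria) -> ComparisonResult:
    """Distance-to-agreement of each evaluated pixel.

    For pixel p with dose v, DTA(p) is the distance to the nearest point of
    the (bilinearly interpolated) baseline carrying dose v.  The iso-level
    line through the baseline is extracted sub-pixel with marching squares
    on a window of the capped search radius; a pixel whose dose value does
    not occur in the baseline within the radius gets DTA = +inf and fails.
    Pixels whose dose already agrees in place (within 1e-9 of the
    normalization dose) have DTA = 0 exactly.
    """
    norm = _check_pair(eval_img, ref_img)
    pitch = ref_img.pixel_pitch_mm
    evaluated = ref_img.values >= criteria.threshold_percent / 100.0 * norm

    dta = np.zeros(ref_img.values.shape, dtype=float)
    tol_floor = max(criteria.dose_resolution, LEVEL_MATCH_RTOL) * norm
    mismatch = evaluated & (np.abs(eval_img.values - ref_img.values) > tol_floor)
    radius_px = criteria.radius_mm / pitch
    w = int(math.ceil(radius_px)) + 1
    ref = ref_img.values
    ny, nx = ref.shape
    # "Same dose" tolerance: the sampled baseline represents its continuous
    # distribution only to within the bilinear interpolation error, bounded
    # per node by one-eighth of the local second differences; below that
    # (or below the dose-resolution floor) two dose values are
    # indistinguishable.  Without this, levels grazing smooth extrema
    # (e.g. the bottom of a couch strip dip, or a saturated plateau) would
    # spuriously not exist anywhere in the baseline.
    if np.any(mismatch):
        d2r = np.pad(np.abs(np.diff(ref, n=2, axis=0)), ((1, 1), (0, 0)), mode="edge")
        d2c = np.pad(np.abs(np.diff(ref, n=2, axis=1)), ((0, 0), (1, 1)), mode="edge")
        node_tol = np.maximum(
            (
                ndimage.maximum_filter(d2r, size=3, mode="nearest")
                + ndimage.maximum_filter(d2c, size=3, mode="nearest")
            )
            / 8.0,
            tol_floor,
        )
    for r0, c0 in zip(*np.nonzero(mismatch)):
        level = eval_img.values[r0, c0]
        rlo, rhi = max(0, r0 - w), min(ny, r0 + w + 1)
        clo, chi = max(0, c0 - w), min(nx, c0 + w + 1)
        window = ref[rlo:rhi, clo:chi]
        tol_win = node_tol[rlo:rhi, clo:chi]
        point = np.array([r0 - rlo, c0 - clo], dtype=float)
        d_px = np.inf
        if window.min() <= level <= window.max():
            contours = measure.find_contours(window, level)
            if contours:
                d_px, q0 = _dist_to_polylines(point, contours)
                if q0 is not None:
                    d_polished = _polish_on_level(window, point, q0, level, norm)
                    if np.isfinite(d_polished):
                        d_px = d_polished
        # Nodes whose value is within their own interpolation-error bound
        # of the level are agreement points too; marching squares alone
        # misses levels that graze grid extrema.
        near = np.abs(window - level) <= tol_win
        if near.any():
            nr, nc = np.nonzero(near)
            d_px = min(d_px, float(np.sqrt(((nr - point[0]) ** 2 + (nc - point[1]) ** 2).min())))
        d_mm = d_px * pitch
        dta[r0, c0] = d_mm if d_mm <= criteria.radius_mm else np.inf

    tol = criteria.dta_tol_mm + criteria.resolve_distance_atol_mm(pitch)
    cat = np.full(dta.shape, Category.EXCLUDED, dtype=np.int8)
    cat[evaluated] = Category.PASS
    cat[evaluated & (dta > tol)] = Category.FAIL_GEOMETRIC
    finite = evaluated & np.isfinite(dta)
    max_dta = float(dta[finite].max()) if finite.any() else 0.0
    if bool(np.any(evaluated & ~np.isfinite(dta))):
        max_dta = math.inf
    return ComparisonResult(dta, cat, criteria, norm, 0.0, max_dta)


# ---------------------------------------------------------------------------
# gamma index


def _disk_offsets(radius_mm: float, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """All (dy, dx) mm offsets on a step grid within the radius, sorted by
    distance; returns (offsets[n,2], r_mm[n])."""
    n = int(math.floor(radius_mm / step_mm))
    axis = np.arange(-n, n + 1) * step_mm
    dy, dx = np.meshgrid(axis, axis, indexing="ij")
    r = np.hypot(dy, dx).ravel()
    keep = r <= radius_mm + 1e-12
    offsets = np.column_stack([dy.ravel()[keep], dx.ravel()[keep]])
    r = r[keep]
    order = np.argsort(r, kind="stable")
    return offsets[order], r[order]


def gamma_map(eval_img: DoseImage, ref_img: DoseImage, criteria: ComparisonCriteria) -> ComparisonResult:
    """Global-normalization 2D gamma index of eval against ref.

    The minimization over baseline points runs on a sub-pixel refinement
    grid (step <= 0.1 * dta_tol) within the capped search radius, with the
    baseline interpolated bilinearly; offsets are visited in order of
    increasing distance so the search stops as soon as the distance term
    alone exceeds the best gamma found for every remaining pixel.
    """
    if criteria.dd_tol_percent <= 0 or criteria.dta_tol_mm <= 0:
        raise ValueError("gamma mode requires both tolerances > 0")
    norm = _check_pair(eval_img, ref_img)
    pitch = ref_img.pixel_pitch_mm
    evaluated = ref_img.values >= criteria.threshold_percent / 100.0 * norm
    dd_abs = criteria.dd_tol_percent / 100.0 * norm
    dta_tol = criteria.dta_tol_mm

    gamma = np.zeros(ref_img.values.shape, dtype=float)
    active_mask = evaluated & (
        np.abs(eval_img.values - ref_img.values) > LEVEL_MATCH_RTOL * norm
    )
    rows, cols = np.nonzero(active_mask)
    if rows.size:
        doses = eval_img.values[rows, cols]
        offsets, r_mm = _disk_offsets(criteria.radius_mm, criteria.step_mm)
        # Seed with the in-place dose term (offset 0 is first in the list).
        g2 = np.full(rows.size, np.inf)
        active = np.arange(rows.size)
        i = 0
        noff = offsets.shape[0]
        while i < noff and active.size:
            r = r_mm[i]
            dist_term = (r / dta_tol) ** 2
            # Retire pixels whose current best cannot be improved at this
            # or any larger radius.
            keep = g2[active] > dist_term
            active = active[keep]
            if not active.size:
                break
            j = i
            while j < noff and r_mm[j] <= r + 1e-12:
                j += 1
            for k in range(i, j):
                dy, dx = offsets[k]
                rr = rows[active] + dy / pitch
                cc = cols[active] + dx / pitch
                ref_q = ndimage.map_coordinates(
                    ref_img.values, [rr, cc], order=1, mode="constant", cval=np.nan
                )
                cand = dist_term + ((doses[active] - ref_q) / dd_abs) ** 2
                cand = np.where(np.isnan(cand), np.inf, cand)
                g2[active] = np.minimum(g2[active], cand)
            i = j
        gamma[rows, cols] = np.sqrt(g2)

    cat = np.full(gamma.shape, Category.EXCLUDED, dtype=np.int8)
    cat[evaluated] = Category.PASS
    cat[evaluated & (gamma > 1.0)] = Category.FAIL_GEOMETRIC
    dd = 100.0 * (eval_img.values - ref_img.values) / norm
    max_abs_dd = float(np.abs(dd[evaluated]).max()) if evaluated.any() else 0.0
    return ComparisonResult(gamma, cat, criteria, norm, max_abs_dd, 0.0)


def compare(eval_img: DoseImage, ref_img: DoseImage, criteria: ComparisonCriteria) -> ComparisonResult:
    """Dispatch on ``criteria.mode``."""
    if criteria.mode == "dd_only":
        return dd_map(eval_img, ref_img, criteria)
    if criteria.mode == "dta_only":
        return dta_map(eval_img, ref_img, criteria)
    return gamma_map(eval_img, ref_img, criteria)


def render_category_map(result: ComparisonResult, path: str) -> None:
    """Write the categorical pass/fail map as a PNG with the conventional
    palette: green pass, orange geometric fail, red hot, blue cold, grey
    excluded."""
    cat = result.category_map
    rgb = np.zeros(cat.shape + (3,), dtype=np.uint8)
    for category, colour in _PALETTE.items():
        rgb[cat == category] = colour
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
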