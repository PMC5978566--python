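"""Synthetic integrated transit EPID images.

This module stands in for a linac + portal imager: it renders the
integrated exit-dose image of one field as

    dose(p) = MU * output_scale * A_sigma(p) * T_scene(p) * (1 + eps_p)

where ``A_sigma`` is the collimator aperture (jaws intersected with the
MLC, rotated by the collimator angle) convolved with an isotropic Gaussian
penumbra, ``T_scene`` multiplies the transmissions of everything in the
beam path (water-equivalent slab, couch strip pattern, couch rail band,
heterogeneous head phantom) and ``eps_p`` is i.i.d. multiplicative Gaussian
noise.  Every edge position is kept in continuous physical coordinates, so
induced shifts are exact and sub-pixel; isocenter-plane coordinates are
magnified onto the detector by sdd/sad.

The error-function edge profile is the exact convolution of the aperture
indicator with the Gaussian, which pins the 50% isodose line onto the
projected geometric edge independently of the penumbra width — the property
the distance-to-agreement experiments rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .dose_image import DEFAULT_PITCH_MM, DoseImage, PlaneGeometry

__all__ = [
    "BeamConfig",
    "MLCBank",
    "PhantomScene",
    "SlabPhantom",
    "CouchTop",
    "RailState",
    "HeadPhantom",
    "NoiseModel",
    "ConfigurationError",
    "millennium120",
    "open_field",
    "project_aperture",
    "render_image",
    "inject_error",
    "make_head_phantom",
    "ERROR_SCENARIOS",
]

#: Default water-equivalent narrow-beam attenuation coefficient for a 6 MV
#: beam, per cm of water.
DEFAULT_MU_EFF = 0.0475

#: Default Gaussian penumbra width at the detector plane, mm.
DEFAULT_PENUMBRA_SIGMA_MM = 1.5


class ConfigurationError(ValueError):
    """An error-injection or scenario configuration is invalid."""


# ---------------------------------------------------------------------------
# machine state


@dataclass
class MLCBank:
    """A multileaf collimator bank pair (left/right tips per leaf pair).

    ``leaf_boundaries_mm`` are the 61 ordered cross-plane (y) boundaries at
    the isocenter plane defining 60 leaf pairs; ``left_positions_mm`` and
    ``right_positions_mm`` are the leaf-tip x positions at isocenter.  A
    closed pair has ``left == right``.
    """

    leaf_boundaries_mm: np.ndarray
    left_positions_mm: np.ndarray
    right_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        self.leaf_boundaries_mm = np.asarray(self.leaf_boundaries_mm, dtype=float)
        self.left_positions_mm = np.asarray(self.left_positions_mm, dtype=float)
        self.right_positions_mm = np.asarray(self.right_positions_mm, dtype=float)
        nb = self.leaf_boundaries_mm.size
        if nb < 2 or np.any(np.diff(self.leaf_boundaries_mm) <= 0):
            raise ValueError("leaf boundaries must be strictly increasing")
        npairs = nb - 1
        if self.left_positions_mm.size != npairs or self.right_positions_mm.size != npairs:
            raise ValueError("need one left and one right position per leaf pair")
        if np.any(self.left_positions_mm > self.right_positions_mm + 1e-12):
            raise ValueError("left leaf positions must not exceed right positions")

    @property
    def n_pairs(self) -> int:
        return self.leaf_boundaries_mm.size - 1

    def copy(self) -> "MLCBank":
        return MLCBank(
            self.leaf_boundaries_mm.copy(),
            self.left_positions_mm.copy(),
            self.right_positions_mm.copy(),
        )


def millennium120(
    left_mm: float | Sequence[float] = 0.0,
    right_mm: float | Sequence[float] = 0.0,
) -> MLCBank:
    """A 120-leaf MLC: 60 pairs, outer 10 per side 10 mm wide, central 40
    pairs 5 mm wide at isocenter (the vendor's standard layout)."""
    widths = np.concatenate([np.full(10, 10.0), np.full(40, 5.0), np.full(10, 10.0)])
    boundaries = np.concatenate([[-200.0], -200.0 + np.cumsum(widths)])
    left = np.broadcast_to(np.asarray(left_mm, dtype=float), (60,)).copy()
    right = np.broadcast_to(np.asarray(right_mm, dtype=float), (60,)).copy()
    return MLCBank(boundaries, left, right)


@dataclass
class BeamConfig:
    """Machine state for one field.

    ``jaws_mm`` holds the retraction of each jaw (X1, X2, Y1, Y2) from the
    central axis at the isocenter plane, so a symmetric 10 cm x 10 cm field
    is ``(50, 50, 50, 50)``.  Increasing a value opens that side of the
    field.  The simulator is planar; ``gantry_label`` only selects which
    scene elements intersect the beam.
    """

    jaws_mm: tuple[float, float, float, float] = (50.0, 50.0, 50.0, 50.0)
    mlc: MLCBank | None = None
    collimator_deg: float = 0.0
    mu: float = 100.0
    output_scale: float = 1.0
    gantry_label: str = "G0"

    def __post_init__(self) -> None:
        if any(j <= 0 for j in self.jaws_mm):
            raise ValueError("jaw openings must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.output_scale <= 0:
            raise ValueError("output_scale must be positive")

    def copy(self) -> "BeamConfig":
        return BeamConfig(
            tuple(self.jaws_mm),
            self.mlc.copy() if self.mlc is not None else None,
            self.collimator_deg,
            self.mu,
            self.output_scale,
            self.gantry_label,
        )


def open_field(x_cm: float, y_cm: float, mu: float = 100.0) -> BeamConfig:
    """Symmetric open field of the given isocenter-plane size."""
    return BeamConfig(jaws_mm=(x_cm * 5.0, x_cm * 5.0, y_cm * 5.0, y_cm * 5.0), mu=mu)


# ---------------------------------------------------------------------------
# scene


@dataclass
class SlabPhantom:
    thickness_cm: float = 10.0
    mu_eff_per_cm: float = DEFAULT_MU_EFF

    def copy(self) -> "SlabPhantom":
        return SlabPhantom(self.thickness_cm, self.mu_eff_per_cm)


@dataclass
class CouchTop:
    """Carbon-fibre strip pattern of a couch top, at the isocenter plane."""

    strip_width_mm: float = 5.0
    strip_pitch_mm: float = 30.0
    strip_transmission: float = 0.97
    lateral_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.strip_transmission <= 1):
            raise ValueError("strip_transmission must be in (0, 1]")
        if self.strip_width_mm <= 0 or self.strip_pitch_mm <= 0:
            raise ValueError("strip width and pitch must be positive")

    def copy(self) -> "CouchTop":
        return CouchTop(
            self.strip_width_mm,
            self.strip_pitch_mm,
            self.strip_transmission,
            self.lateral_offset_mm,
        )


@dataclass
class RailState:
    """A movable couch rail: an attenuating band when moved into the beam."""

    position: str = "out"  # "in" | "out"
    band_width_mm: float = 30.0
    band_transmission: float = 0.92
    band_center_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.position not in ("in", "out"):
            raise ValueError("rail position must be 'in' or 'out'")
        if not (0 < self.band_transmission <= 1):
            raise ValueError("band_transmission must be in (0, 1]")
        if self.band_width_mm <= 0:
            raise ValueError("band_width_mm must be positive")

    def copy(self) -> "RailState":
        return RailState(
            self.position, self.band_width_mm, self.band_transmission, self.band_center_mm
        )


@dataclass
class HeadPhantom:
    """Heterogeneous head: water-equivalent path length (cm) over the
    isocenter-plane field of view, plus a rigid in-plane pose.

    ``attenuation_map`` is sampled on a regular grid of pitch
    ``map_pitch_mm`` centred on the beam axis; the pose (lateral x shift,
    longitudinal y shift, roll) transforms the map rigidly.  The roll pivot
    sits at ``(pivot_x_mm, pivot_y_mm)``, by default 10 cm from the beam
    axis on the support side: a phantom on a leveling plate rotates about its support, so
    a roll displaces the anatomy laterally as well as angularly — which is
    why small roll errors leave a stronger image signature than equally
    small translations.
    """

    attenuation_map: np.ndarray
    map_pitch_mm: float = 0.5
    lateral_shift_mm: float = 0.0
    longitudinal_shift_mm: float = 0.0
    roll_deg: float = 0.0
    pivot_x_mm: float = 0.0
    pivot_y_mm: float = 100.0

    def __post_init__(self) -> None:
        self.attenuation_map = np.asarray(self.attenuation_map, dtype=float)
        if np.any(self.attenuation_map < 0):
            raise ValueError("path lengths must be >= 0")
        if self.map_pitch_mm <= 0:
            raise ValueError("map_pitch_mm must be positive")

    def copy(self) -> "HeadPhantom":
        return HeadPhantom(
            self.attenuation_map.copy(),
            self.map_pitch_mm,
            self.lateral_shift_mm,
            self.longitudinal_shift_mm,
            self.roll_deg,
            self.pivot_x_mm,
            self.pivot_y_mm,
        )

    def path_length_cm(self, x_iso_mm: np.ndarray, y_iso_mm: np.ndarray) -> np.ndarray:
        """Water-equivalent path at isocenter-plane points, pose applied."""
        th = math.radians(self.roll_deg)
        xs = np.asarray(x_iso_mm, dtype=float) - self.lateral_shift_mm - self.pivot_x_mm
        ys = np.asarray(y_iso_mm, dtype=float) - self.longitudinal_shift_mm - self.pivot_y_mm
        xr = math.cos(th) * xs + math.sin(th) * ys + self.pivot_x_mm
        yr = -math.sin(th) * xs + math.cos(th) * ys + self.pivot_y_mm
        ny, nx = self.attenuation_map.shape
        row = yr / self.map_pitch_mm + (ny - 1) / 2.0
        col = xr / self.map_pitch_mm + (nx - 1) / 2.0
        out = ndimage.map_coordinates(
            self.attenuation_map, [row, col], order=1, mode="constant", cval=0.0
        )
        return np.clip(out, 0.0, None)


@dataclass
class PhantomScene:
    """Everything in the beam path for one field."""

    slab: SlabPhantom | None = None
    couch: CouchTop | None = None
    rail: RailState | None = None
    head: HeadPhantom | None = None
    mu_eff_per_cm: float = DEFAULT_MU_EFF

    def copy(self) -> "PhantomScene":
        return PhantomScene(
            self.slab.copy() if self.slab else None,
            self.couch.copy() if self.couch else None,
            self.rail.copy() if self.rail else None,
            self.head.copy() if self.head else None,
            self.mu_eff_per_cm,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Per-pixel multiplicative Gaussian noise: dose *= (1 + N(0, sigma))."""

    relative_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")


# ---------------------------------------------------------------------------
# aperture projection and rendering


def _edge_profile(u: np.ndarray, a: float, b: float, sigma: float) -> np.ndarray:
    """Indicator of [a, b] convolved with a Gaussian of width sigma."""
    if b <= a:
        return np.zeros_like(u)
    if sigma <= 0:
        return ((u >= a) & (u <= b)).astype(float)
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((u - a) / s) + erf((b - u) / s))


def _aperture_rects_iso(beam: BeamConfig) -> list[tuple[float, float, float, float]]:
    """Aperture as disjoint (x_lo, x_hi, y_lo, y_hi) rectangles at isocenter."""
    x1, x2, y1, y2 = beam.jaws_mm
    jaw = (-x1, x2, -y1, y2)
    if beam.mlc is None:
        return [jaw]
    rects = []
    bnd = beam.mlc.leaf_boundaries_mm
    for i in range(beam.mlc.n_pairs):
        y_lo = max(bnd[i], jaw[2])
        y_hi = min(bnd[i + 1], jaw[3])
        x_lo = max(beam.mlc.left_positions_mm[i], jaw[0])
        x_hi = min(beam.mlc.right_positions_mm[i], jaw[1])
        if y_hi > y_lo and x_hi > x_lo:
            rects.append((x_lo, x_hi, y_lo, y_hi))
    return rects


def project_aperture(beam: BeamConfig, geom: PlaneGeometry = PlaneGeometry()) -> list[np.ndarray]:
    """Aperture outline at the detector plane, as (4, 2) corner arrays.

    Isocenter-plane coordinates are magnified by sdd/sad, then the
    collimator rotation is applied as an exact rotation about the central
    axis.  Corners are ordered counter-clockwise as (x, y) pairs in mm.
    """
    m = geom.magnification
    th = math.radians(beam.collimator_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    polys = []
    for x_lo, x_hi, y_lo, y_hi in _aperture_rects_iso(beam):
        corners = np.array(
            [[x_lo, y_lo], [x_hi, y_lo], [x_hi, y_hi], [x_lo, y_hi]], dtype=float
        )
        polys.append((m * corners) @ rot.T)
    return polys


def _scene_transmission(
    scene: PhantomScene | None,
    x_det: np.ndarray,
    y_det: np.ndarray,
    m: float,
    sigma_mm: float,
) -> np.ndarray | float:
    """Composite scene transmission sampled at detector-plane coordinates.

    ``x_det`` is a 1D array of column coordinates, ``y_det`` of row
    coordinates; laterally structured elements (couch strips, rail band)
    are functions of x only, the head phantom is fully 2D.
    """
    if scene is None:
        return 1.0
    t_x = np.ones_like(x_det)
    factor = 1.0
    if scene.slab is not None:
        factor *= math.exp(-scene.slab.mu_eff_per_cm * scene.slab.thickness_cm)
    if scene.couch is not None:
        c = scene.couch
        half_w = c.strip_width_mm / 2.0
        span = max(abs(x_det[0]), abs(x_det[-1])) / m + c.strip_pitch_mm
        kmax = int(math.ceil(span / c.strip_pitch_mm))
        depth = 1.0 - c.strip_transmission
        for k in range(-kmax, kmax + 1):
            center = k * c.strip_pitch_mm + c.lateral_offset_mm
            t_x = t_x - depth * _edge_profile(
                x_det, m * (center - half_w), m * (center + half_w), sigma_mm
            )
    if scene.rail is not None and scene.rail.position == "in":
        r = scene.rail
        t_x = t_x - (1.0 - r.band_transmission) * _edge_profile(
            x_det,
            m * (r.band_center_mm - r.band_width_mm / 2.0),
            m * (r.band_center_mm + r.band_width_mm / 2.0),
            sigma_mm,
        )
    t = factor * t_x[np.newaxis, :] * np.ones((y_det.size, 1))
    if scene.head is not None:
        xx, yy = np.meshgrid(x_det / m, y_det / m)
        t = t * np.exp(-scene.mu_eff_per_cm * scene.head.path_length_cm(xx, yy))
    return t


def render_image(
    beam: BeamConfig,
    scene: PhantomScene | None = None,
    noise: NoiseModel | None = None,
    geom: PlaneGeometry = PlaneGeometry(),
    pitch_mm: float = DEFAULT_PITCH_MM,
    panel_shape: tuple[int, int] = (768, 1024),
    penumbra_sigma_mm: float = DEFAULT_PENUMBRA_SIGMA_MM,
    meta: dict | None = None,
) -> DoseImage:
    """Render the integrated transit image of one field.

    Deterministic given ``(beam, scene, noise.seed)``.  The panel is
    centred on the beam axis; the aperture is evaluated analytically per
    pixel centre so edge positions are continuous, not snapped to the grid.
    """
    ny, nx = panel_shape
    origin = (ny / 2.0, nx / 2.0)
    y = (np.arange(ny) + 0.5 - origin[0]) * pitch_mm
    x = (np.arange(nx) + 0.5 - origin[1]) * pitch_mm
    m = geom.magnification
    rects = [(m * a, m * b, m * c, m * d) for a, b, c, d in _aperture_rects_iso(beam)]

    th = math.radians(beam.collimator_deg)
    aperture = np.zeros((ny, nx))
    if beam.collimator_deg == 0.0:
        for x_lo, x_hi, y_lo, y_hi in rects:
            fy = _edge_profile(y, y_lo, y_hi, penumbra_sigma_mm)
            fx = _edge_profile(x, x_lo, x_hi, penumbra_sigma_mm)
            rows = np.nonzero(fy > 1e-12)[0]
            if rows.size:
                sl = slice(rows[0], rows[-1] + 1)
                aperture[sl, :] += np.outer(fy[sl], fx)
    else:
        # Evaluate the unrotated aperture in the collimator frame: rotating
        # the aperture by theta == sampling it at coordinates rotated by
        # -theta (the isotropic penumbra commutes with the rotation).
        xx, yy = np.meshgrid(x, y)
        u = math.cos(th) * xx + math.sin(th) * yy
        v = -math.sin(th) * xx + math.cos(th) * yy
        for x_lo, x_hi, y_lo, y_hi in rects:
            aperture += _edge_profile(u, x_lo, x_hi, penumbra_sigma_mm) * _edge_profile(
                v, y_lo, y_hi, penumbra_sigma_mm
            )

    if aperture.max() < 1e-9:
        warnings.warn("aperture entirely outside the panel; rendering zeros", stacklevel=2)

    dose = beam.mu * beam.output_scale * aperture
    dose = dose * _scene_transmission(scene, x, y, m, penumbra_sigma_mm)

    if noise is not None and noise.relative_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        dose = dose * (1.0 + noise.relative_sigma * rng.standard_normal(dose.shape))
    dose = np.clip(dose, 0.0, None)
    return DoseImage(dose, pitch_mm, geom.sdd_mm, origin, dict(meta or {}))


# ---------------------------------------------------------------------------
# error injection

_JAW_INDEX = {"X1": 0, "X2": 1, "Y1": 2, "Y2": 3}

ERROR_SCENARIOS = (
    "jaw_shift",
    "mlc_shift",
    "collimator_rotation",
    "output_error",
    "mu_error",
    "couch_shift",
    "rail_state",
    "head_pose",
)


def inject_error(
    beam: BeamConfig,
    scene: PhantomScene | None,
    error: str,
    **params,
) -> tuple[BeamConfig, PhantomScene | None]:
    """Return deep-modified copies of (beam, scene) with one induced error.

    The nominal objects are never touched.  Supported errors and their
    parameters:

    - ``jaw_shift(jaw="X1", shift_mm=...)`` — open one jaw further by the
      given isocenter-plane distance.
    - ``mlc_shift(leaves=[...], bank="left"|"right", shift_mm=...)`` — move
      the listed leaf tips outward along the leaf-motion axis
      (``shift_mm`` may be a scalar or one value per listed leaf).
    - ``collimator_rotation(angle_deg=...)``
    - ``output_error(percent=...)`` / ``mu_error(percent=...)``
    - ``couch_shift(lateral_mm=...)``
    - ``rail_state(position="in"|"out")``
    - ``head_pose(lateral_mm=0, longitudinal_mm=0, roll_deg=0)``
    """
    if error not in ERROR_SCENARIOS:
        raise ConfigurationError(
            f"unknown error scenario {error!r}; valid scenarios: {', '.join(ERROR_SCENARIOS)}"
        )
    beam = beam.copy()
    scene = scene.copy() if scene is not None else None

    if error == "jaw_shift":
        jaw = params["jaw"]
        if jaw not in _JAW_INDEX:
            raise ConfigurationError(f"unknown jaw {jaw!r}")
        jaws = list(beam.jaws_mm)
        jaws[_JAW_INDEX[jaw]] += float(params["shift_mm"])
        beam.jaws_mm = tuple(jaws)
    elif error == "mlc_shift":
        if beam.mlc is None:
            raise ConfigurationError("beam has no MLC to shift")
        leaves = list(params["leaves"])
        shift = np.broadcast_to(
            np.asarray(params["shift_mm"], dtype=float), (len(leaves),)
        )
        bank = params.get("bank", "left")
        if bank == "left":
            beam.mlc.left_positions_mm[leaves] -= shift
        elif bank == "right":
            beam.mlc.right_positions_mm[leaves] += shift
        else:
            raise ConfigurationError(f"unknown MLC bank {bank!r}")
    elif error == "collimator_rotation":
        beam.collimator_deg += float(params["angle_deg"])
    elif error in ("output_error", "mu_error"):
        factor = 1.0 + float(params["percent"]) / 100.0
        if error == "output_error":
            beam.output_scale *= factor
        else:
            beam.mu *= factor
    elif error == "couch_shift":
        if scene is None or scene.couch is None:
            raise ConfigurationError("scene has no couch to shift")
        scene.couch.lateral_offset_mm += float(params["lateral_mm"])
    elif error == "rail_state":
        if scene is None or scene.rail is None:
            raise ConfigurationError("scene has no rail")
        position = params["position"]
        if position not in ("in", "out"):
            raise ConfigurationError("rail position must be 'in' or 'out'")
        scene.rail.position = position
    elif error == "head_pose":
        if scene is None or scene.head is None:
            raise ConfigurationError("scene has no head phantom")
        scene.head.lateral_shift_mm += float(params.get("lateral_mm", 0.0))
        scene.head.longitudinal_shift_mm += float(params.get("longitudinal_mm", 0.0))
        scene.head.roll_deg += float(params.get("roll_deg", 0.0))
    return beam, scene


# ---------------------------------------------------------------------------
# synthetic head phantom


def make_head_phantom(seed: int = 0, map_pitch_mm: float = 1.0) -> HeadPhantom:
    """Reproducible synthetic head: an elliptical water-equivalent head with
    a skull-like dense rim, internal bone structure and air cavities.

    The map covers a 16 cm x 20 cm isocenter-plane field of view, enough
    for a 9 cm x 11.5 cm anterior-posterior field.  Path length is zero
    strictly outside the external contour and positive inside, so rigid
    pose errors move both internal gradients and the tissue-air boundary.
    """
    rng = np.random.default_rng(seed)
    ny = int(round(200.0 / map_pitch_mm)) + 1
    nx = int(round(160.0 / map_pitch_mm)) + 1
    y = (np.arange(ny) - (ny - 1) / 2.0) * map_pitch_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * map_pitch_mm
    xx, yy = np.meshgrid(x, y)

    # External contour: ellipse with mild seeded anisotropy.
    rx = 62.0 + rng.uniform(-3.0, 3.0)
    ry = 82.0 + rng.uniform(-3.0, 3.0)
    q = (xx / rx) ** 2 + (yy / ry) ** 2
    inside = q < 1.0
    # Ellipsoidal chord length in beam direction, scaled to a ~16 cm head.
    depth_cm = 16.0 + rng.uniform(-1.0, 1.0)
    path = np.where(inside, depth_cm * np.sqrt(np.clip(1.0 - q, 0.0, None)), 0.0)

    # Skull rim: bone-equivalent excess near the external contour.
    rim = inside & (q > 0.72)
    path = path + np.where(rim, 3.5 * (q - 0.72) / 0.28, 0.0) * inside

    # One bone-like dense blob (e.g. petrous bone / mandible analogue).
    bx, by = rng.uniform(-25, 25), rng.uniform(5, 45)
    brx, bry = rng.uniform(8, 14), rng.uniform(8, 14)
    bone = np.clip(1.0 - ((xx - bx) / brx) ** 2 - ((yy - by) / bry) ** 2, 0.0, None)
    path = path + 6.0 * bone * inside

    # Air cavities (sinus / nasopharynx analogues): subtract path, but keep
    # a positive floor inside the contour — the beam still crosses tissue
    # fore and aft of a cavity.
    for _ in range(2):
        ax, ay = rng.uniform(-20, 20), rng.uniform(-50, -10)
        arx, ary = rng.uniform(6, 12), rng.uniform(6, 12)
        cav = np.clip(1.0 - ((xx - ax) / arx) ** 2 - ((yy - ay) / ary) ** 2, 0.0, None)
        path = path - 7.0 * cav
    path = np.where(inside, np.clip(path, 0.8, None), 0.0)
    # Mild smoothing for realistic internal gradients; the external contour
    # stays a genuine tissue-air step.
    sm = ndimage.gaussian_filter(path, sigma=2.0 / map_pitch_mm)
    path = np.where(inside, sm, 0.0)
    path = np.where(inside, np.clip(path, 0.4, None), 0.0)
    return HeadPhantom(path, map_pitch_mm=map_pitch_mm)
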