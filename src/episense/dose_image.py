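"""2D dose images on regular grids at a stated detector plane.

A :class:`DoseImage` is the package's central container: a rectangular grid
of relative dose values living in a physical plane a known distance from the
radiation source, with an explicit pixel pitch and the position of the beam
central axis on the grid.  All geometry is expressed in millimetres.

Coordinate convention
---------------------
Pixel ``(0, 0)`` is the top-left corner of the panel; pixel *centres* sit at
half-integer offsets in continuous pixel coordinates.  Physical coordinates
are measured from the beam central axis: ``x`` increases with column index
(crossplane), ``y`` increases with row index (inplane).  The ``origin``
field stores the central-axis position as ``(row, col)`` in continuous
pixel coordinates, so sub-pixel feature positions are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

__all__ = [
    "DoseImage",
    "PlaneGeometry",
    "DEFAULT_PANEL_SHAPE",
    "DEFAULT_PITCH_MM",
    "rescale_to_plane",
    "resample_grid",
]

#: Default panel: a 40 cm x 30 cm amorphous-silicon portal imager read out
#: as 1024 x 768 pixels.  The pitch is kept exact (400 mm / 1024) rather
#: than the rounded 0.39 mm quoted on spec sheets.
DEFAULT_PANEL_SHAPE = (768, 1024)
DEFAULT_PITCH_MM = 400.0 / 1024.0


@dataclass(frozen=True)
class PlaneGeometry:
    """Source / isocenter / detector geometry of a planar acquisition.

    Parameters
    ----------
    sad_mm:
        Source-to-axis distance.  Default 1000 mm.
    sdd_mm:
        Source-to-detector distance.  Default 1500 mm, i.e. the panel is
        mounted 50 cm beyond the isocenter and isocenter-plane features are
        magnified by 1.5 on the image.
    """

    sad_mm: float = 1000.0
    sdd_mm: float = 1500.0

    def __post_init__(self) -> None:
        if self.sad_mm <= 0 or self.sdd_mm <= 0:
            raise ValueError("sad_mm and sdd_mm must be strictly positive")

    @property
    def magnification(self) -> float:
        """Detector-plane size of a unit isocenter-plane feature (sdd/sad)."""
        return self.sdd_mm / self.sad_mm


@dataclass
class DoseImage:
    """A 2D relative-dose distribution on a regular grid.

    Attributes
    ----------
    values:
        2D float array of dose, arbitrary relative units, finite and >= 0.
    pixel_pitch_mm:
        Grid spacing, identical along both axes.
    plane_sdd_mm:
        Source-to-detector distance of the plane the grid lives in.
    origin:
        ``(row, col)`` continuous-pixel position of the beam central axis.
    meta:
        Free-form annotations (field label, fraction index, scenario id...).
    """

    values: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PITCH_MM
    plane_sdd_mm: float = 1500.0
    origin: tuple[float, float] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be strictly positive")
        if self.plane_sdd_mm <= 0:
            raise ValueError("plane_sdd_mm must be strictly positive")
        if self.origin is None:
            self.origin = (self.values.shape[0] / 2.0, self.values.shape[1] / 2.0)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_to_mm(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Continuous pixel coordinates -> physical (y, x) mm off-axis."""
        y = (np.asarray(row) - self.origin[0]) * self.pixel_pitch_mm
        x = (np.asarray(col) - self.origin[1]) * self.pixel_pitch_mm
        return y, x

    def mm_to_pixel(self, y_mm: np.ndarray, x_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(y_mm) / self.pixel_pitch_mm + self.origin[0]
        col = np.asarray(x_mm) / self.pixel_pitch_mm + self.origin[1]
        return row, col

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates of all pixel centres, as 1D arrays."""
        ny, nx = self.values.shape
        y, _ = self.pixel_to_mm(np.arange(ny) + 0.5, 0.0)
        _, x = self.pixel_to_mm(0.0, np.arange(nx) + 0.5)
        return y, x

    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the panel."""
        ny, nx = self.values.shape
        return ny * self.pixel_pitch_mm, nx * self.pixel_pitch_mm

    def copy(self) -> "DoseImage":
        return DoseImage(
            self.values.copy(),
            self.pixel_pitch_mm,
            self.plane_sdd_mm,
            self.origin,
            dict(self.meta),
        )

    def same_grid(self, other: "DoseImage", rtol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.pixel_pitch_mm, other.pixel_pitch_mm, rtol=rtol)
            and np.isclose(self.plane_sdd_mm, other.plane_sdd_mm, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
        )


def rescale_to_plane(img: DoseImage, target_sdd_mm: float) -> DoseImage:
    """Re-express an image at a different source-to-detector plane.

    The beam diverges from a point source, so the same beam cross-section at
    a plane closer to (or farther from) the source is a pure lateral scaling
    by ``target_sdd / plane_sdd``.  Only the coordinates change: the pixel
    pitch is rescaled and the dose values are untouched, because every
    comparison in this package is between relative dose images living in
    the same (jointly rescaled) plane — no inverse-square correction is
    wanted or applied.
    """
    if target_sdd_mm <= 0:
        raise ValueError("target_sdd_mm must be strictly positive")
    if target_sdd_mm == img.plane_sdd_mm:
        return img.copy()
    scale = target_sdd_mm / img.plane_sdd_mm
    out = img.copy()
    out.pixel_pitch_mm = img.pixel_pitch_mm * scale
    out.plane_sdd_mm = float(target_sdd_mm)
    return out


def resample_grid(img: DoseImage, new_pitch_mm: float, interpolation: str = "bilinear") -> DoseImage:
    """Resample an image onto a new pixel pitch covering the same extent.

    Bilinear interpolation of dose; the beam central axis stays at the same
    physical position.  The new grid is anchored at the first original pixel
    centre and spans the original pixel-centre lattice, so a pitch change by
    an integer factor keeps the original sample positions on the new grid
    (no extrapolation is ever performed).
    """
    if new_pitch_mm <= 0:
        raise ValueError("new_pitch_mm must be strictly positive")
    if interpolation != "bilinear":
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    height, width = img.extent_mm()
    if new_pitch_mm > min(height, width):
        raise ValueError("new_pitch_mm exceeds the image extent")

    ny_old, nx_old = img.values.shape
    span_y = (ny_old - 1) * img.pixel_pitch_mm
    span_x = (nx_old - 1) * img.pixel_pitch_mm
    ny = int(np.floor(span_y / new_pitch_mm + 1e-9)) + 1
    nx = int(np.floor(span_x / new_pitch_mm + 1e-9)) + 1
    # Continuous pixel coordinates (into the old grid) of the new samples;
    # sample k sits new_pitch * k beyond the first old pixel centre.
    step = new_pitch_mm / img.pixel_pitch_mm
    row = np.arange(ny) * step
    col = np.arange(nx) * step
    rr, cc = np.meshgrid(row, col, indexing="ij")
    vals = ndimage.map_coordinates(img.values, [rr, cc], order=1, mode="nearest")
    vals = np.clip(vals, 0.0, None)
    # Physical position of the first new sample is the first old centre;
    # solve (0.5 - origin_new) * new_pitch = (0.5 - origin_old) * old_pitch.
    first_y = (0.5 - img.origin[0]) * img.pixel_pitch_mm
    first_x = (0.5 - img.origin[1]) * img.pixel_pitch_mm
    new_origin = (0.5 - first_y / new_pitch_mm, 0.5 - first_x / new_pitch_mm)
    return DoseImage(vals, new_pitch_mm, img.plane_sdd_mm, new_origin, dict(img.meta))
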