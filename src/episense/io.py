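"""Readers and writers for 2D dose images.

Two on-disk dialects are supported:

``matrix-text``
    A trivially diffable UTF-8 format: ``#``-prefixed header lines carrying
    ``pitch_mm=``, ``sdd_mm=``, ``origin_row=``, ``origin_col=`` (plus any
    ``meta.<key>=`` annotations), followed by whitespace-separated rows of
    dose values.

``dicom-rt-image``
    A minimal RT Image subset: Rows, Columns, ImagePlanePixelSpacing,
    RTImageSID, RTImagePosition and linearly scaled 16-bit pixel data.
    Enough to exchange integrated portal images with planning-system
    exports; no claim of full conformance.
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dose_image import DoseImage

__all__ = ["read_dose_image", "write_dose_image", "FormatError"]

RT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"

_MATRIX_KEYS = ("pitch_mm", "sdd_mm", "origin_row", "origin_col")


class FormatError(ValueError):
    """A file is missing mandatory header keys / tags or carries bad data."""


def _guess_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("dicom-rt-image", "matrix-text"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "dicom-rt-image" if ext in (".dcm", ".dicom") else "matrix-text"


# ---------------------------------------------------------------------------
# matrix-text dialect


def _write_matrix_text(img: DoseImage, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pitch_mm={img.pixel_pitch_mm!r}\n")
        fh.write(f"# sdd_mm={img.plane_sdd_mm!r}\n")
        fh.write(f"# origin_row={img.origin[0]!r}\n")
        fh.write(f"# origin_col={img.origin[1]!r}\n")
        for key, value in sorted(img.meta.items()):
            fh.write(f"# meta.{key}={value}\n")
        for row in img.values:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def _read_matrix_text(path: str) -> DoseImage:
    header: dict[str, str] = {}
    meta: dict[str, Any] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    continue
                key, value = body.split("=", 1)
                key = key.strip()
                if key.startswith("meta."):
                    meta[key[5:]] = value.strip()
                else:
                    header[key] = value.strip()
            else:
                rows.append([float(tok) for tok in line.split()])
    for key in _MATRIX_KEYS:
        if key not in header:
            raise FormatError(f"matrix-text header missing mandatory key {key!r}")
    if not rows:
        raise FormatError("matrix-text file contains no dose rows")
    values = np.asarray(rows, dtype=float)
    if np.any(values < 0):
        raise FormatError("negative dose values in matrix-text payload")
    return DoseImage(
        values,
        pixel_pitch_mm=float(header["pitch_mm"]),
        plane_sdd_mm=float(header["sdd_mm"]),
        origin=(float(header["origin_row"]), float(header["origin_col"])),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# DICOM RT Image dialect


def _write_dicom(img: DoseImage, path: str) -> None:
    ds = Dataset()
    ds.SOPClassUID = RT_IMAGE_STORAGE
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTIMAGE"
    ds.Rows, ds.Columns = img.values.shape
    ds.ImagePlanePixelSpacing = [img.pixel_pitch_mm, img.pixel_pitch_mm]
    ds.RTImageSID = img.plane_sdd_mm
    # IEC X-ray image receptor coordinates of the upper-left pixel centre:
    # x to the right, y up, relative to the beam central axis.
    ds.RTImagePosition = [
        -(img.origin[1] - 0.5) * img.pixel_pitch_mm,
        (img.origin[0] - 0.5) * img.pixel_pitch_mm,
    ]
    vmax = float(img.values.max())
    slope = vmax / 65535.0 if vmax > 0 else 1.0
    raw = np.round(img.values / slope).astype(np.uint16)
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = 0.0
    ds.PixelData = raw.tobytes()
    if img.meta:
        ds.ImageComments = ";".join(f"{k}={v}" for k, v in sorted(img.meta.items()))

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: str) -> DoseImage:
    ds = pydicom.dcmread(path)
    for tag in ("Rows", "Columns", "ImagePlanePixelSpacing", "RTImageSID"):
        if getattr(ds, tag, None) is None:
            raise FormatError(f"DICOM RT Image missing mandatory attribute {tag!r}")
    pitch_row, pitch_col = (float(v) for v in ds.ImagePlanePixelSpacing)
    if not np.isclose(pitch_row, pitch_col, rtol=1e-6):
        raise FormatError("anisotropic pixel spacing is not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = ds.pixel_array.astype(float) * slope + intercept
    if np.any(values < 0):
        raise FormatError("negative dose after rescale slope/intercept")
    if getattr(ds, "RTImagePosition", None) is not None:
        px, py = (float(v) for v in ds.RTImagePosition)
        origin = (py / pitch_row + 0.5, -px / pitch_col + 0.5)
    else:
        origin = None
    meta: dict[str, Any] = {}
    for item in str(getattr(ds, "ImageComments", "")).split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            meta[k] = v
    return DoseImage(
        values,
        pixel_pitch_mm=pitch_row,
        plane_sdd_mm=float(ds.RTImageSID),
        origin=origin,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# public API


def read_dose_image(path: str, format: str | None = None) -> DoseImage:
    """Read a dose image, auto-detecting the dialect from the extension.

    ``.dcm`` / ``.dicom`` files are read as RT Images, anything else as
    matrix-text; pass ``format`` to override.
    """
    fmt = _guess_format(path, format)
    if fmt == "dicom-rt-image":
        return _read_dicom(path)
    return _read_matrix_text(path)


def write_dose_image(img: DoseImage, path: str, format: str | None = None) -> None:
    """Write a dose image in the chosen (or extension-implied) dialect."""
    fmt = _guess_format(path, format)
    if fmt == "dicom-rt-image":
        _write_dicom(img, path)
    else:
        _write_matrix_text(img, path)
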