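"""DICOM ingestion and export for phantom images.

The measurement core works exclusively on :class:`~ctslice.image.PhantomImage`
objects; this module is the only place that touches DICOM. Reading honours
RescaleSlope/RescaleIntercept and PixelSpacing bit-exactly; writing emits a
single-frame CT image (signed 16-bit stored values, identity rescale) that
round-trips HU within 0.5 (integer quantization).

Geometry is never rescaled here: the FWHM measured downstream is in pixels
and only the final mm conversion consumes the header spacing.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import CalibrationError, FormatError, SeriesInconsistencyError
from .image import PhantomImage

__all__ = ["read_ct_image", "read_series", "write_dicom"]

_SPACING_ATOL_MM = 1e-6


def read_ct_image(path: str | os.PathLike) -> PhantomImage:
    """Read one single-frame CT DICOM file as a calibrated HU image.

    Parameters
    ----------
    path : path-like
        A readable DICOM file with pixel data, PixelSpacing and (optionally)
        rescale tags.

    Returns
    -------
    PhantomImage
        ``pixels = stored * RescaleSlope + RescaleIntercept`` (slope/intercept
        default to 1/0 when absent); spacing in (row, col) order.

    Raises
    ------
    FormatError
        Not a parseable DICOM image.
    CalibrationError
        PixelSpacing missing.
    """
    try:
        ds = pydicom.dcmread(os.fspath(path))
        stored = ds.pixel_array
    except Exception as exc:  # pydicom raises a mix of error types here
        raise FormatError(f"{path}: not a readable DICOM image ({exc})") from exc
    if stored.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2-D image")
    if "PixelSpacing" not in ds:
        raise CalibrationError(f"{path}: missing PixelSpacing tag (0028,0030)")
    slope = float(ds.get("RescaleSlope", 1.0))
    intercept = float(ds.get("RescaleIntercept", 0.0))
    hu = stored.astype(np.float64) * slope + intercept
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return PhantomImage(hu, spacing, source_id=os.fspath(path))


def read_series(paths: Sequence[str | os.PathLike]) -> list[PhantomImage]:
    """Read an ordered series of frames, enforcing a common pixel spacing.

    Raises
    ------
    SeriesInconsistencyError
        If the list is empty or any frame's spacing differs from the first
        by more than 1e-6 mm (offending paths are listed in the message).
    """
    if len(paths) == 0:
        raise SeriesInconsistencyError("empty series: at least one frame is required")
    frames = [read_ct_image(p) for p in paths]
    ref = frames[0].pixel_spacing
    offenders = [
        f.source_id
        for f in frames
        if abs(f.pixel_spacing_row - ref[0]) > _SPACING_ATOL_MM
        or abs(f.pixel_spacing_col - ref[1]) > _SPACING_ATOL_MM
    ]
    if offenders:
        raise SeriesInconsistencyError(
            "frames disagree on pixel spacing with "
            f"{frames[0].source_id} ({ref[0]:.6f}, {ref[1]:.6f} mm): "
            + ", ".join(offenders)
        )
    return frames


def write_dicom(img: PhantomImage, path: str | os.PathLike) -> str:
    """Write a phantom image as a single-frame CT DICOM file.

    HU values are stored as signed 16-bit integers with an identity
    rescale, so ``read_ct_image(write_dicom(img))`` reproduces them within
    0.5 HU; PixelSpacing is written to 6 decimals.
    """
    path = os.fspath(path)
    # signed 16-bit storage with identity rescale: HU round-trips within
    # 0.5 without clipping noisy air values below -1024
    info = np.iinfo(np.int16)
    stored = np.clip(np.rint(img.pixels), info.min, info.max).astype(np.int16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(path, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.ImageType = ["DERIVED", "SECONDARY"]
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [
        f"{img.pixel_spacing_row:.6f}",
        f"{img.pixel_spacing_col:.6f}",
    ]
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.PixelData = stored.tobytes()
    try:
        ds.save_as(path, enforce_file_format=True)
    except OSError as exc:
        raise OSError(f"cannot write DICOM to {path}: {exc}") from exc
    return path
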