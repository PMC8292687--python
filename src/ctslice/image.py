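"""Core in-memory containers: calibrated phantom images and ground truth.

A :class:`PhantomImage` is a 2-D array of Hounsfield units together with
the physical pixel spacing read from the DICOM header (or set by the
synthetic generator). Synthetic images additionally carry a
:class:`GroundTruth` record so the whole measurement chain can be
validated in a closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruth", "PhantomImage"]


@dataclass(frozen=True)
class GroundTruth:
    """Known answers attached to synthetic phantom images.

    Attributes
    ----------
    true_fwhm_mm : float
        FWHM of the ideal bar profile (slice thickness the measurement
        should recover), in mm.
    true_angle_deg : float
        In-plane rotation applied to the stair assembly, degrees.
    bar_centers_px : tuple of (row, col)
        Fractional pixel centers of each stair bar, ordered along the
        stair axis.
    """

    true_fwhm_mm: float
    true_angle_deg: float
    bar_centers_px: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if not self.true_fwhm_mm > 0:
            raise ValueError("true_fwhm_mm must be positive")


@dataclass
class PhantomImage:
    """A calibrated 2-D CT image in Hounsfield units.

    Attributes
    ----------
    pixels : ndarray, shape (rows, cols)
        HU values; finite, non-empty.
    pixel_spacing : (float, float)
        Physical pixel size in mm, (row spacing, column spacing); the
        DICOM PixelSpacing order.
    source_id : str
        Provenance: a file path or ``"synthetic:<seed>"``.
    truth : GroundTruth or None
        Present only for synthetic images.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    source_id: str = ""
    truth: GroundTruth | None = field(default=None, repr=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite HU values")
        sr, sc = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if not (sr > 0 and sc > 0):
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing = (sr, sc)

    @property
    def pixel_spacing_row(self) -> float:
        return self.pixel_spacing[0]

    @property
    def pixel_spacing_col(self) -> float:
        return self.pixel_spacing[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]
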