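"""Stair-bar segmentation: find the three aluminum bars, pick the middle one.

The AAPM phantom's slice-thickness module shows three thin, elongated
aluminum plates on a low-contrast foundation strip, surrounded by water.
Segmentation thresholds the HU image, labels 8-connected components and
keeps only bar-shaped regions (area window, elongation >= 3), which rejects
the water disc, speckle and anything blob-like. The middle bar is selected
by ranking centroids along the principal axis of the bar centroids, which
reduces to column order for an upright phantom but survives any in-plane
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import SegmentationError
from .image import PhantomImage

__all__ = [
    "ObjectRegion",
    "resolve_threshold",
    "segment_stairs",
    "select_middle_object",
    "crop_about",
]

#: HU window used by the automatic threshold. Values below the floor are
#: treated as air and excluded; values above the ceiling are clipped.
HU_CLIP = (-200.0, 1200.0)

#: Bar-shape filters at the reference spacing of 0.508 mm/px. The plates are
#: 0.635 mm x 25.4 mm physically; imaged widths follow the slice thickness,
#: so the admissible area window is wide. Bounds scale with (0.508/spacing)^2.
AREA_RANGE_PX = (20.0, 2000.0)
MIN_ELONGATION = 3.0
_REF_SPACING_MM = 0.508
_MIN_CLASS_SEPARATION_HU = 100.0


@dataclass(frozen=True)
class ObjectRegion:
    """One labeled connected component in image coordinates.

    ``bbox`` is (row_min, col_min, row_max, col_max), 0-based half-open;
    ``elongation`` is the major/minor axis ratio (>= 1).
    """

    label: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area_px: int
    elongation: float

    def __post_init__(self):
        if self.area_px <= 0 or self.area_px != int(self.mask.sum()):
            raise ValueError("area_px must equal the number of mask pixels")
        r, c = self.centroid
        r0, c0, r1, c1 = self.bbox
        if not (r0 <= r <= r1 and c0 <= c <= c1):
            raise ValueError("centroid must lie inside bbox")
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")


def resolve_threshold(pixels: np.ndarray, hu_threshold: float | str) -> float:
    """Turn a threshold policy into a concrete HU value.

    ``"auto"`` applies Otsu's method to the HU values above the air floor
    (−200 HU), clipped at +1200 HU; a number is passed through unchanged.
    """
    if hu_threshold != "auto":
        return float(hu_threshold)
    vals = pixels[pixels > HU_CLIP[0]]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise SegmentationError("no stair objects found (image has no contrast)")
    vals = np.minimum(vals, HU_CLIP[1])
    thr = float(threshold_otsu(vals))
    # guard against thresholding pure noise: the foreground/background
    # class means must be separated by much more than the noise level
    separation = float(vals[vals >= thr].mean() - vals[vals < thr].mean())
    if separation < _MIN_CLASS_SEPARATION_HU:
        raise SegmentationError(
            "no stair objects found (foreground/background separation "
            f"{separation:.0f} HU below {_MIN_CLASS_SEPARATION_HU:.0f} HU)"
        )
    return thr


def segment_stairs(
    img: PhantomImage,
    hu_threshold: float | str = "auto",
    area_range_px: tuple[float, float] = AREA_RANGE_PX,
    min_elongation: float = MIN_ELONGATION,
) -> list[ObjectRegion]:
    """Segment bar-shaped objects, sorted by centroid column.

    Parameters
    ----------
    img : PhantomImage
    hu_threshold : float or "auto"
        Foreground threshold in HU. "auto" uses Otsu on the clipped HU
        histogram; a fixed value around +200 HU (far above water, far below
        aluminum) is a reasonable manual choice.
    area_range_px, min_elongation
        Bar-shape filters at 0.508 mm/px; the area window is rescaled by
        (0.508 / spacing)^2 for other spacings.

    Raises
    ------
    SegmentationError
        If no component passes the filters ("no stair objects found").
    """
    thr = resolve_threshold(img.pixels, hu_threshold)
    binary = img.pixels >= thr
    labels = label(binary, connectivity=2)
    scale = (_REF_SPACING_MM / img.pixel_spacing_row) ** 2
    lo, hi = (area_range_px[0] * scale, area_range_px[1] * scale)
    regions: list[ObjectRegion] = []
    for rp in regionprops(labels):
        if not lo <= rp.area <= hi:
            continue
        minor = rp.axis_minor_length
        elong = rp.axis_major_length / minor if minor > 1e-9 else np.inf
        if elong < min_elongation:
            continue
        regions.append(
            ObjectRegion(
                label=int(rp.label),
                mask=labels == rp.label,
                bbox=tuple(int(v) for v in rp.bbox),  # type: ignore[arg-type]
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
                elongation=float(elong),
            )
        )
    if not regions:
        raise SegmentationError("no stair objects found")
    regions.sort(key=lambda r: r.centroid[1])
    return regions


def select_middle_object(regions: list[ObjectRegion]) -> ObjectRegion:
    """Pick the middle stair bar (rank 2 of 3 along the stair axis).

    The stair axis is the principal axis of the region centroids, so the
    ranking is invariant to phantom rotation; for an upright phantom it
    reduces to plain column order.
    """
    n = len(regions)
    if n < 3:
        raise SegmentationError(
            f"expected at least 3 stair objects, found {n}"
        )
    pts = np.array([r.centroid for r in regions], dtype=float)
    centered = pts - pts.mean(axis=0)
    # first principal axis of the centroid scatter
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="stable")
    return regions[int(order[n // 2])]


def crop_about(
    img: PhantomImage, center: tuple[float, float], half_size_px: int
) -> PhantomImage:
    """Axis-aligned crop of side ``2*half_size_px + 1`` about a point.

    The center is rounded to the nearest pixel and the window is clipped at
    the image borders; pixel spacing is inherited.
    """
    if half_size_px < 0:
        raise ValueError("half_size_px must be non-negative")
    rows, cols = img.shape
    r = int(round(center[0]))
    c = int(round(center[1]))
    if not (0 <= r < rows and 0 <= c < cols):
        raise SegmentationError(f"crop center {center} lies outside the image")
    r0, r1 = max(0, r - half_size_px), min(rows, r + half_size_px + 1)
    c0, c1 = max(0, c - half_size_px), min(cols, c + half_size_px + 1)
    return PhantomImage(
        img.pixels[r0:r1, c0:c1].copy(),
        img.pixel_spacing,
        source_id=f"{img.source_id}#crop",
    )
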