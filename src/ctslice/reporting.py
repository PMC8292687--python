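"""Series aggregation and automated-vs-manual comparison.

Measurements are taken on several frames of a series; the report is the
mean +- sample standard deviation over frames, printed to one decimal
(full precision is retained internally and never fed back into the
computation). The percent difference between an automated and a manual
slice-thickness value is 100 * |manual - automated| / automated, rounded
half-up to one decimal — the convention is fixed by the published QC
tables this mirrors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .errors import CtsliceError
from .profile import SliceThicknessResult

__all__ = [
    "SeriesResult",
    "ComparisonRow",
    "aggregate_frames",
    "percent_difference",
    "series_to_dict",
]


@dataclass(frozen=True)
class SeriesResult:
    """Mean +- sample SD of the per-frame slice thickness (mm)."""

    mean_mm: float
    sd_mm: float
    n_frames: int
    per_frame: tuple[SliceThicknessResult, ...]

    def __post_init__(self):
        if self.n_frames != len(self.per_frame) or self.n_frames < 1:
            raise ValueError("n_frames must match per_frame and be >= 1")
        if self.sd_mm < 0:
            raise ValueError("sd_mm must be >= 0")

    def __str__(self) -> str:
        return f"{self.mean_mm:.1f} ± {self.sd_mm:.1f}"


@dataclass(frozen=True)
class ComparisonRow:
    """One automated-vs-manual table row with its percent difference."""

    condition_label: str
    automated_mm: float
    manual_mm: float
    diff_percent: float


def aggregate_frames(results: Sequence[SliceThicknessResult]) -> SeriesResult:
    """Mean and sample (n-1) standard deviation of per-frame FWHM in mm."""
    if len(results) == 0:
        raise CtsliceError("cannot aggregate an empty list of frame results")
    vals = [r.fwhm_mm for r in results]
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
    return SeriesResult(mean_mm=mean, sd_mm=sd, n_frames=n, per_frame=tuple(results))


def percent_difference(automated_mm: float, manual_mm: float) -> float:
    """Percent difference of a manual from an automated measurement.

    ``100 * |manual - automated| / automated``, rounded half-up to one
    decimal (the automated value is the denominator).
    """
    if not automated_mm > 0:
        raise CtsliceError(f"automated value must be positive, got {automated_mm}")
    # exact decimal arithmetic on the printed values, so e.g. (4.0, 4.01)
    # yields exactly 0.25 and rounds up to 0.3 rather than drifting below
    # 0.25 in binary floating point
    a = Decimal(repr(float(automated_mm)))
    m = Decimal(repr(float(manual_mm)))
    d = 100 * abs(m - a) / a
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compare(
    automated_mm: Sequence[float],
    manual_mm: Sequence[float],
    labels: Sequence[str] | None = None,
) -> list[ComparisonRow]:
    """Build an automated-vs-manual comparison table."""
    if len(automated_mm) != len(manual_mm):
        raise CtsliceError("automated and manual value lists differ in length")
    labels = labels or [f"condition {i + 1}" for i in range(len(automated_mm))]
    return [
        ComparisonRow(lbl, a, m, percent_difference(a, m))
        for lbl, a, m in zip(labels, automated_mm, manual_mm)
    ]


def series_to_dict(series: SeriesResult) -> dict:
    """JSON-ready representation of a series result (metadata included)."""
    return {
        "mean_mm": series.mean_mm,
        "sd_mm": series.sd_mm,
        "sd_definition": "sample (n-1)",
        "n_frames": series.n_frames,
        "summary": str(series),
        "per_frame": [
            {
                "frame_id": r.frame_id,
                "fwhm_px": r.fwhm_px,
                "fwhm_mm": r.fwhm_mm,
                "angle_deg": r.angle_deg,
            }
            for r in series.per_frame
        ],
    }


def series_to_json(series: SeriesResult) -> str:
    return json.dumps(series_to_dict(series), indent=2)
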