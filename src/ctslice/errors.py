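"""Exception hierarchy for the measurement pipeline.

Every stage of the pipeline raises a specific subclass of
:class:`CtsliceError`; the end-to-end driver wraps them in
:class:`StageError` so a failure always names the stage it came from.
"""


class CtsliceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CtsliceError):
    """A file is not a readable single-frame CT DICOM image."""


class CalibrationError(CtsliceError):
    """A DICOM tag required for calibration (e.g. PixelSpacing) is missing."""


class SeriesInconsistencyError(CtsliceError):
    """Frames of a series disagree on pixel spacing."""


class SegmentationError(CtsliceError):
    """No stair objects (or too few) were found in the image."""


class AngleEstimationError(CtsliceError):
    """The Hough orientation estimate could not be computed."""


class ProfileError(CtsliceError):
    """The intensity profile is degenerate or its FWHM is undefined."""


class GeometryError(CtsliceError):
    """Synthetic phantom geometry is inconsistent (e.g. bars outside water)."""


class StageError(CtsliceError):
    """Pipeline failure wrapper carrying the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
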