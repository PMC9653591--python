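"""Exception hierarchy for calibration failures."""


class CalibrationError(Exception):
    """Base class for all funduscalib errors."""


class BlankImageError(CalibrationError):
    """The red channel carries no signal; the frame cannot be thresholded."""


class RoiNotFoundError(CalibrationError):
    """No circle gathered enough Hough votes to qualify as the ROI."""


class DiscNotFoundError(CalibrationError):
    """No candidate region was bright enough against the fundus background."""


class EdgeTooWeakError(CalibrationError):
    """Too few angular columns produced a usable disc-edge response."""
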