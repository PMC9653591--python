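"""Fundus image container and raster I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["FundusImage", "load_fundus_image", "save_fundus_image"]


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph plus identifying metadata.

    ``pixels`` is an H x W x 3 uint8 array (red, green, blue planes).  Frames
    smaller than 64 x 64 are rejected: the detection chain needs room for both
    the ROI circle and the disc.
    """

    pixels: np.ndarray
    id: str = ""
    camera_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # tolerate grayscale input by replication
            px = np.stack([px] * 3, axis=-1)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 raster, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"frame too small: {px.shape[:2]} (need >= 64 x 64)")
        if px.dtype != np.uint8:
            px = px.astype(np.float64)
            top = px.max()
            if top > 255:  # e.g. 16-bit TIFF; rescale to 8-bit range
                px = px * (255.0 / top)
            px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[:, :, 2]


def load_fundus_image(path: str | Path, camera_label: str = "") -> FundusImage:
    """Read a PNG/JPEG/TIFF raster into a :class:`FundusImage`.

    The image id defaults to the file stem.
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return FundusImage(pixels=arr, id=path.stem, camera_label=camera_label)


def save_fundus_image(image: FundusImage, path: str | Path) -> None:
    """Write the raster to ``path`` (format chosen by extension)."""
    Image.fromarray(image.pixels).save(Path(path))
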