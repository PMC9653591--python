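"""Automated detection of the circular region of interest (ROI).

The ROI is the valid imaging area of a fundus photograph: a bright circle on
a dark background, possibly cropped by the frame on one or more sides.  Its
pixel diameter ``l_ROI`` is the camera-stable quantity the calibration method
builds on, so the detector must recover the full circle geometry even when
only arcs survive inside the frame.

Pipeline (deterministic): threshold the red channel at one third of its mean
gray value, keep the largest bright connected component, Canny-edge the
component boundary, and run a circular Hough transform over the edge map; the
most-voted circle is the ROI.  A final sub-pixel refinement fits a circle to
the edge pixels that supported the winning Hough cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.filters import gaussian, sobel
from skimage.measure import label, regionprops
from skimage.transform import hough_circle

from .errors import BlankImageError, RoiNotFoundError
from .image import FundusImage

__all__ = ["RoiConfig", "RoiMeasurement", "binarize_red", "largest_component", "detect_roi"]


@dataclass
class RoiConfig:
    """Tunables of the ROI detector.

    Canny hysteresis thresholds are fractions of the maximum edge magnitude;
    the Hough radius search range is a fraction of ``max(H, W)``.
    """

    canny_sigma: float = 1.5
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.3
    radius_min_frac: float = 0.25
    radius_max_frac: float = 0.75
    radius_step: int = 1
    #: minimum normalized vote fraction for a circle to count as found
    min_vote_frac: float = 0.15
    #: minimum circularity 4*pi*A/P^2 of the candidate blob; a disk is ~1,
    #: a frame-filling cropped disk ~0.7, noise speckle far below
    min_circularity: float = 0.3
    #: image border width (px) whose edge pixels are discarded, so that the
    #: straight cut lines of a cropped ROI do not vote
    border_margin: int = 2
    #: half-width (px) of the inlier band used for sub-pixel refinement
    refine_window: float = 2.0
    #: skip the coarse downsampled Hough pass below this frame size
    coarse_min_dim: int = 256


@dataclass
class RoiMeasurement:
    """A fitted ROI circle in pixel coordinates.

    ``center_xy`` uses 0-based (x, y) = (column, row) pixel-centre
    coordinates; ``cropped`` flags the (left, top, right, bottom) sides the
    circle extends past.
    """

    center_xy: tuple[float, float]
    diameter_px: float
    votes: float
    cropped: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    @property
    def is_cropped(self) -> bool:
        return any(self.cropped)


def binarize_red(image: FundusImage) -> np.ndarray:
    """Threshold the red channel at one third of its mean gray value.

    Returns a boolean mask ``red >= mean(red) / 3`` computed over the whole
    frame; raises :class:`BlankImageError` if the red plane is identically
    zero.
    """
    red = image.red.astype(np.float64)
    mean = red.mean()
    if mean == 0.0:
        raise BlankImageError("blank image: red channel is all zero")
    return red >= mean / 3.0


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected true region of ``mask``.

    Area ties are broken by the smallest (row, col) top-left bounding-box
    corner.  Raises ``ValueError`` on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    labels = label(mask, connectivity=2)
    props = regionprops(labels)
    best = min(props, key=lambda p: (-p.area, p.bbox[0], p.bbox[1]))
    return labels == best.label


def _canny_fractional(img: np.ndarray, sigma: float, low_frac: float, high_frac: float) -> np.ndarray:
    """Canny with hysteresis thresholds given as fractions of the peak edge magnitude."""
    grad_max = sobel(gaussian(img, sigma=sigma, preserve_range=True)).max()
    if grad_max == 0:
        return np.zeros(img.shape, dtype=bool)
    return canny(
        img,
        sigma=sigma,
        low_threshold=low_frac * grad_max,
        high_threshold=high_frac * grad_max,
    )


def _strip_border(edges: np.ndarray, margin: int) -> np.ndarray:
    if margin > 0:
        edges = edges.copy()
        edges[:margin, :] = False
        edges[-margin:, :] = False
        edges[:, :margin] = False
        edges[:, -margin:] = False
    return edges


def _kasa_circle(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit (Kasa)."""
    A = np.column_stack([xs, ys, np.ones_like(xs)])
    b = xs**2 + ys**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise np.linalg.LinAlgError("degenerate circle fit")
    return cx, cy, float(np.sqrt(r2))


def _best_circle(acc: np.ndarray, radii: np.ndarray, frame_center: tuple[float, float]):
    """Most-voted Hough cell; ties broken by larger radius, then by center
    closest to the frame center."""
    vmax = acc.max()
    ks, ys, xs = np.nonzero(acc >= vmax - 1e-9)
    order = sorted(
        range(len(ks)),
        key=lambda i: (
            -radii[ks[i]],
            (xs[i] - frame_center[0]) ** 2 + (ys[i] - frame_center[1]) ** 2,
        ),
    )
    i = order[0]
    return float(vmax), int(radii[ks[i]]), int(xs[i]), int(ys[i])


def detect_roi(image: FundusImage, config: RoiConfig | None = None) -> RoiMeasurement:
    """Measure the ROI circle of a fundus photograph.

    Runs the threshold / largest-component / Canny / circular-Hough chain and
    returns the most-voted circle, refined to sub-pixel precision.  The Hough
    accumulator covers in-frame centers only, which suffices for
    macula-centered photographs whether or not the circle is cropped: the
    surviving arcs still vote for the true center and radius.

    Raises
    ------
    RoiNotFoundError
        If no circle reaches ``config.min_vote_frac`` of the normalized vote.
    """
    cfg = config or RoiConfig()
    mask = largest_component(binarize_red(image))
    H, W = mask.shape
    max_dim = max(H, W)

    props = regionprops(mask.astype(np.uint8))[0]
    if props.perimeter > 0:
        circularity = 4.0 * np.pi * props.area / props.perimeter**2
        if circularity < cfg.min_circularity:
            raise RoiNotFoundError(
                f"ROI not found: candidate region circularity {circularity:.2f} "
                f"< {cfg.min_circularity}"
            )
    edges = _strip_border(
        _canny_fractional(mask.astype(np.float64), cfg.canny_sigma, cfg.canny_low_frac, cfg.canny_high_frac),
        cfg.border_margin,
    )
    if not edges.any():
        raise RoiNotFoundError("ROI not found: no edge pixels")
    frame_center = ((W - 1) / 2.0, (H - 1) / 2.0)

    r_lo = max(2, int(round(cfg.radius_min_frac * max_dim)))
    r_hi = int(round(cfg.radius_max_frac * max_dim))

    # Coarse pass on a downsampled edge map narrows the radius window; the
    # definitive vote is then cast at full resolution with the configured step.
    if max_dim >= cfg.coarse_min_dim:
        ds = 2
        while max_dim / ds > 320:
            ds *= 2
        small = mask[::ds, ::ds]
        e0 = _strip_border(
            _canny_fractional(small.astype(np.float64), 1.0, cfg.canny_low_frac, cfg.canny_high_frac),
            1,
        )
        radii0 = np.arange(max(2, r_lo // ds), max(3, r_hi // ds) + 1, 2)
        if e0.any() and len(radii0):
            acc0 = hough_circle(e0, radii0, normalize=True)
            _, r0, _, _ = _best_circle(acc0, radii0, (frame_center[0] / ds, frame_center[1] / ds))
            lo = max(r_lo, r0 * ds - 2 * ds - 2)
            hi = min(r_hi, r0 * ds + 2 * ds + 2)
            radii = np.arange(lo, hi + 1, cfg.radius_step)
        else:
            radii = np.arange(r_lo, r_hi + 1, cfg.radius_step)
    else:
        radii = np.arange(r_lo, r_hi + 1, cfg.radius_step)

    acc = hough_circle(edges, radii, normalize=True)
    votes, r, cx, cy = _best_circle(acc, radii, frame_center)
    if votes < cfg.min_vote_frac:
        raise RoiNotFoundError(
            f"ROI not found: best vote fraction {votes:.3f} < {cfg.min_vote_frac}"
        )

    # Sub-pixel refinement: circle fit to the edge pixels near the Hough circle.
    ey, ex = np.nonzero(edges)
    fx, fy, fr = float(cx), float(cy), float(r)
    for _ in range(2):
        d = np.hypot(ex - fx, ey - fy)
        sel = np.abs(d - fr) <= cfg.refine_window
        if sel.sum() < 8:
            break
        try:
            fx, fy, fr = _kasa_circle(ex[sel].astype(float), ey[sel].astype(float))
        except np.linalg.LinAlgError:
            break

    cropped = (fx - fr < 0, fy - fr < 0, fx + fr > W - 1, fy + fr > H - 1)
    return RoiMeasurement(
        center_xy=(fx, fy),
        diameter_px=2.0 * fr,
        votes=votes,
        cropped=cropped,
    )


def roi_mask(measurement: RoiMeasurement, shape: tuple[int, int]) -> np.ndarray:
    """Boolean in-frame mask of the fitted ROI circle (helper for downstream steps)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cx, cy = measurement.center_xy
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= measurement.radius_px**2
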