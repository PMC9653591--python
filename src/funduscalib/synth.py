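"""Seeded generator of ground-truthed synthetic fundus photographs.

The generator emulates the statistical structure the calibration method
relies on, at desk scale: a per-camera ROI diameter that is almost constant
(sub-pixel spread), a population of optic-disc diameters drawn in
millimetres and projected to pixels through the camera's true pitch and the
eye's ametropia, and a macula-centered layout with the disc at a lateral
(nasal) offset.  Each rendered frame carries its :class:`GroundTruth`, so
every stage of the detection chain can be scored against known geometry.

It does **not** attempt photorealism: no retinal texture, pathology, or
illumination artefacts — just the bright cropped-circle ROI, a brighter
elliptical disc, optional dark vessel strokes, and additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .image import FundusImage, save_fundus_image
from .optics import DEFAULT_F1_MM, delta_d_from_diopter

__all__ = [
    "CameraProfile",
    "GroundTruth",
    "RenderConfig",
    "PopulationModel",
    "DESK_PROFILES",
    "make_profile",
    "render_fundus",
    "sample_ground_truths",
    "sample_cohort",
    "write_cohort",
    "expected_ratio",
    "truth_measurements",
]


@dataclass(frozen=True)
class CameraProfile:
    """A synthetic fundus camera: frame size, ROI statistics, and true pitch.

    ``roi_diameter_px`` may exceed the frame height, in which case rendered
    ROI circles are cropped top and bottom exactly as real cameras crop them.
    ``crop_fraction`` records the nominal per-side crop implied by the frame.
    """

    name: str
    image_size: tuple[int, int]  # (W, H)
    roi_diameter_px: float
    roi_diameter_std_px: float
    pitch_um_truth: float
    crop_fraction: float = 0.0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if self.roi_diameter_px > math.hypot(w, h):
            raise ValueError("ROI diameter exceeds the frame diagonal")
        if not 0.0 <= self.crop_fraction <= 0.3:
            raise ValueError("crop_fraction must lie in [0, 0.3]")
        if self.pitch_um_truth <= 0 or self.roi_diameter_px <= 0:
            raise ValueError("pitch and ROI diameter must be positive")
        if self.roi_diameter_std_px < 0:
            raise ValueError("ROI diameter std must be >= 0")


@dataclass
class GroundTruth:
    """Per-image rendering geometry, serialized alongside each frame."""

    roi_center: tuple[float, float]
    roi_diameter_px: float
    disc_center: tuple[float, float]
    disc_major_px: float
    disc_minor_px: float
    diopter_D: float = 0.0

    def __post_init__(self) -> None:
        if self.disc_minor_px > self.disc_major_px:
            raise ValueError("minor axis exceeds major axis")
        gap = math.hypot(
            self.disc_center[0] - self.roi_center[0],
            self.disc_center[1] - self.roi_center[1],
        )
        if gap + self.disc_major_px / 2.0 > self.roi_diameter_px / 2.0 + 1e-9:
            raise ValueError("disc is not entirely inside the ROI")

    def to_dict(self) -> dict:
        return {
            "roi_center_x": self.roi_center[0],
            "roi_center_y": self.roi_center[1],
            "roi_diameter_px": self.roi_diameter_px,
            "disc_center_x": self.disc_center[0],
            "disc_center_y": self.disc_center[1],
            "disc_major_px": self.disc_major_px,
            "disc_minor_px": self.disc_minor_px,
            "diopter_D": self.diopter_D,
        }


@dataclass
class RenderConfig:
    """Appearance knobs of the renderer."""

    background_level: float = 8.0
    roi_rgb: tuple[float, float, float] = (175.0, 95.0, 38.0)
    #: quadratic radial shading coefficient of the ROI interior
    shading: float = 0.30
    disc_rgb: tuple[float, float, float] = (235.0, 190.0, 120.0)
    disc_edge_width_px: float = 1.2
    n_vessels: int = 4
    vessel_width_px: float = 1.6
    vessel_darken: tuple[float, float, float] = (35.0, 45.0, 10.0)
    noise_sigma: float = 3.0
    #: optional quadratic radial lens distortion (0 disables the remap)
    distortion_k2: float = 0.0


@dataclass
class PopulationModel:
    """Cohort-level distributions the truth sampler draws from.

    Disc diameters are normal in millimetres; diopters are normal and
    truncated at ``diopter_bound_D``.  The disc sits at
    ``disc_offset_frac`` of the ROI radius to one side of the macula
    (side chosen at random, emulating left/right eyes).
    """

    disc_diam_mm_mean: float = 1.921
    disc_diam_mm_sd: float = 0.19
    diopter_mean_D: float = -0.559
    diopter_sd_D: float = 3.522
    diopter_bound_D: float = 10.0
    disc_axis_ratio: float = 0.90  # minor / major; major axis is vertical
    disc_offset_frac: float = 0.60
    f1_mm: float = DEFAULT_F1_MM


def make_profile(
    name: str,
    roi_diameter_px: float,
    pitch_um_truth: float,
    roi_diameter_std_px: float = 0.1,
    crop_fraction: float = 0.0,
    width_pad_frac: float = 0.05,
) -> CameraProfile:
    """Build a profile whose frame realizes a given per-side ROI crop."""
    h = int(round(roi_diameter_px * (1.0 - 2.0 * crop_fraction)))
    w = int(round(roi_diameter_px * (1.0 + 2.0 * width_pad_frac)))
    return CameraProfile(
        name=name,
        image_size=(w, h),
        roi_diameter_px=roi_diameter_px,
        roi_diameter_std_px=roi_diameter_std_px,
        pitch_um_truth=pitch_um_truth,
        crop_fraction=crop_fraction,
    )


def _desk(name, size, roi, roi_std, pitch):
    w, h = size
    crop = max(0.0, (roi - h) / 2.0 / roi)
    return CameraProfile(name, size, roi, roi_std, pitch, crop_fraction=crop)


#: Four camera profiles mirroring the printed cohort cameras at 1/5 scale:
#: frame geometry, ROI spread and ISO-style pitch are each scaled so a full
#: detection run stays fast while disc diameters remain 50-70 px.
DESK_PROFILES: dict[str, CameraProfile] = {
    "canon": _desk("canon", (595, 397), 360.478, 0.103, 34.485),
    "topcon": _desk("topcon", (391, 387), 371.397, 0.728, 34.035),
    "zeiss": _desk("zeiss", (425, 411), 424.742, 0.096, 28.465),
    "newvision": _desk("newvision", (418, 398), 418.119, 0.048, 30.250),
}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (deterministic given the rng state)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def disc_pixels_from_mm(
    disc_mm: float, pitch_um: float, diopter_D: float, f1_mm: float = DEFAULT_F1_MM
) -> float:
    """Project a physical disc diameter to pixels through pitch and ametropia.

    The local pitch near the disc scales with the retinal-sphere radius,
    ``pitch * (f1 + delta_d) / f1``, so a myopic (elongated) eye renders the
    same disc smaller in pixels.
    """
    delta_d = delta_d_from_diopter(diopter_D, f1_mm)
    local_pitch = pitch_um * (f1_mm + delta_d) / f1_mm
    return disc_mm * 1000.0 / local_pitch


def render_fundus(
    profile: CameraProfile,
    truth: GroundTruth,
    seed: int,
    config: RenderConfig | None = None,
) -> FundusImage:
    """Render one synthetic fundus frame for a truth record.

    Deterministic per ``seed``: two calls with identical arguments produce
    bit-identical rasters.  Raises ``ValueError`` if the truth geometry is
    inconsistent with the profile (frame cannot contain the ROI center, or
    the ROI diameter strays >10% from the profile mean).
    """
    cfg = config or RenderConfig()
    W, H = profile.image_size
    cx, cy = truth.roi_center
    if not (0 <= cx <= W - 1 and 0 <= cy <= H - 1):
        raise ValueError("truth ROI center outside the profile frame")
    if abs(truth.roi_diameter_px - profile.roi_diameter_px) > 0.1 * profile.roi_diameter_px:
        raise ValueError("truth ROI diameter inconsistent with profile")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    r_roi = truth.roi_diameter_px / 2.0
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(r_roi + 0.5 - dist, 0.0, 1.0)  # anti-aliased rim
    shade = np.clip(1.0 - cfg.shading * (dist / r_roi) ** 2, 0.0, 1.0)

    img = np.empty((H, W, 3), dtype=np.float64)
    for c in range(3):
        img[:, :, c] = cfg.background_level + coverage * shade * (
            cfg.roi_rgb[c] - cfg.background_level
        )

    # vessels: dark arcs leaving the disc, bending toward the macula
    if cfg.n_vessels > 0:
        _stamp_vessels(img, truth, r_roi, rng, cfg)

    # elliptical disc, vertical major axis, soft (anti-aliased) edge
    dx = xx - truth.disc_center[0]
    dy = yy - truth.disc_center[1]
    b = truth.disc_minor_px / 2.0  # horizontal semi-axis
    a = truth.disc_major_px / 2.0  # vertical semi-axis
    q = np.sqrt((dx / b) ** 2 + (dy / a) ** 2)
    t = (1.0 - q) * min(a, b)
    disc_cov = np.clip(t / cfg.disc_edge_width_px + 0.5, 0.0, 1.0)
    for c in range(3):
        img[:, :, c] = img[:, :, c] * (1.0 - disc_cov) + cfg.disc_rgb[c] * disc_cov

    if cfg.distortion_k2 != 0.0:
        img = _radial_distort(img, (cx, cy), r_roi, cfg.distortion_k2)

    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels, id=f"{profile.name}_{seed:08d}", camera_label=profile.name)


def _stamp_vessels(img, truth, r_roi, rng, cfg: RenderConfig) -> None:
    H, W = img.shape[:2]
    dcx, dcy = truth.disc_center
    macula_dir = -1.0 if dcx > truth.roi_center[0] else 1.0
    for k in range(cfg.n_vessels):
        up = 1.0 if k % 2 == 0 else -1.0  # alternate superior / inferior arcades
        tilt = rng.normal(0.0, 0.08)
        length = r_roi * (0.7 + 0.2 * rng.random())
        bend = macula_dir * (0.35 + 0.2 * rng.random())
        ts = np.linspace(0.02, 1.0, max(8, int(length)))
        px = dcx + bend * r_roi * ts**2 + length * ts * tilt
        py = dcy - up * length * ts
        w = cfg.vessel_width_px
        for x0, y0 in zip(px, py):
            lo_y, hi_y = int(max(0, y0 - w - 1)), int(min(H, y0 + w + 2))
            lo_x, hi_x = int(max(0, x0 - w - 1)), int(min(W, x0 + w + 2))
            if lo_y >= hi_y or lo_x >= hi_x:
                continue
            sy, sx = np.mgrid[lo_y:hi_y, lo_x:hi_x].astype(np.float64)
            cov = np.clip(w / 2.0 + 0.5 - np.hypot(sx - x0, sy - y0), 0.0, 1.0)
            for c in range(3):
                img[lo_y:hi_y, lo_x:hi_x, c] -= cfg.vessel_darken[c] * cov


def _radial_distort(img, center, r_norm, k2):
    """Quadratic radial remap emulating barrel/pincushion lens distortion."""
    from scipy.ndimage import map_coordinates

    H, W = img.shape[:2]
    cx, cy = center
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    rho = np.hypot(dx, dy) / r_norm
    scale = 1.0 + k2 * rho**2
    src_x = (cx + dx * scale).ravel()
    src_y = (cy + dy * scale).ravel()
    out = np.empty_like(img)
    for c in range(3):
        out[:, :, c] = map_coordinates(
            img[:, :, c], [src_y, src_x], order=1, mode="nearest"
        ).reshape(H, W)
    return out


def sample_ground_truths(
    profile: CameraProfile,
    n: int,
    population: PopulationModel | None = None,
    seed: int = 0,
) -> list[GroundTruth]:
    """Draw ``n`` per-image truth records for a camera profile."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = population or PopulationModel()
    rng = np.random.default_rng(seed)
    W, H = profile.image_size
    out = []
    for _ in range(n):
        roi_d = max(8.0, rng.normal(profile.roi_diameter_px, profile.roi_diameter_std_px))
        disc_mm = _truncated_normal(
            rng,
            pop.disc_diam_mm_mean,
            pop.disc_diam_mm_sd,
            pop.disc_diam_mm_mean - 3.5 * pop.disc_diam_mm_sd,
            pop.disc_diam_mm_mean + 3.5 * pop.disc_diam_mm_sd,
        )
        diopter = _truncated_normal(
            rng, pop.diopter_mean_D, pop.diopter_sd_D, -pop.diopter_bound_D, pop.diopter_bound_D
        )
        major = disc_pixels_from_mm(disc_mm, profile.pitch_um_truth, diopter, pop.f1_mm)
        minor = pop.disc_axis_ratio * major
        side = 1.0 if rng.random() < 0.5 else -1.0
        roi_center = ((W - 1) / 2.0, (H - 1) / 2.0)
        offset = pop.disc_offset_frac * roi_d / 2.0
        jitter_y = rng.normal(0.0, 0.02 * roi_d / 2.0)
        out.append(
            GroundTruth(
                roi_center=roi_center,
                roi_diameter_px=float(roi_d),
                disc_center=(roi_center[0] + side * offset, roi_center[1] + jitter_y),
                disc_major_px=float(major),
                disc_minor_px=float(minor),
                diopter_D=diopter,
            )
        )
    return out


def sample_cohort(
    profile: CameraProfile,
    n: int,
    population: PopulationModel | None = None,
    seed: int = 0,
    render: bool = True,
    render_config: RenderConfig | None = None,
) -> Iterator[tuple[FundusImage | None, GroundTruth]]:
    """Yield ``(image, truth)`` pairs for a synthetic cohort.

    With ``render=False`` only truths are produced (measurement-level
    cohorts for statistical checks, no rasterization cost).
    """
    truths = sample_ground_truths(profile, n, population, seed)
    rng = np.random.default_rng(seed + 1)
    for truth in truths:
        img = None
        if render:
            img = render_fundus(profile, truth, seed=int(rng.integers(0, 2**31 - 1)), config=render_config)
        yield img, truth


def truth_measurements(truth: GroundTruth) -> tuple[float, float]:
    """Ground-truth ``(l_ROI, l_disc)`` pixel pair of one record.

    The disc diameter under the farthest-pair definition is the major axis.
    """
    return truth.roi_diameter_px, truth.disc_major_px


def expected_ratio(
    profile: CameraProfile, population: PopulationModel | None = None, n_grid: int = 4001
) -> float:
    """Closed-form (quadrature) expectation of the per-image ROI-disc ratio.

    ``r = l_ROI * pitch_disc / (L * 1000)`` with independent draws, so
    ``E[r] = E[l_ROI] * pitch / 1000 * E[(f1+dd)/f1] * E[1/L]`` — each factor
    integrated over its (truncated) normal density on a dense grid.  This is
    the generator's own analytic value that cohort statistics are checked
    against.
    """
    pop = population or PopulationModel()

    def _trunc_expect(fn, mean, sd, lo, hi):
        if sd == 0:
            return fn(np.clip(mean, lo, hi))
        xs = np.linspace(lo, hi, n_grid)
        pdf = np.exp(-0.5 * ((xs - mean) / sd) ** 2)
        pdf /= np.trapezoid(pdf, xs)
        return float(np.trapezoid(fn(xs) * pdf, xs))

    e_inv_L = _trunc_expect(
        lambda L: 1.0 / L,
        pop.disc_diam_mm_mean,
        pop.disc_diam_mm_sd,
        pop.disc_diam_mm_mean - 3.5 * pop.disc_diam_mm_sd,
        pop.disc_diam_mm_mean + 3.5 * pop.disc_diam_mm_sd,
    )
    f1 = pop.f1_mm
    e_mag = _trunc_expect(
        lambda D: (f1 + np.vectorize(delta_d_from_diopter)(D, f1)) / f1,
        pop.diopter_mean_D,
        pop.diopter_sd_D,
        -pop.diopter_bound_D,
        pop.diopter_bound_D,
    )
    return profile.roi_diameter_px * profile.pitch_um_truth / 1000.0 * e_mag * e_inv_L


def write_cohort(
    profile: CameraProfile,
    n: int,
    out_dir: str | Path,
    population: PopulationModel | None = None,
    seed: int = 0,
    render_config: RenderConfig | None = None,
) -> Path:
    """Render a cohort to ``out_dir`` as PNGs plus a manifest.csv of truths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth) in enumerate(
        sample_cohort(profile, n, population, seed, render=True, render_config=render_config)
    ):
        name = f"{profile.name}_{i:05d}.png"
        save_fundus_image(img, out / name)
        rows.append({"id": Path(name).stem, "file": name, "camera_label": profile.name, **truth.to_dict()})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
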