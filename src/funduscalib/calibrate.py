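"""Pixel-pitch calibration from ROI and disc diameters.

Offline phase: over a cohort of fundus photographs from one camera (or from
any cameras sharing a 45 degree FOV), the per-image ratio ``r = l_ROI /
l_disc`` of ROI to disc pixel diameters is averaged.  Because the physical
ROI size is fixed by the FOV and the population-mean disc diameter ``L_disc``
is stable, this ratio is a calibration constant of the camera (or of the
FOV).

Online phase: a single image's measured ROI diameter then yields the pixel
pitch near the optic disc, ``P_disc = r * L_disc / l_ROI`` (um), with a
propagated uncertainty combining the spread of the ratio, of the anatomical
prior, and of the ROI measurement in quadrature.

All standard deviations here are population (1/n) standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .optics import DEFAULT_F1_MM, compensate_pitch  # noqa: F401  (re-export context)

__all__ = [
    "RatioStatistics",
    "DiscDiameterPrior",
    "PitchEstimate",
    "mean_pixel_pitch",
    "roi_disc_ratio",
    "offline_calibrate",
    "estimate_pitch",
    "propagate_uncertainty",
    "iso_pitch",
    "pitch_bias",
    "sensitivity_to_prior",
]

#: Default exclusion threshold for serious axial ametropia, diopters.
DEFAULT_DIOPTER_EXCLUSION = 6.0


@dataclass
class RatioStatistics:
    """Offline-phase ROI-disc ratio statistics for one scope.

    ``scope`` is a camera label for camera-specified calibration or a FOV tag
    (e.g. ``"FOV45"``) when pooling cameras of a common field of view.
    ``r_mean_of_means`` is the alternative estimate built from the ratio of
    the mean diameters, reported alongside for transparency.
    """

    scope: str
    r_mean: float
    r_std: float
    n: int
    lroi_mean: float
    lroi_std: float
    r_mean_of_means: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.r_mean <= 0:
            raise ValueError("r_mean must be positive")
        if self.r_std < 0 or self.lroi_std < 0:
            raise ValueError("standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "n": self.n,
            "r_mean": self.r_mean,
            "r_std": self.r_std,
            "lroi_mean": self.lroi_mean,
            "lroi_std": self.lroi_std,
            "r_mean_of_means": self.r_mean_of_means,
        }


@dataclass
class DiscDiameterPrior:
    """Anatomical prior on the vertical optic-disc diameter (mm)."""

    L_disc: float
    U_Ldisc: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.L_disc <= 0:
            raise ValueError("L_disc must be positive")
        if self.U_Ldisc < 0:
            raise ValueError("U_Ldisc must be >= 0")


@dataclass
class PitchEstimate:
    """A per-image pixel-pitch estimate with uncertainty and optional ISO bias."""

    P_disc: float
    U_Pdisc: float
    scenario: str
    P_iso: float | None = None
    delta_P: float | None = None
    delta_P_rel: float | None = None

    def __post_init__(self) -> None:
        if self.P_disc <= 0:
            raise ValueError("P_disc must be positive")
        if self.U_Pdisc < 0:
            raise ValueError("U_Pdisc must be >= 0")
        if self.P_iso is not None and self.delta_P is None:
            self.delta_P, self.delta_P_rel = pitch_bias(self.P_disc, self.P_iso)


def mean_pixel_pitch(L_ROI_mm: float, l_ROI_px: float) -> float:
    """Average pitch over the whole image: ``L_ROI / l_ROI`` in um/px."""
    if L_ROI_mm <= 0 or l_ROI_px <= 0:
        raise ValueError("L_ROI and l_ROI must be positive")
    return L_ROI_mm * 1000.0 / l_ROI_px


def roi_disc_ratio(l_ROI_px: float, l_disc_px: float) -> float:
    """Per-image ROI-disc diameter ratio ``r = l_ROI / l_disc``."""
    if l_ROI_px <= 0:
        raise ValueError("l_ROI must be positive")
    if l_disc_px <= 0:
        raise ValueError("l_disc must be positive")
    return l_ROI_px / l_disc_px


def offline_calibrate(
    measurements: Iterable[tuple[float, float]],
    scope: str = "FOV45",
) -> RatioStatistics:
    """Pool per-image ``(l_ROI, l_disc)`` pixel measurements into ratio statistics.

    ``r_mean``/``r_std`` are the mean and population standard deviation of
    the per-image ratios; ``l_ROI`` statistics are reported the same way.
    Exclusion of abnormal images (failed detections, serious ametropia)
    happens upstream — every pair passed in counts.
    """
    pairs = [(float(a), float(b)) for a, b in measurements]
    if not pairs:
        raise ValueError("no measurements to calibrate from")
    lroi = np.array([p[0] for p in pairs])
    ldisc = np.array([p[1] for p in pairs])
    if (lroi <= 0).any() or (ldisc <= 0).any():
        raise ValueError("all diameters must be positive")
    ratios = lroi / ldisc
    return RatioStatistics(
        scope=scope,
        r_mean=float(ratios.mean()),
        r_std=float(ratios.std(ddof=0)),
        n=len(pairs),
        lroi_mean=float(lroi.mean()),
        lroi_std=float(lroi.std(ddof=0)),
        r_mean_of_means=float(lroi.mean() / ldisc.mean()),
    )


def estimate_pitch(r: float, L_disc_mm: float, l_ROI_px: float) -> float:
    """Pixel pitch near the disc: ``P_disc = r * L_disc / l_ROI`` in um/px."""
    if r <= 0 or L_disc_mm <= 0 or l_ROI_px <= 0:
        raise ValueError("r, L_disc and l_ROI must all be positive")
    return r * L_disc_mm * 1000.0 / l_ROI_px


def propagate_uncertainty(
    P_disc: float,
    r: float,
    U_r: float,
    L_disc: float,
    U_Ldisc: float,
    l_ROI: float,
    U_lROI: float,
) -> float:
    """Quadrature propagation of the three relative uncertainties onto ``P_disc``.

    ``U_P = P sqrt((U_r/r)^2 + (U_L/L)^2 + (U_l/l)^2)`` — the standard
    first-order formula for a product/quotient of independent factors.
    """
    if r <= 0 or L_disc <= 0 or l_ROI <= 0:
        raise ValueError("r, L_disc and l_ROI must all be positive")
    if min(U_r, U_Ldisc, U_lROI) < 0:
        raise ValueError("uncertainties must be >= 0")
    rel = (U_r / r) ** 2 + (U_Ldisc / L_disc) ** 2 + (U_lROI / l_ROI) ** 2
    return P_disc * math.sqrt(rel)


def iso_pitch(N_px: float) -> float:
    """Reference pitch from the 100 mm target at 1000 mm: ``P = 1700 / N`` um.

    ``N`` is the pixel count spanning the 100 mm scale; the constant 1700
    assumes an emmetropic eye of 17 mm focal length.
    """
    if N_px <= 0:
        raise ValueError("N must be positive")
    return 1700.0 / N_px


def pitch_bias(P_disc: float, P_iso: float) -> tuple[float, float]:
    """Absolute (um) and relative (%) bias of an estimate against the ISO pitch."""
    if P_iso <= 0:
        raise ValueError("P_iso must be positive")
    delta = P_disc - P_iso
    return delta, 100.0 * delta / P_iso


def sensitivity_to_prior(
    prior_alternatives_mm: Sequence[float],
    r: float,
    cameras: Sequence[tuple[str, float, float]],
) -> list[dict]:
    """Re-estimate pitch and ISO bias for each alternative disc-diameter prior.

    ``cameras`` holds ``(label, l_ROI_px, P_iso_um)`` triples.  Returns one
    row per (prior, camera) with the recomputed pitch and relative bias —
    the knob being how much the anatomical prior could plausibly move.
    """
    rows = []
    for L in prior_alternatives_mm:
        for label, l_roi, p_iso in cameras:
            P = estimate_pitch(r, L, l_roi)
            dP, dP_rel = pitch_bias(P, p_iso)
            rows.append(
                {
                    "L_disc_mm": L,
                    "camera": label,
                    "P_disc_um": P,
                    "P_iso_um": p_iso,
                    "delta_P_um": dP,
                    "delta_P_rel_pct": dP_rel,
                }
            )
    return rows


def filter_measurements(
    records: Iterable[dict],
    max_abs_diopter: float = DEFAULT_DIOPTER_EXCLUSION,
) -> list[dict]:
    """Exclusion gate for abnormal cohort records.

    Drops records with missing/non-positive diameters (failed detections) and,
    when a diopter is present, those with serious axial ametropia
    (|D| > ``max_abs_diopter``).  Records without a diopter are kept.
    """
    kept = []
    for rec in records:
        lroi = rec.get("roi_diameter_px")
        ldisc = rec.get("disc_diameter_px")
        if lroi is None or ldisc is None or lroi <= 0 or ldisc <= 0:
            continue
        D = rec.get("diopter")
        if D is not None and abs(D) > max_abs_diopter:
            continue
        kept.append(rec)
    return kept
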