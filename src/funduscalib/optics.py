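"""Reduced-eye and fundus-camera geometric optics.

The eye is modelled as a single refractive surface with first focal length
``f1`` (~17 mm in air).  Together with the camera the system behaves like a
telescope: for an emmetropic eye the retina coincides with the second focal
plane and the image-side magnification is ``f0 / f1``.  Axial ametropia of
``D`` diopters displaces the retina by a signed distance ``delta_d`` from the
second focal plane, which perturbs the magnification to ``f0 / (f1 + delta_d)``
and stretches the retinal arc subtended by the camera's field of view.

Unit contract: all lengths are millimetres except where noted; pixel pitches
are micrometres; the field of view ``alpha`` is radians.  The diopter product
``f1 * D`` is evaluated with ``f1`` in metres (diopters are inverse metres).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EyeCameraModel",
    "delta_d_from_diopter",
    "diopter_from_delta_d",
    "magnification",
    "magnification_bias",
    "roi_fundus_diameter",
    "compensate_pitch",
]

#: First focal length of the reduced emmetropic eye in air, mm.
DEFAULT_F1_MM = 17.0
#: Axial length of the reduced emmetropic eye, mm (informational).
DEFAULT_AXIAL_LENGTH_MM = 23.87
#: Refractive index of the vitreous humour (informational).
N_VITREOUS = 1.336

_CONSISTENCY_TOL_MM = 1e-9


def delta_d_from_diopter(D: float, f1: float = DEFAULT_F1_MM) -> float:
    """Signed retina offset (mm) from the second focal plane for ametropia ``D``.

    ``delta_d = -f1^2 D / (1 + f1 D)`` with ``f1`` in metres inside the
    product; the result is returned in mm.  A myopic (negative) diopter yields
    a positive offset: the retina sits beyond the focal plane.

    Raises
    ------
    ValueError
        If ``f1 <= 0`` or the denominator ``1 + f1*D`` vanishes (non-physical
        diopter for the given focal length).
    """
    if f1 <= 0:
        raise ValueError(f"f1 must be positive, got {f1}")
    f1_m = f1 * 1e-3
    denom = 1.0 + f1_m * D
    if abs(denom) < 1e-12:
        raise ValueError(
            f"non-physical diopter {D} for f1 = {f1} mm (singular 1 + f1*D)"
        )
    delta_d_m = -(f1_m**2) * D / denom
    return delta_d_m * 1e3


def diopter_from_delta_d(delta_d: float, f1: float = DEFAULT_F1_MM) -> float:
    """Inverse of :func:`delta_d_from_diopter`: ``D = -delta_d/(f1 (f1+delta_d))``.

    Arguments in mm, ``f1`` converted to metres internally so the result is in
    diopters.
    """
    if f1 <= 0:
        raise ValueError(f"f1 must be positive, got {f1}")
    f1_m = f1 * 1e-3
    dd_m = delta_d * 1e-3
    denom = f1_m * (f1_m + dd_m)
    if abs(denom) < 1e-18:
        raise ValueError("singular geometry: f1 + delta_d must not vanish")
    return -dd_m / denom


def magnification(f0: float, f1: float = DEFAULT_F1_MM, delta_d: float = 0.0) -> float:
    """Fundus-image magnification ``m = f0 / (f1 + delta_d)``.

    ``f0`` is the camera focal length (mm).  Requires ``f1 + delta_d > 0``.
    """
    denom = f1 + delta_d
    if denom <= 0:
        raise ValueError(f"f1 + delta_d must be positive, got {denom}")
    return f0 / denom


def magnification_bias(delta_d: float, f1: float = DEFAULT_F1_MM) -> float:
    """Relative magnification deviation ``delta_d / f1`` of an ametropic eye.

    A 1 mm retina offset at f1 = 17 mm gives 0.059, i.e. a 5.9% bias relative
    to the emmetropic magnification.
    """
    if f1 <= 0:
        raise ValueError(f"f1 must be positive, got {f1}")
    return delta_d / f1


def roi_fundus_diameter(
    alpha: float, f1: float = DEFAULT_F1_MM, delta_d: float = 0.0
) -> float:
    """Physical arc length ``L_ROI = alpha (f1 + delta_d)`` of the ROI on the retina.

    ``alpha`` is the field of view in radians; ``f1 + delta_d`` approximates
    the radius of the retinal sphere.  Result in mm.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if f1 + delta_d <= 0:
        raise ValueError("f1 + delta_d must be positive")
    return alpha * (f1 + delta_d)


def compensate_pitch(P_disc: float, D: float, f1: float = DEFAULT_F1_MM) -> float:
    """Diopter-compensated pixel pitch ``P' = P (f1 + delta_d) / f1`` (um).

    The pitch around the disc scales with the retinal-sphere radius; when the
    eye's ametropia ``D`` is known the statistical estimate can be corrected
    for the individual eye.
    """
    delta_d = delta_d_from_diopter(D, f1)
    return P_disc * ((f1 + delta_d) / f1)  # ratio first: exact identity at D = 0


@dataclass
class EyeCameraModel:
    """Reduced-eye plus camera constants.

    Parameters
    ----------
    f1 : first focal length of the eye in air, mm.
    f2p : second focal length in the vitreous, mm (informational).
    a : axial length, mm (informational).
    f0 : camera focal length, mm; unknown for most clinical cameras.
    alpha : field of view, radians.
    D : axial ametropia, diopters (signed).
    delta_d : retina offset from the second focal plane, mm (signed).  If
        omitted it is derived from ``D``; if both are given they must agree
        through the ametropia relation to 1e-9 mm.
    """

    f1: float = DEFAULT_F1_MM
    f2p: float = DEFAULT_F1_MM * N_VITREOUS
    a: float = DEFAULT_AXIAL_LENGTH_MM
    f0: float | None = None
    alpha: float = math.radians(45.0)
    D: float = 0.0
    delta_d: float | None = None

    def __post_init__(self) -> None:
        if self.f1 <= 0:
            raise ValueError("f1 must be positive")
        if not 0.0 < self.alpha < math.pi:
            raise ValueError("alpha must lie in (0, pi)")
        implied = delta_d_from_diopter(self.D, self.f1)
        if self.delta_d is None:
            self.delta_d = implied
        elif abs(self.delta_d - implied) > _CONSISTENCY_TOL_MM:
            raise ValueError(
                f"delta_d = {self.delta_d} mm inconsistent with D = {self.D} D "
                f"(expected {implied} mm)"
            )

    @property
    def roi_diameter_mm(self) -> float:
        """Physical ROI diameter on the retina for this eye and FOV."""
        return roi_fundus_diameter(self.alpha, self.f1, self.delta_d)

    def magnification(self) -> float:
        """Image magnification; requires a known camera focal length ``f0``."""
        if self.f0 is None:
            raise ValueError("camera focal length f0 is not set")
        return magnification(self.f0, self.f1, self.delta_d)
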