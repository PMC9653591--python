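"""Two-phase calibration workflow over image batches.

Offline: measure ROI and disc diameters on every image of a cohort, drop the
failures (and, when diopters are known, seriously ametropic eyes), and pool
the per-image ratios into :class:`~funduscalib.calibrate.RatioStatistics`.

Online: measure only the ROI of a single image and convert it to a pixel
pitch with a stored ratio and a disc-diameter prior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import calibrate as cal
from .calibrate import DiscDiameterPrior, PitchEstimate, RatioStatistics
from .disc import DiscConfig, DiscLocator, measure_disc
from .errors import CalibrationError
from .image import FundusImage, load_fundus_image
from .optics import DEFAULT_F1_MM, compensate_pitch
from .roi import RoiConfig, detect_roi

logger = logging.getLogger("funduscalib")

__all__ = ["ImageMeasurement", "measure_image", "run_offline", "run_online"]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class ImageMeasurement:
    """Per-image detection results (NaNs/None where a stage failed)."""

    id: str
    camera_label: str = ""
    roi_center_xy: tuple[float, float] | None = None
    roi_diameter_px: float | None = None
    roi_votes: float | None = None
    roi_cropped: tuple[bool, bool, bool, bool] | None = None
    disc_center_xy: tuple[float, float] | None = None
    disc_diameter_px: float | None = None
    n_edge_points: int = 0
    diopter: float | None = None
    error: str | None = None

    def to_row(self) -> dict:
        cx, cy = self.roi_center_xy or (float("nan"), float("nan"))
        dx, dy = self.disc_center_xy or (float("nan"), float("nan"))
        return {
            "id": self.id,
            "camera_label": self.camera_label,
            "center_x": cx,
            "center_y": cy,
            "roi_diameter_px": self.roi_diameter_px,
            "votes": self.roi_votes,
            "cropped_flags": "".join(
                "LTRB"[i] for i, f in enumerate(self.roi_cropped or ()) if f
            ),
            "disc_center_x": dx,
            "disc_center_y": dy,
            "disc_diameter_px": self.disc_diameter_px,
            "n_edge_points": self.n_edge_points,
            "diopter": self.diopter,
            "error": self.error or "",
        }


def measure_image(
    image: FundusImage,
    roi_config: RoiConfig | None = None,
    disc_config: DiscConfig | None = None,
    locator: DiscLocator | None = None,
    with_disc: bool = True,
) -> ImageMeasurement:
    """Run ROI (and optionally disc) detection on one image, catching failures."""
    m = ImageMeasurement(id=image.id, camera_label=image.camera_label)
    try:
        roi = detect_roi(image, roi_config)
    except (CalibrationError, ValueError) as exc:
        m.error = f"roi: {exc}"
        return m
    m.roi_center_xy = roi.center_xy
    m.roi_diameter_px = roi.diameter_px
    m.roi_votes = roi.votes
    m.roi_cropped = roi.cropped
    if with_disc:
        try:
            disc = measure_disc(image, roi=roi, locator=locator, config=disc_config)
        except (CalibrationError, ValueError) as exc:
            m.error = f"disc: {exc}"
            return m
        m.disc_center_xy = disc.center_xy
        m.disc_diameter_px = disc.diameter_px
        m.n_edge_points = disc.n_edge_points
    return m


def _iter_images(image_dir: Path) -> Iterable[Path]:
    return sorted(p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)


def run_offline(
    image_dir: str | Path,
    scope: str = "FOV45",
    roi_config: RoiConfig | None = None,
    disc_config: DiscConfig | None = None,
    locator: DiscLocator | None = None,
    metadata_csv: str | Path | None = None,
    max_abs_diopter: float = cal.DEFAULT_DIOPTER_EXCLUSION,
    per_image_csv: str | Path | None = None,
) -> RatioStatistics:
    """Offline statistical calibration over a directory of fundus images.

    Unreadable images and per-image detection failures are logged and
    skipped, never aborting the batch.  ``metadata_csv`` may supply per-image
    ``id,diopter`` columns used for the serious-ametropia exclusion gate.
    Raises ``ValueError`` if no image yields a valid measurement.
    """
    image_dir = Path(image_dir)
    diopters: dict[str, float] = {}
    if metadata_csv is not None:
        meta = pd.read_csv(metadata_csv)
        if "id" in meta.columns and "diopter" in meta.columns:
            diopters = dict(zip(meta["id"].astype(str), meta["diopter"].astype(float)))

    measurements: list[ImageMeasurement] = []
    for path in _iter_images(image_dir):
        try:
            img = load_fundus_image(path)
        except Exception as exc:  # unreadable file: warn, keep going
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            continue
        m = measure_image(img, roi_config, disc_config, locator)
        m.diopter = diopters.get(m.id)
        if m.error:
            logger.warning("detection failed on %s (%s)", path.name, m.error)
        measurements.append(m)

    if per_image_csv is not None:
        pd.DataFrame([m.to_row() for m in measurements]).to_csv(per_image_csv, index=False)

    kept = cal.filter_measurements(
        [
            {
                "roi_diameter_px": m.roi_diameter_px,
                "disc_diameter_px": m.disc_diameter_px,
                "diopter": m.diopter,
            }
            for m in measurements
        ],
        max_abs_diopter=max_abs_diopter,
    )
    if not kept:
        raise ValueError(f"no valid measurements in {image_dir}")
    return cal.offline_calibrate(
        [(rec["roi_diameter_px"], rec["disc_diameter_px"]) for rec in kept], scope=scope
    )


def run_online(
    image: FundusImage,
    ratio: RatioStatistics,
    prior: DiscDiameterPrior,
    roi_config: RoiConfig | None = None,
    diopter: float | None = None,
    iso_pitch_um: float | None = None,
    f1_mm: float = DEFAULT_F1_MM,
) -> PitchEstimate:
    """Online single-image pitch estimate from the measured ROI diameter.

    Only the ROI is measured (no disc is needed online).  The offline
    cohort's ROI spread stands in for the single image's measurement
    uncertainty.  An available diopter applies the ametropia compensation;
    an available ISO reference pitch adds the bias columns.
    """
    roi = detect_roi(image, roi_config)
    P = cal.estimate_pitch(ratio.r_mean, prior.L_disc, roi.diameter_px)
    if diopter is not None:
        P = compensate_pitch(P, diopter, f1_mm)
    U = cal.propagate_uncertainty(
        P,
        ratio.r_mean,
        ratio.r_std,
        prior.L_disc,
        prior.U_Ldisc,
        roi.diameter_px,
        ratio.lroi_std,
    )
    scenario = "FOV-specified" if ratio.scope.upper().startswith("FOV") else "camera-specified"
    return PitchEstimate(P_disc=P, U_Pdisc=U, scenario=scenario, P_iso=iso_pitch_um)


def ratio_to_json(ratio: RatioStatistics, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ratio.to_dict(), indent=2) + "\n")


def ratio_from_json(path: str | Path) -> RatioStatistics:
    d = json.loads(Path(path).read_text())
    return RatioStatistics(
        scope=d["scope"],
        r_mean=d["r_mean"],
        r_std=d["r_std"],
        n=d["n"],
        lroi_mean=d["lroi_mean"],
        lroi_std=d["lroi_std"],
        r_mean_of_means=d.get("r_mean_of_means", float("nan")),
    )


def prior_to_json(prior: DiscDiameterPrior, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"L_disc_mm": prior.L_disc, "U_Ldisc_mm": prior.U_Ldisc, "source": prior.source},
            indent=2,
        )
        + "\n"
    )


def prior_from_json(path: str | Path) -> DiscDiameterPrior:
    d = json.loads(Path(path).read_text())
    return DiscDiameterPrior(
        L_disc=d["L_disc_mm"], U_Ldisc=d["U_Ldisc_mm"], source=d.get("source", "")
    )
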