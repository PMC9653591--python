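"""Shared fixtures: all test imagery is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from funduscalib.synth import (
    DESK_PROFILES,
    CameraProfile,
    PopulationModel,
    RenderConfig,
    render_fundus,
    sample_ground_truths,
)


@pytest.fixture(scope="session")
def canon_profile() -> CameraProfile:
    return DESK_PROFILES["canon"]


@pytest.fixture(scope="session")
def full_circle_profile() -> CameraProfile:
    """Uncropped 500 px ROI centered in a 560 x 540 frame."""
    return CameraProfile(
        name="full500",
        image_size=(560, 540),
        roi_diameter_px=500.0,
        roi_diameter_std_px=0.0,
        pitch_um_truth=26.0,
    )


@pytest.fixture(scope="session")
def rendered_fixture(canon_profile):
    """One deterministic rendered frame plus its ground truth."""
    truth = sample_ground_truths(canon_profile, 1, seed=42)[0]
    image = render_fundus(canon_profile, truth, seed=42)
    return image, truth


@pytest.fixture(scope="session")
def clean_render_config() -> RenderConfig:
    """Noise- and vessel-free rendering for geometry-only checks."""
    return RenderConfig(noise_sigma=0.0, n_vessels=0)


@pytest.fixture(scope="session")
def circular_disc_population() -> PopulationModel:
    """Population whose discs are perfect circles (axis ratio 1)."""
    return PopulationModel(disc_axis_ratio=1.0)
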