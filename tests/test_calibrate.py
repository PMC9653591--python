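"""Calibration arithmetic: ratios, pitch, uncertainty, ISO reference, bias."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from funduscalib.calibrate import (
    estimate_pitch,
    filter_measurements,
    iso_pitch,
    mean_pixel_pitch,
    offline_calibrate,
    pitch_bias,
    propagate_uncertainty,
    roi_disc_ratio,
    sensitivity_to_prior,
)


class TestMeanPixelPitch:
    def test_45_degree_roi(self):
        assert mean_pixel_pitch(13.352, 2000.0) == pytest.approx(6.676, abs=1e-3)

    def test_unity(self):
        assert mean_pixel_pitch(1e-3, 1.0) == pytest.approx(1.0)

    def test_inverse_in_pixel_count(self):
        assert mean_pixel_pitch(13.0, 4000.0) == pytest.approx(
            mean_pixel_pitch(13.0, 2000.0) / 2
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mean_pixel_pitch(0.0, 100.0)


class TestRoiDiscRatio:
    def test_canon_camera_ratio(self):
        assert roi_disc_ratio(1802.4, 291.4) == pytest.approx(6.186, abs=2e-3)

    def test_equal_diameters(self):
        assert roi_disc_ratio(300.0, 300.0) == 1.0

    def test_round_trip(self):
        r = roi_disc_ratio(1920.0, 300.0)
        assert r * 300.0 == pytest.approx(1920.0, rel=1e-12)

    def test_zero_disc_rejected(self):
        with pytest.raises(ValueError):
            roi_disc_ratio(1920.0, 0.0)


class TestOfflineCalibrate:
    def test_single_pair(self):
        stats = offline_calibrate([(1920.0, 300.0)], scope="camX")
        assert stats.r_mean == pytest.approx(6.4)
        assert stats.r_std == 0.0
        assert stats.n == 1

    def test_recovers_generating_ratio_within_three_se(self):
        rng = np.random.default_rng(1)
        n = 2000
        lroi = np.full(n, 1800.0)
        ratios = rng.normal(6.40, 0.6, size=n)
        pairs = list(zip(lroi, lroi / ratios))
        stats = offline_calibrate(pairs)
        se = stats.r_std / np.sqrt(n)
        assert abs(stats.r_mean - 6.40) < 3 * se
        assert abs(stats.r_mean - 6.40) < 0.04

    def test_duplication_leaves_statistics_unchanged(self):
        pairs = [(1800.0, 280.0), (1810.0, 290.0), (1795.0, 275.0)]
        a = offline_calibrate(pairs)
        b = offline_calibrate(pairs * 2)
        assert b.r_mean == pytest.approx(a.r_mean, rel=1e-12)
        assert b.r_std == pytest.approx(a.r_std, rel=1e-12)
        assert b.lroi_std == pytest.approx(a.lroi_std, rel=1e-12)

    def test_population_std_convention(self):
        stats = offline_calibrate([(1800.0, 300.0), (1800.0, 280.0)])
        ratios = np.array([6.0, 1800.0 / 280.0])
        assert stats.r_std == pytest.approx(float(ratios.std(ddof=0)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            offline_calibrate([])


class TestEstimatePitch:
    @pytest.mark.parametrize(
        "r, l_roi, expected",
        [
            (6.404, 1802.4, 6.825),  # FOV-wide ratio, Canon-class ROI
            (6.186, 1802.4, 6.593),  # camera-specific ratio
            (6.404, 2123.717, 5.793),  # Zeiss-class ROI
        ],
    )
    def test_printed_scenarios(self, r, l_roi, expected):
        assert round(estimate_pitch(r, 1.921, l_roi), 3) == expected

    def test_ratio_pitch_composition_is_disc_scale_identity(self):
        l_roi, l_disc, L = 1987.3, 310.7, 1.902
        P = estimate_pitch(roi_disc_ratio(l_roi, l_disc), L, l_roi)
        assert P == pytest.approx(L * 1000.0 / l_disc, abs=1e-9)


class TestPropagateUncertainty:
    def test_printed_fov_canon_uncertainty(self):
        P = estimate_pitch(6.404, 1.921, 1802.4)
        U = propagate_uncertainty(P, 6.404, 0.619, 1.921, 0.026, 1802.4, 0.473)
        assert round(U, 3) == 0.666

    def test_zero_uncertainties(self):
        assert propagate_uncertainty(6.8, 6.4, 0, 1.921, 0, 1802.4, 0) == 0.0

    def test_dominates_each_component(self):
        P = 6.825
        U = propagate_uncertainty(P, 6.404, 0.619, 1.921, 0.026, 1802.4, 0.473)
        for rel in (0.619 / 6.404, 0.026 / 1.921, 0.473 / 1802.4):
            assert U / P >= rel

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(min_value=0.001, max_value=0.2), st.floats(min_value=0.001, max_value=0.2))
    def test_invariant_under_exchanging_relative_uncertainties(self, rel_a, rel_b):
        # which factor carries which relative uncertainty cannot matter
        P = estimate_pitch(6.404, 1.921, 1802.4)
        u1 = propagate_uncertainty(P, 6.404, rel_a * 6.404, 1.921, rel_b * 1.921, 1802.4, 0)
        u2 = propagate_uncertainty(P, 6.404, rel_b * 6.404, 1.921, rel_a * 1.921, 1802.4, 0)
        assert u1 == pytest.approx(u2, rel=1e-12)


class TestIsoPitch:
    def test_unit(self):
        assert iso_pitch(1700.0) == 1.0

    def test_quarter_kilopixel(self):
        assert iso_pitch(250.0) == pytest.approx(6.8)

    def test_canon_reference(self):
        assert iso_pitch(246.5) == pytest.approx(6.897, abs=1e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            iso_pitch(0.0)


class TestPitchBias:
    def test_zero_bias(self):
        assert pitch_bias(6.897, 6.897) == (0.0, 0.0)

    def test_camera_specified_canon(self):
        P = estimate_pitch(6.186, 1.921, 1802.4)
        _, rel = pitch_bias(P, 6.897)
        assert rel == pytest.approx(-4.402, abs=0.01)

    def test_sign_convention(self):
        d, rel = pitch_bias(7.0, 6.897)
        assert d > 0 and rel > 0


class TestSensitivityToPrior:
    CAMERAS = [
        ("canon", 1802.4, 6.897),
        ("topcon", 1856.96, 6.807),
        ("zeiss", 2123.717, 5.693),
        ("newvision", 2090.61, 6.050),
    ]

    def test_smallest_reported_diameter(self):
        rows = sensitivity_to_prior([1.82], 6.404, self.CAMERAS)
        biases = [r["delta_P_rel_pct"] for r in rows]
        for got, expected in zip(biases, [-6.2, -7.8, -3.6, -7.8]):
            assert got == pytest.approx(expected, abs=0.1)

    def test_reference_prior_reproduces_fov_biases(self):
        rows = sensitivity_to_prior([1.921], 6.404, self.CAMERAS)
        for row, expected in zip(rows, [-1.033, -2.673, 1.759, -2.733]):
            assert row["delta_P_rel_pct"] == pytest.approx(expected, abs=0.01)

    def test_bias_monotone_in_prior(self):
        rows = sensitivity_to_prior([1.82, 1.921, 2.0], 6.404, [self.CAMERAS[0]])
        biases = [r["delta_P_rel_pct"] for r in rows]
        assert biases[0] < biases[1] < biases[2]


class TestFilterMeasurements:
    def test_drops_failures_and_serious_ametropia(self):
        recs = [
            {"roi_diameter_px": 1800.0, "disc_diameter_px": 280.0, "diopter": -1.0},
            {"roi_diameter_px": None, "disc_diameter_px": 280.0, "diopter": 0.0},
            {"roi_diameter_px": 1800.0, "disc_diameter_px": 280.0, "diopter": -8.5},
            {"roi_diameter_px": 1800.0, "disc_diameter_px": 281.0},  # no diopter: keep
        ]
        kept = filter_measurements(recs)
        assert len(kept) == 2
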