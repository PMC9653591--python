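"""Disc measurement: locating, polar edge detection, farthest-pair fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from funduscalib.disc import (
    DiscConfig,
    detect_disc_edge,
    fit_circumscribed_circle,
    inverse_polar,
    locate_disc,
    measure_disc,
    polar_transform,
)
from funduscalib.errors import DiscNotFoundError, EdgeTooWeakError
from funduscalib.image import FundusImage
from funduscalib.roi import detect_roi
from funduscalib.synth import render_fundus, sample_ground_truths


def brute_force_farthest_pair(pts: np.ndarray) -> tuple[int, int, float]:
    """Independent O(N^2) oracle with lexicographic tie-break."""
    best = (-1.0, None)
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]))
            if d > best[0]:
                best = (d, (i, j))
    return best[1][0], best[1][1], best[0]


class TestLocateDisc:
    def test_locates_known_center(self, canon_profile, rendered_fixture):
        image, truth = rendered_fixture
        roi = detect_roi(image)
        x, y = locate_disc(image, roi=roi)
        assert np.hypot(x - truth.disc_center[0], y - truth.disc_center[1]) < 10

    def test_uniform_image_rejected(self):
        px = np.full((200, 200, 3), 120, dtype=np.uint8)
        with pytest.raises(DiscNotFoundError):
            locate_disc(FundusImage(pixels=px))

    @pytest.mark.parametrize("seed", [101, 102, 103, 104])
    def test_nasal_offset_both_sides(self, canon_profile, seed):
        # the sampler flips the nasal side at random; over several seeds both occur
        truth = sample_ground_truths(canon_profile, 1, seed=seed)[0]
        image = render_fundus(canon_profile, truth, seed=seed)
        roi = detect_roi(image)
        x, y = locate_disc(image, roi=roi)
        assert np.hypot(x - truth.disc_center[0], y - truth.disc_center[1]) < 10

    def test_custom_locator_strategy(self, rendered_fixture):
        image, truth = rendered_fixture
        external = lambda img, roi, cfg: truth.disc_center  # e.g. a detector box center
        assert locate_disc(image, locator=external) == truth.disc_center


class TestPolarTransform:
    def test_concentric_rings_become_rows(self):
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        rings = np.sin(np.hypot(xx - 128, yy - 128) / 6.0) * 100 + 120
        pol = polar_transform(rings, (128.0, 128.0), n_theta=180, r_max=100.0)
        inner = pol[5:95]  # away from pole and rim
        assert float(np.ptp(inner, axis=1).mean()) < 4.0  # rows ~constant over angle

    def test_round_trip_with_inverse(self):
        yy, xx = np.mgrid[0:200, 0:200].astype(float)
        smooth = 100 + 50 * np.sin(xx / 37.0) * np.cos(yy / 23.0)
        center, r_max = (100.0, 100.0), 90.0
        pol = polar_transform(smooth, center, n_theta=720, r_max=r_max)
        back = inverse_polar(pol, center, (200, 200), r_max)
        rr = np.hypot(xx - center[0], yy - center[1])
        annulus = (rr > 3) & (rr < r_max * 0.95)
        mae = np.abs(back - smooth)[annulus].mean()
        assert mae < 2.0

    def test_center_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            polar_transform(np.zeros((64, 64)), (100.0, 10.0), r_max=20.0)


class TestDetectDiscEdge:
    @staticmethod
    def _disc_image(a, b, size=400, value=200.0, background=80.0):
        """Bright ellipse, semi-axes a (x) and b (y), centered in the frame."""
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        c = (size - 1) / 2.0
        q = np.sqrt(((xx - c) / a) ** 2 + ((yy - c) / b) ** 2)
        img = background + (value - background) * np.clip((1 - q) * min(a, b) + 0.5, 0, 1)
        return img, (c, c)

    def test_circular_disc_radii(self):
        img, center = self._disc_image(120, 120, size=600)
        pol = polar_transform(img, center, n_theta=360, r_max=240.0)
        pts = detect_disc_edge(pol, center, 240.0)
        r = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        assert len(pts) >= 0.9 * 360
        assert ((118 <= r) & (r <= 122)).mean() >= 0.9

    def test_elliptical_disc_matches_polar_radius_oracle(self):
        a, b = 130.0, 110.0
        img, center = self._disc_image(a, b, size=600)
        pol = polar_transform(img, center, n_theta=360, r_max=260.0)
        pts = detect_disc_edge(pol, center, 260.0)
        dx, dy = pts[:, 0] - center[0], pts[:, 1] - center[1]
        theta = np.arctan2(dy, dx)
        r_expect = 1.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)
        rms = float(np.sqrt(np.mean((np.hypot(dx, dy) - r_expect) ** 2)))
        assert rms < 3.0

    def test_featureless_raster_rejected(self):
        with pytest.raises(EdgeTooWeakError):
            detect_disc_edge(np.full((80, 360), 100.0), (100.0, 100.0), 80.0)


class TestFitCircumscribedCircle:
    def test_unit_square(self):
        m = fit_circumscribed_circle([(0, 0), (1, 0), (0, 1), (1, 1)])
        assert m.diameter_px == pytest.approx(np.sqrt(2), abs=1e-12)
        assert m.center_xy == pytest.approx((0.5, 0.5))
        assert m.farthest_pair == (0, 3)  # lexicographic tie-break

    def test_points_on_circle(self):
        t = 2 * np.pi * np.arange(360) / 360
        pts = np.column_stack([5 + 10 * np.cos(t), -3 + 10 * np.sin(t)])
        m = fit_circumscribed_circle(pts)
        assert m.diameter_px == pytest.approx(20.0, abs=0.002)
        assert m.center_xy[0] == pytest.approx(5, abs=0.01)
        assert m.center_xy[1] == pytest.approx(-3, abs=0.01)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-50, 50, size=(50, 2))
        m = fit_circumscribed_circle(pts)
        i, j, d = brute_force_farthest_pair(pts)
        assert m.farthest_pair == (i, j)
        assert m.diameter_px == d

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circumscribed_circle(np.array([[1.0, 2.0]]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_to_order_and_rotation(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 10, size=(30, 2))
        d0 = fit_circumscribed_circle(pts).diameter_px
        perm = rng.permutation(30)
        d1 = fit_circumscribed_circle(pts[perm]).diameter_px
        ang = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        d2 = fit_circumscribed_circle(pts @ R.T).diameter_px
        assert d1 == pytest.approx(d0, abs=1e-9)
        assert d2 == pytest.approx(d0, abs=1e-9)

    def test_large_set_uses_hull_and_agrees(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 30, size=(2500, 2))
        m = fit_circumscribed_circle(pts)
        i, j, d = brute_force_farthest_pair(pts)
        assert m.diameter_px == d
        assert m.farthest_pair == (i, j)


class TestMeasureDiscChain:
    def test_elliptical_disc_reads_major_axis(self, canon_profile, clean_render_config):
        truth = sample_ground_truths(canon_profile, 1, seed=21)[0]
        image = render_fundus(canon_profile, truth, seed=21, config=clean_render_config)
        roi = detect_roi(image)
        disc = measure_disc(image, roi=roi)
        assert disc.diameter_px == pytest.approx(truth.disc_major_px, rel=0.03)

    def test_circular_discs_within_two_percent(
        self, canon_profile, circular_disc_population
    ):
        errs = []
        for seed in range(30):
            truth = sample_ground_truths(
                canon_profile, 1, circular_disc_population, seed=seed
            )[0]
            image = render_fundus(canon_profile, truth, seed=seed)
            disc = measure_disc(image, roi=detect_roi(image))
            errs.append(disc.diameter_px / truth.disc_major_px - 1.0)
        assert max(abs(e) for e in errs) < 0.02
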