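"""Tension-point localization, angular statistics, and cortex morphometry."""

import numpy as np
import pytest

from mechanoquant.imaging import (
    CortexRing,
    TensionPointMap,
    angular_concentration,
    cortex_metrics,
    detect_high_tension_points,
    polarize_points,
    segment_cell_circle,
)
from mechanoquant.synthetic import gen_tension_image


def disk_image(cx=256.0, cy=256.0, r=100.0, size=512, value=200.0):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = value
    return img


class TestSegmentCellCircle:
    def test_recovers_disk(self):
        (cx, cy), r = segment_cell_circle(disk_image())
        assert cx == pytest.approx(256, abs=1)
        assert cy == pytest.approx(256, abs=1)
        assert r == pytest.approx(100, rel=0.02)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            segment_cell_circle(np.zeros((64, 64)))

    def test_small_speckle_ignored(self):
        img = disk_image()
        img[10:13, 10:13] = 200.0  # speckle, area << disk
        (cx, cy), r = segment_cell_circle(img)
        assert cx == pytest.approx(256, abs=1)
        assert r == pytest.approx(100, rel=0.02)


class TestDetectHighTensionPoints:
    @pytest.mark.parametrize("red, detected", [(150, True), (120, True), (180, True),
                                               (100, False), (200, False)])
    def test_window_is_inclusive(self, red, detected):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[16, 20, 0] = red
        pts = detect_high_tension_points(img)
        assert (len(pts) == 1) is detected
        if detected:
            assert pts[0] == (20.0, 16.0)

    def test_cluster_reduced_to_centroid(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[10:13, 20:23, 0] = 150
        pts = detect_high_tension_points(img)
        assert len(pts) == 1
        assert pts[0] == (21.0, 11.0)

    def test_non_uint8_requires_window(self):
        img = np.zeros((8, 8, 3), dtype=float)
        with pytest.raises(ValueError):
            detect_high_tension_points(img)
        assert detect_high_tension_points(img, window=(120, 180)) == []


class TestPolarizePoints:
    def test_axis_point(self):
        pm = polarize_points([(300.0, 200.0)], (200.0, 200.0), 100.0)
        assert pm.points[0].norm_r == pytest.approx(1.0)
        assert pm.points[0].theta == pytest.approx(0.0)

    def test_quarter_turn_with_image_y_down(self):
        # (cx, cy - r) is visually "up"; mathematical convention puts it at 90°
        pm = polarize_points([(200.0, 100.0)], (200.0, 200.0), 100.0)
        assert pm.points[0].theta == pytest.approx(90.0)

    def test_centroid_degenerate_angle(self):
        pm = polarize_points([(200.0, 200.0)], (200.0, 200.0), 100.0)
        assert pm.points[0].norm_r == 0.0
        assert pm.points[0].theta == 0.0

    def test_outside_cell_flagged(self):
        pm = polarize_points([(320.0, 200.0)], (200.0, 200.0), 100.0)
        assert pm.points[0].outside_cell

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            polarize_points([], (0.0, 0.0), 0.0)


def pmap_from_thetas(thetas):
    pts = [
        (100.0 + 50.0 * np.cos(np.radians(t)), 100.0 - 50.0 * np.sin(np.radians(t)))
        for t in thetas
    ]
    return polarize_points(pts, (100.0, 100.0), 50.0)


class TestAngularConcentration:
    def test_single_sector_mass(self):
        conc = angular_concentration(pmap_from_thetas(np.linspace(10, 30, 16)))
        assert conc.max_bin_fraction == 100.0
        assert conc.n_points == 16

    def test_uniform_bin_centers_give_baseline(self):
        conc = angular_concentration(pmap_from_thetas(np.arange(22.5, 360, 45.0)))
        assert np.all(conc.counts == 1)
        assert conc.max_bin_fraction == pytest.approx(12.5)
        assert conc.baseline == 12.5

    def test_half_mass_in_one_bin(self):
        thetas = [10, 12, 14, 16, 18, 60, 110, 160, 210, 260]
        conc = angular_concentration(pmap_from_thetas(thetas))
        assert conc.max_bin_fraction == pytest.approx(50.0)

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            angular_concentration(TensionPointMap((0, 0), 1.0, []))

    def test_uniform_draws_average_to_baseline(self):
        rng = np.random.default_rng(0)
        sums = np.zeros(8)
        n_draws = 1000
        for _ in range(n_draws):
            conc = angular_concentration(pmap_from_thetas(rng.uniform(0, 360, 16)))
            sums += conc.counts
        mean_pct = 100.0 * sums / (16 * n_draws)
        assert np.all(np.abs(mean_pct - 12.5) < 1.0)


class TestRotationCovariance:
    def test_rot90_shifts_theta_and_preserves_radius(self):
        angles = (15.0, 75.0, 200.0)
        img, _ = gen_tension_image(cell_radius=80, point_angles=angles,
                                   image_size=256, seed=0)
        rot = np.rot90(img, k=1, axes=(0, 1)).copy()
        results = []
        for im in (img, rot):
            centroid, radius = segment_cell_circle(np.asarray(im[:, :, 0], float))
            pm = polarize_points(detect_high_tension_points(im), centroid, radius)
            conc = angular_concentration(pm)
            results.append((pm, conc))
        (pm0, c0), (pm1, c1) = results
        t0 = sorted(p.theta for p in pm0.points)
        t1 = sorted((p.theta - 90.0) % 360.0 for p in pm1.points)
        assert np.allclose(t0, t1, atol=1.0)
        r0 = sorted(p.norm_r for p in pm0.points)
        r1 = sorted(p.norm_r for p in pm1.points)
        assert np.allclose(r0, r1, atol=0.02)
        assert c0.max_bin_fraction == c1.max_bin_fraction


class TestCortexMetrics:
    def test_thickness_definition(self):
        ring = CortexRing(8.0, 6.6, 500.0)
        thickness, _ = cortex_metrics(ring)
        assert thickness == pytest.approx(0.7)

    def test_normalized_intensity(self):
        ring = CortexRing(10.0, 9.0, 1000.0)
        _, norm = cortex_metrics(ring)
        assert norm == pytest.approx(1000.0 / (np.pi * 19.0), rel=1e-6)

    def test_empty_ring_rejected(self):
        with pytest.raises(ValueError):
            CortexRing(6.6, 6.6, 100.0)
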