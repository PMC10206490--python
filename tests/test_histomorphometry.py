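"""Contour areas, intima extraction, stain fractions, and aggregation."""

import math

import numpy as np
import pytest

from atheroflow.histomorphometry import (
    ChannelBounds,
    aggregate_sections,
    binary_stain_fraction,
    dual_threshold_picrosirius,
    greyscale_stain_fraction,
    intima_mask,
    plaque_burden,
    polygon_area,
    rasterize_polygon,
)
from atheroflow.synthetic import make_histology_section


def circle(cx, cy, r, n=256):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(UNIT_SQUARE) == pytest.approx(1.0)

    def test_orientation_independent(self):
        assert polygon_area(UNIT_SQUARE[::-1]) == pytest.approx(1.0)

    def test_polygon_approaches_circle(self):
        assert polygon_area(circle(0, 0, 1, n=1000)) == pytest.approx(np.pi, abs=1e-4)

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="simple"):
            polygon_area(bowtie)


class TestIntimaMask:
    def test_identical_contours_empty_intima(self):
        lum = circle(64, 64, 30)
        mask, area = intima_mask(lum, lum, (128, 128))
        assert area == 0 and not mask.any()

    def test_concentric_annulus_area(self):
        mask, _ = intima_mask(circle(64, 64, 50), circle(64, 64, 60), (128, 128))
        assert mask.sum() == pytest.approx(np.pi * (60**2 - 50**2), rel=0.01)

    def test_eccentric_crescent_matches_generator_truth(self):
        section, truth = make_histology_section(0.3, 0.0, offset=0.5, seed=1)
        mask, _ = intima_mask(section.lumen, section.iel, section.stain_image.shape)
        assert mask.sum() == truth["n_intima_px"]

    def test_lumen_outside_iel_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            intima_mask(circle(80, 64, 30), circle(64, 64, 32), (128, 128))


class TestPlaqueBurden:
    def test_healthy_section_zero(self):
        lum = circle(0, 0, 50)
        assert plaque_burden(lum, lum, circle(0, 0, 70)) == 0.0

    def test_concentric_analytic_value(self):
        val = plaque_burden(circle(0, 0, 50), circle(0, 0, 60), circle(0, 0, 70))
        assert val == pytest.approx(100 * (60**2 - 50**2) / 70**2, rel=1e-3)

    def test_occluded_lumen_approaches_full_burden(self):
        tiny = circle(0, 0, 1e-3)
        eel = circle(0, 0, 70)
        assert plaque_burden(tiny, eel, eel) == pytest.approx(100.0, abs=0.1)

    def test_growing_lumen_never_increases_burden(self):
        iel, eel = circle(0, 0, 60), circle(0, 0, 70)
        vals = [plaque_burden(circle(0, 0, r), iel, eel) for r in (20, 35, 50, 59)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestStainFractions:
    def test_full_coverage_is_100(self):
        intima = np.zeros((10, 10), bool)
        intima[2:8, 2:8] = True
        assert binary_stain_fraction(intima.copy(), intima) == 100.0

    def test_synthetic_quarter_coverage_exact(self):
        section, truth = make_histology_section(0.3, 0.25, seed=9)
        mask, _ = intima_mask(section.lumen, section.iel, section.stain_image.shape)
        frac = binary_stain_fraction(section.stain_image > 0, mask)
        assert frac == truth["stain_fraction_pct"]  # exact by construction

    def test_stain_outside_intima_ignored(self):
        intima = np.zeros((10, 10), bool)
        intima[2:8, 2:8] = True
        stain = ~intima
        assert binary_stain_fraction(stain, intima) == 0.0

    def test_greyscale_norm_identity_and_flag(self):
        intima = np.ones((4, 4), bool)
        pct, over = greyscale_stain_fraction(np.full((4, 4), 30.0), intima)
        assert pct == pytest.approx(100.0) and not over
        pct, over = greyscale_stain_fraction(np.full((4, 4), 45.0), intima)
        assert pct == pytest.approx(150.0) and over
        pct, _ = greyscale_stain_fraction(np.full((4, 4), 15.0), intima)
        assert pct == pytest.approx(50.0)
        pct, _ = greyscale_stain_fraction(np.zeros((4, 4)), intima)
        assert pct == 0.0

    def test_empty_intima_is_missing_not_zero(self):
        with pytest.raises(ValueError, match="empty intima"):
            binary_stain_fraction(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    def test_adding_stain_pixels_monotone(self):
        rng = np.random.default_rng(0)
        intima = np.ones((20, 20), bool)
        stain = np.zeros((20, 20), bool)
        prev = 0.0
        for _ in range(5):
            free = np.flatnonzero(intima.ravel() & ~stain.ravel())
            stain.ravel()[rng.choice(free, 10, replace=False)] = True
            cur = binary_stain_fraction(stain, intima)
            assert cur > prev
            prev = cur


class TestDualThreshold:
    def make_image(self):
        img = np.zeros((10, 10, 3))
        img[1:3, 1:3] = [200, 50, 0]   # red/yellow patch (4 px)
        img[5:8, 5:8] = [0, 180, 40]   # green patch (9 px)
        return img

    RED = ChannelBounds(r=(150, 255), g=(0, 100), b=(0, 100))
    GREEN = ChannelBounds(r=(0, 100), g=(120, 255), b=(0, 100))

    def test_disjoint_patches_sum(self):
        mask = dual_threshold_picrosirius(self.make_image(), self.RED, self.GREEN)
        assert mask.sum() == 4 + 9

    def test_overlap_counted_once(self):
        wide_a = ChannelBounds(r=(0, 255), g=(0, 255), b=(0, 50))
        mask = dual_threshold_picrosirius(self.make_image(), wide_a, self.GREEN)
        assert mask.sum() <= wide_a.apply(self.make_image()).sum() + 9

    def test_excluding_thresholds_empty(self):
        none = ChannelBounds(r=(256, 300))
        mask = dual_threshold_picrosirius(self.make_image(), none, none)
        assert not mask.any()


class TestAggregation:
    def test_mean_of_sections(self):
        assert aggregate_sections([8.0, 10.0, 12.0]) == pytest.approx(10.0)

    def test_single_viable_section(self):
        assert aggregate_sections([7.5]) == 7.5

    def test_damaged_section_excluded(self):
        val = aggregate_sections([8, 10, 12, 99], viable=[True, True, True, False],
                                 reasons=["", "", "", "damaged"])
        assert val == pytest.approx(10.0)

    def test_no_viable_sections_is_missing(self):
        assert math.isnan(aggregate_sections([8.0], viable=[False]))
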