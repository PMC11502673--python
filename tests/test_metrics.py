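"""Synaptic-interface metrics: around-bead fraction, extraction, spreading,
recruitment, circularity, foci, intensity summaries."""

import numpy as np
import pytest
from shapely.geometry import Polygon
from skimage.draw import disk
from skimage.measure import perimeter_crofton

from isquant import (
    Bead,
    BeadROI,
    ChannelStack,
    Scene,
    SynapticPlane,
    around_bead_fraction,
    circularity,
    count_foci,
    extraction_remaining,
    intensity_summary,
    recruitment_index,
    spreading_area,
)
from isquant.metrics import (
    DegenerateOutlineError,
    MultiComponentError,
    ZeroIntensityError,
)


def _stack(data, voxel=(0.5, 0.2, 0.2), name="LAMP1"):
    return ChannelStack(name=name, data=np.asarray(data, float), voxel_size=voxel)


# ---------------------------------------------------------------------------
# around-bead fraction
# ---------------------------------------------------------------------------

class TestAroundBeadFraction:
    VOXEL = (0.5, 0.2, 0.2)

    def _setup(self, data):
        ch = _stack(data, self.VOXEL)
        mask = np.ones(data.shape, dtype=bool)
        bead = BeadROI(center=(2.0, 2.0), bead_radius=0.5, analysis_radius=1.0)
        return ch, bead, mask

    def test_all_fluorescence_inside_disc_gives_one(self):
        data = np.zeros((4, 20, 20))
        data[:, 10, 10] = 5.0  # pixel at (x=2.0, y=2.0), bead center
        ch, bead, mask = self._setup(data)
        assert around_bead_fraction(ch, bead, mask) == pytest.approx(1.0)

    def test_no_fluorescence_inside_disc_gives_zero(self):
        data = np.zeros((4, 20, 20))
        data[:, 0, 0] = 5.0  # far corner
        ch, bead, mask = self._setup(data)
        assert around_bead_fraction(ch, bead, mask) == 0.0

    def test_uniform_intensity_equals_pixel_count_ratio(self):
        data = np.ones((3, 20, 20))
        ch, bead, mask = self._setup(data)
        got = around_bead_fraction(ch, bead, mask)
        # direct pixel count of the disc
        count = sum(
            1
            for y in range(20)
            for x in range(20)
            if (x * 0.2 - 2.0) ** 2 + (y * 0.2 - 2.0) ** 2 <= 1.0
        )
        assert got == pytest.approx(count / 400)

    def test_monotone_in_analysis_radius_and_bounded(self, rng):
        data = rng.random((3, 20, 20))
        ch = _stack(data, self.VOXEL)
        mask = np.ones(data.shape, dtype=bool)
        prev = -1.0
        for r in (0.5, 1.0, 2.0, 4.0, 8.0):
            f = around_bead_fraction(
                ch, BeadROI(center=(2.0, 2.0), bead_radius=0.5, analysis_radius=r), mask
            )
            assert 0.0 <= f <= 1.0 and f >= prev
            prev = f
        assert prev == pytest.approx(1.0)  # huge disc covers the cell

    def test_zero_cell_intensity_is_error(self):
        ch, bead, mask = self._setup(np.zeros((2, 20, 20)))
        with pytest.raises(ZeroIntensityError):
            around_bead_fraction(ch, bead, mask)


# ---------------------------------------------------------------------------
# antigen extraction
# ---------------------------------------------------------------------------

class TestExtractionRemaining:
    def _scene(self, scale):
        data = np.zeros((3, 10, 10))
        data[:, 4:7, 4:7] = 10.0 * scale
        return Scene(channels={"Ag": _stack(data, name="Ag")})

    BEAD = BeadROI(center=(1.0, 1.0), bead_radius=0.5, analysis_radius=3.5)

    def test_time_zero_is_exactly_100(self):
        series = [(0, self._scene(1.0)), (60, self._scene(0.73))]
        out = extraction_remaining(series, "Ag", self.BEAD)
        assert out[0] == 100.0

    def test_halved_intensity_is_50(self):
        series = [(0, self._scene(1.0)), (120, self._scene(0.5))]
        assert extraction_remaining(series, "Ag", self.BEAD)[120] == pytest.approx(50.0)

    def test_arbitrary_decay_matches_direct_summation(self, rng):
        scenes = [(t, self._scene(s)) for t, s in [(0, 1.0), (30, 0.8), (60, 0.41)]]
        out = extraction_remaining(scenes, "Ag", self.BEAD)
        # per-pixel accumulation oracle inside the fixed disc
        def disc_sum(scene):
            img = scene.channels["Ag"].data.sum(axis=0)
            total = 0.0
            for y in range(10):
                for x in range(10):
                    if (x * 0.2 - 1.0) ** 2 + (y * 0.2 - 1.0) ** 2 <= 3.5**2:
                        total += img[y, x]
            return total

        base = disc_sum(scenes[0][1])
        for t, scene in scenes:
            assert out[t] == pytest.approx(100.0 * disc_sum(scene) / base)

    def test_missing_time_zero_is_error(self):
        with pytest.raises(ValueError, match="time 0"):
            extraction_remaining([(30, self._scene(1.0))], "Ag", self.BEAD)


# ---------------------------------------------------------------------------
# spreading area
# ---------------------------------------------------------------------------

class TestSpreadingArea:
    def test_mask_pixel_count_times_pixel_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 100 px at 0.1x0.1 μm
        plane = SynapticPlane(z_index=0, images={}, outline=mask, pixel_size=(0.1, 0.1))
        assert spreading_area(plane) == pytest.approx(1.0)

    def test_rasterized_disc_close_to_analytic_area(self):
        mask = np.zeros((240, 240), dtype=bool)
        rr, cc = disk((120, 120), 100)  # 5 μm radius at 0.05 μm pixels
        mask[rr, cc] = True
        plane = SynapticPlane(z_index=0, images={}, outline=mask, pixel_size=(0.05, 0.05))
        assert spreading_area(plane) == pytest.approx(np.pi * 25, rel=0.01)

    def test_polygon_square_shoelace(self):
        poly = Polygon([(0, 0), (2, 0), (2, 2), (0, 2)])
        plane = SynapticPlane(z_index=0, images={}, outline=poly, pixel_size=(0.1, 0.1))
        assert spreading_area(plane) == pytest.approx(4.0)

    def test_empty_outline_is_error(self):
        plane = SynapticPlane(
            z_index=0, images={}, outline=np.zeros((5, 5), bool), pixel_size=(0.1, 0.1)
        )
        with pytest.raises(DegenerateOutlineError):
            spreading_area(plane)


# ---------------------------------------------------------------------------
# recruitment index
# ---------------------------------------------------------------------------

class TestRecruitmentIndex:
    PX = (0.1, 0.1)

    def test_uniform_intensity_gives_zero(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        img = np.where(mask, 3.0, 0.0)
        assert recruitment_index(img, mask, self.PX) == pytest.approx(0.0)

    def test_all_intensity_central_gives_three(self):
        # polygon outline: exact areas, central square is the middle quarter
        poly = Polygon([(0.5, 0.5), (3.5, 0.5), (3.5, 3.5), (0.5, 3.5)])
        img = np.zeros((40, 40))
        img[18:22, 18:22] = 10.0  # well inside the central 1.5..2.5 μm square
        assert recruitment_index(img, poly, self.PX) == pytest.approx(3.0)

    def test_all_intensity_peripheral_gives_minus_one(self):
        poly = Polygon([(0.5, 0.5), (3.5, 0.5), (3.5, 3.5), (0.5, 3.5)])
        img = np.zeros((40, 40))
        img[7:9, 7:9] = 5.0  # inside outline, outside the central square
        assert recruitment_index(img, poly, self.PX) == pytest.approx(-1.0)

    def test_invariant_to_global_intensity_scaling(self, rng):
        mask = np.zeros((30, 30), dtype=bool)
        mask[4:26, 4:26] = True
        img = rng.random((30, 30)) * mask
        a = recruitment_index(img, mask, self.PX)
        b = recruitment_index(img * 37.5, mask, self.PX)
        assert a == pytest.approx(b) and a >= -1.0

    def test_central_raster_region_has_quarter_area(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:55, 5:55] = True
        from isquant.metrics import _central_region_mask

        central = _central_region_mask(mask)
        assert central.sum() / mask.sum() == pytest.approx(0.25, rel=0.05)
        assert not np.any(central & ~mask)

    def test_zero_intensity_is_error(self):
        mask = np.ones((10, 10), dtype=bool)
        with pytest.raises(ZeroIntensityError):
            recruitment_index(np.zeros((10, 10)), mask, self.PX)


# ---------------------------------------------------------------------------
# circularity
# ---------------------------------------------------------------------------

class TestCircularity:
    def test_circle_polygon_approaches_one(self):
        theta = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
        poly = Polygon(np.column_stack([np.cos(theta), np.sin(theta)]))
        assert circularity(poly) == pytest.approx(1.0, abs=1e-4)

    def test_square_polygon_is_pi_over_four(self):
        poly = Polygon([(0, 0), (3, 0), (3, 3), (0, 3)])
        assert circularity(poly) == pytest.approx(np.pi / 4)

    def test_raster_ellipse_matches_crofton_oracle(self):
        """4πA/P² with P from an independent Crofton-formula estimate, within 2%."""
        yy, xx = np.mgrid[0:120, 0:160]
        mask = ((yy - 60) / 40.0) ** 2 + ((xx - 80) / 60.0) ** 2 <= 1.0
        got = circularity(mask, pixel_size=(1.0, 1.0))
        p_crofton = perimeter_crofton(mask, directions=4)
        expected = 4 * np.pi * mask.sum() / p_crofton**2
        assert got == pytest.approx(expected, rel=0.02)

    def test_rugosity_decreases_circularity(self, rng):
        yy, xx = np.mgrid[0:100, 0:100]
        smooth = (yy - 50) ** 2 + (xx - 50) ** 2 <= 35**2
        # radial perturbation of the boundary
        ang = np.arctan2(yy - 50, xx - 50)
        r = np.sqrt((yy - 50) ** 2 + (xx - 50) ** 2)
        rough = r <= 35 + 4 * np.sin(9 * ang)
        assert circularity(rough, (1.0, 1.0)) < circularity(smooth, (1.0, 1.0))

    def test_convex_shapes_do_not_exceed_one(self):
        for n in (8, 64, 512):
            theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
            poly = Polygon(np.column_stack([np.cos(theta), 0.5 * np.sin(theta)]))
            assert circularity(poly) <= 1.0 + 1e-6

    def test_multi_component_mask_is_error(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        with pytest.raises(MultiComponentError):
            circularity(mask, (1.0, 1.0))


# ---------------------------------------------------------------------------
# foci counting and intensity summaries
# ---------------------------------------------------------------------------

class TestCountFoci:
    def _plane(self, img):
        outline = np.ones(img.shape, dtype=bool)
        return SynapticPlane(
            z_index=0, images={"actin": img}, outline=outline, pixel_size=(0.1, 0.1)
        )

    def test_three_discs_counted(self):
        img = np.zeros((60, 60))
        for cy, cx in [(10, 10), (30, 40), (50, 20)]:
            rr, cc = disk((cy, cx), 4)  # ~0.5 μm² each
            img[rr, cc] = 100.0
        assert count_foci(self._plane(img), "actin", 0.10, 4.00) == 3

    def test_empty_plane_counts_zero(self):
        assert count_foci(self._plane(np.zeros((20, 20))), "actin", 0.10, 4.00) == 0

    def test_oversized_focus_excluded(self):
        img = np.zeros((60, 60))
        rr, cc = disk((30, 30), 16)  # ~8 μm²
        img[rr, cc] = 100.0
        assert count_foci(self._plane(img), "actin", 0.10, 4.00) == 0


class TestIntensitySummary:
    def test_constant_image(self):
        s = intensity_summary(np.full((8, 8), 3.5), np.ones((8, 8), bool), (0.2, 0.2))
        assert s.mean == pytest.approx(3.5)
        assert s.integrated == pytest.approx(3.5 * 64)

    def test_checkerboard_mean(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 10.0
        s = intensity_summary(img, np.ones((8, 8), bool), (0.1, 0.1))
        assert s.mean == pytest.approx(5.0)

    def test_matches_direct_summation(self, rng):
        img = rng.random((12, 12))
        mask = rng.random((12, 12)) > 0.5
        s = intensity_summary(img, mask, (0.3, 0.2))
        total = sum(
            img[y, x] for y in range(12) for x in range(12) if mask[y, x]
        )
        assert s.integrated == pytest.approx(total)
        assert s.mean == pytest.approx(total / mask.sum())
        assert s.area_um2 == pytest.approx(mask.sum() * 0.06)
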