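"""Section geometry, alignment, binning, and pixelwise statistics."""

from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Polygon

from icbkit import spatial as sp
from icbkit.spatial import (
    ActivityMap,
    AlignmentTransform,
    GridSpec,
    StriatalSection,
)


def square_section(side=2000.0, n_cells=0, lesion=None, seed=0, **kw):
    half = side / 2
    outline = np.array(
        [[-half, -half], [half, -half], [half, half], [-half, half]]
    )
    rng = np.random.default_rng(seed)
    cells = rng.uniform(-half, half, size=(n_cells, 2))
    return StriatalSection("a0", kw.pop("hemisphere", "left"), 1.08, outline,
                           cells, lesion=lesion, **kw)


class TestLesionExtent:
    def test_no_lesion_100pct(self):
        assert sp.lesion_extent(square_section()) == 100.0

    def test_lesion_equals_outline_0pct(self):
        s = square_section()
        s.lesion = s.outline.copy()
        assert sp.lesion_extent(s) == pytest.approx(0.0)

    def test_half_linear_size_75pct(self):
        half = 500.0
        lesion = np.array(
            [[-half, -half], [half, -half], [half, half], [-half, half]]
        )
        s = square_section(side=2000.0, lesion=lesion)
        assert sp.lesion_extent(s) == pytest.approx(75.0)


class TestCellDensity:
    def test_known_density(self):
        s = square_section(side=1000.0, n_cells=100)  # 1 mm^2
        assert sp.cell_density(s, "total") == pytest.approx(100.0)

    def test_empty_region_zero(self):
        assert sp.cell_density(square_section(side=1000.0), "total") == 0.0

    def test_matches_point_in_polygon_oracle(self):
        rng = np.random.default_rng(1)
        s = square_section(side=2000.0, n_cells=0)
        s.cells = rng.uniform(-1500, 1500, size=(400, 2))  # some outside
        poly = Polygon(s.outline)
        from shapely.geometry import Point

        inside = sum(poly.contains(Point(*c)) for c in s.cells)
        assert sp.cell_density(s, "total") == pytest.approx(
            inside / (poly.area / 1e6)
        )


class TestFlip:
    def test_left_unchanged(self):
        s = square_section()
        assert sp.flip_right(s) is s

    def test_double_flip_identity(self):
        s = square_section(hemisphere="right", n_cells=10)
        once = sp.flip_right(s)
        assert once.hemisphere == "left"
        twice = replace(once, hemisphere="right")
        back = sp.flip_right(twice)
        assert np.allclose(back.cells, s.cells)
        assert np.allclose(back.outline, s.outline)


class TestAlignment:
    @staticmethod
    def _blob(seed=0):
        from icbkit.synthetic import default_outline

        return default_outline()

    def test_identity_on_identical_outlines(self):
        out = self._blob()
        s = StriatalSection("a", "left", 1.08, out, np.zeros((0, 2)))
        tr = sp.align_section(s, out)
        assert tr.residual < 1.0
        assert abs(tr.rotation) < 0.01
        assert tr.scale == pytest.approx(1.0, abs=0.01)

    def test_known_transform_recovered_within_1pct(self):
        out = self._blob()
        known = AlignmentTransform(np.deg2rad(10.0), 1.1, (300.0, -150.0))
        s = StriatalSection("a", "left", 1.08, known.apply(out), np.zeros((0, 2)))
        tr = sp.align_section(s, out)
        assert tr.rotation == pytest.approx(-np.deg2rad(10.0), abs=np.deg2rad(0.1))
        assert tr.scale == pytest.approx(1 / 1.1, rel=0.01)

    def test_transform_inverse_roundtrip(self):
        tr = AlignmentTransform(0.3, 1.2, (100.0, -50.0))
        pts = np.random.default_rng(0).uniform(-1000, 1000, (20, 2))
        back = tr.inverse().apply(tr.apply(pts))
        assert np.allclose(back, pts, atol=1e-6)

    def test_jittered_outline_residual_bounded(self):
        from icbkit.synthetic import SectionGenParams, gen_sections

        secs = gen_sections(SectionGenParams(base_intensity=0.0, jitter=60.0,
                                             n_animals=1, levels_per_animal=1,
                                             hemispheres=1, seed=3))
        tr = sp.align_section(secs[0], self._blob())
        assert tr.residual <= 3 * 60.0

    def test_prerotation_leaves_map_unchanged(self):
        """Alignment equivariance: rotating a section before mapping
        changes its activity map only by discretisation error."""
        from icbkit.synthetic import SectionGenParams, gen_sections

        secs = gen_sections(SectionGenParams(n_animals=1, levels_per_animal=1,
                                             hemispheres=1, jitter=0.0, seed=4))
        s = secs[0]
        ref = self._blob()
        grid = GridSpec.from_reference(ref)
        rot = AlignmentTransform(0.6, 1.0, (0.0, 0.0))
        s_rot = replace(s, outline=rot.apply(s.outline), cells=rot.apply(s.cells))
        maps = []
        for sec in (s, s_rot):
            tr = sp.align_section(sec, ref)
            maps.append(sp.bin_cells(sp.apply_alignment(sec, tr), grid))
        diff = np.abs(maps[0].counts.astype(float) - maps[1].counts).mean()
        assert diff * grid.n_pixels <= 0.05 * maps[0].total


class TestBinning:
    def test_single_cell_at_bin_centre(self):
        grid = GridSpec(n=75, bin_um=80.0, origin=(0.0, 0.0))
        s = square_section(side=12000.0)
        s.cells = np.array([[40.0 + 80.0 * 10, 40.0 + 80.0 * 20]])
        amap = sp.bin_cells(s, grid)
        assert amap.counts[20, 10] == 1
        assert amap.total == 1

    def test_mass_conservation(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(n=75, bin_um=80.0, origin=(-3000.0, -3000.0))
        s = square_section(side=5000.0)
        s.cells = rng.uniform(-4000, 4000, size=(1000, 2))  # some off-grid
        amap = sp.bin_cells(s, grid)
        assert amap.total + amap.n_outside == 1000

    def test_grid_flattens_to_5625(self):
        grid = GridSpec()
        assert grid.n_pixels == 5625
        amap = ActivityMap(np.zeros((75, 75), dtype=int), grid)
        assert amap.flatten().shape == (5625,)


class TestGroupComparison:
    @staticmethod
    def _maps(rng, n, lam, grid, bump=None):
        maps = []
        for _ in range(n):
            counts = rng.poisson(lam, size=(grid.n, grid.n))
            if bump is not None:
                sl, amount = bump
                counts[sl] += rng.poisson(amount, size=counts[sl].shape)
            maps.append(ActivityMap(counts, grid))
        return maps

    def test_identical_groups_zero_diff_and_empty_mask(self):
        grid = GridSpec(n=20, bin_um=80.0)
        rng = np.random.default_rng(6)
        a = self._maps(rng, 5, 3.0, grid)
        mask = np.ones((20, 20), dtype=bool)
        diff = sp.group_difference_map(a, a, mask)
        assert np.nanmax(np.abs(diff)) == 0.0
        stat = sp.pixelwise_test(a, a, mask)
        assert not stat.significant.any()

    def test_constant_offset_diff(self):
        grid = GridSpec(n=10, bin_um=80.0)
        base = ActivityMap(np.full((10, 10), 4), grid)
        plus = ActivityMap(np.full((10, 10), 7), grid)
        mask = np.ones((10, 10), dtype=bool)
        diff = sp.group_difference_map([plus], [base], mask)
        assert np.allclose(diff, 3.0)

    def test_shifted_block_detected(self):
        """A strong shift confined to one pixel block is flagged there
        and (almost) only there."""
        grid = GridSpec(n=20, bin_um=80.0)
        mask = np.ones((20, 20), dtype=bool)
        block = (slice(5, 10), slice(5, 10))
        hits, false = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = self._maps(rng, 10, 3.0, grid, bump=(block, 30.0))
            b = self._maps(rng, 10, 3.0, grid)
            stat = sp.pixelwise_test(a, b, mask, alpha=0.01)
            inside = stat.significant[block]
            outside = stat.significant.copy()
            outside[block] = False
            hits.append(inside.mean())
            false.append(outside.mean())
        assert np.mean(hits) >= 0.8
        assert np.mean(false) < 0.02

    def test_all_tied_bin_p_one_never_nan(self):
        grid = GridSpec(n=5, bin_um=80.0)
        a = [ActivityMap(np.full((5, 5), 2), grid) for _ in range(4)]
        b = [ActivityMap(np.full((5, 5), 2), grid) for _ in range(4)]
        stat = sp.pixelwise_test(a, b, np.ones((5, 5), bool))
        assert not np.isnan(stat.pvalues[~np.isnan(stat.pvalues)]).any()
        assert stat.n_tested == 0  # zero-variance bins are excluded

    def test_requires_three_maps(self):
        grid = GridSpec(n=5, bin_um=80.0)
        a = [ActivityMap(np.zeros((5, 5), int), grid)] * 2
        with pytest.raises(ValueError, match="3 maps"):
            sp.pixelwise_test(a, a, np.ones((5, 5), bool))


def test_mask_subset_of_tested_universe():
    grid = GridSpec(n=15, bin_um=80.0)
    rng = np.random.default_rng(8)
    a = [ActivityMap(rng.poisson(3.0, (15, 15)), grid) for _ in range(6)]
    b = [ActivityMap(rng.poisson(8.0, (15, 15)), grid) for _ in range(6)]
    mask = np.zeros((15, 15), dtype=bool)
    mask[2:8, 2:8] = True
    stat = sp.pixelwise_test(a, b, mask)
    assert not stat.significant[~mask].any()
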