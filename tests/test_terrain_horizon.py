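"""Terrain horizon geometry against trigonometric and ray-marching oracles."""

import numpy as np
import pytest

from hemirad import (
    ElevationGrid,
    HorizonProfile,
    ModelConfig,
    combine_horizons,
    horizon_from_grid,
    horizon_to_image,
    oracle_horizon,
)


def _flat_grid(value=500.0, n=100, res=5.0):
    return ElevationGrid(values=np.full((n, n), value), resolution=res,
                         origin=(2_650_000.0, 1_180_000.0))


class TestHorizonFromGrid:
    def test_flat_terrain_gives_zero_horizon(self):
        grid = _flat_grid()
        centre = (2_650_000.0 + 250.0, 1_180_000.0 - 250.0)
        prof = horizon_from_grid(grid, centre, 200.0)
        assert prof.angles.shape == (360,)
        assert np.allclose(prof.angles, 0.0, atol=1e-9)

    def test_raised_block_due_north(self):
        """A 10 m bump at 100 m north subtends atan(10/100) ≈ 5.71°.

        The bump is a 3×3-cell plateau so the ray through the north bin's
        centre (0.5° off true north) still samples its full height.
        """
        grid = _flat_grid(value=500.0)
        centre_x = 2_650_000.0 + 252.5  # a cell centre
        centre_y = 1_180_000.0 - 252.5
        rows, cols = grid.world_to_index(centre_x, centre_y + 100.0)
        r, c = int(round(float(rows))), int(round(float(cols)))
        grid.values[r - 1: r + 2, c - 1: c + 2] += 10.0
        prof = horizon_from_grid(grid, (centre_x, centre_y), 200.0)
        north = prof.angles[0]
        assert north == pytest.approx(np.degrees(np.arctan(10.0 / 100.0)), abs=0.5)
        # far-from-north azimuths remain flat
        assert np.allclose(prof.angles[90:270], 0.0, atol=1e-6)

    def test_crater_rim_subtends_its_rim_angle(self, crater_scene):
        """Viewer at the crater centre sees ~30° in every azimuth, matching
        the dense ray-marching oracle within one cell's angular subtense."""
        local, _ = crater_scene.terrain_grids()
        centre = crater_scene.spec.centre
        prof = horizon_from_grid(local, centre, 150.0)
        tol = np.degrees(np.arctan(local.resolution / crater_scene.spec.crater_radius))
        for az in range(0, 360, 15):
            oracle = oracle_horizon(crater_scene, centre, az + 0.5, max_range=150.0)
            assert prof.angles[az] == pytest.approx(oracle, abs=tol)
        assert np.all(np.abs(prof.angles - 30.0) < tol + 0.5)

    def test_point_outside_grid_rejected(self):
        grid = _flat_grid()
        with pytest.raises(ValueError, match="outside"):
            horizon_from_grid(grid, (0.0, 0.0), 100.0)

    def test_radius_below_one_cell_rejected(self):
        grid = _flat_grid()
        with pytest.raises(ValueError, match="radius"):
            horizon_from_grid(grid, (2_650_250.0, 1_179_750.0), 2.0)

    def test_raising_terrain_never_lowers_horizon(self, rng):
        """Monotonicity: adding elevation anywhere can only raise angles."""
        base = _flat_grid(n=40)
        centre = (2_650_100.0, 1_179_900.0)
        before = horizon_from_grid(base, centre, 90.0).angles
        bumped = base.copy_with(base.values + rng.random(base.values.shape) * 5.0)
        after = horizon_from_grid(bumped, centre, 90.0).angles
        assert np.all(after >= before - 1e-9)

    def test_terrain_beyond_radius_has_no_effect(self):
        base = _flat_grid(n=100)
        centre = (2_650_250.0, 1_179_750.0)
        ref = horizon_from_grid(base, centre, 100.0).angles
        spiked = base.copy_with(base.values.copy())
        # a huge wall 150 m east of the viewer, well beyond the 100 m radius
        rows, cols = spiked.world_to_index(centre[0] + 150.0, centre[1])
        spiked.values[:, int(round(float(cols))):] += 500.0
        walled = horizon_from_grid(spiked, centre, 100.0).angles
        assert np.allclose(walled, ref, atol=1e-9)

    def test_nodata_neighbourhood_yields_nan_profile(self):
        grid = _flat_grid(n=20)
        grid.values[:, :] = np.nan
        prof = horizon_from_grid(grid, (2_650_050.0, 1_179_950.0), 50.0)
        assert np.all(np.isnan(prof.angles))


class TestCombineHorizons:
    def test_elementwise_maximum(self):
        local = HorizonProfile(np.full(360, 10.0))
        regional = HorizonProfile(np.full(360, 25.0))
        assert np.allclose(combine_horizons(local, regional).angles, 25.0)

    def test_peak_overrides_ridge_only_in_its_bin(self):
        local = np.zeros(360)
        local[42] = 40.0
        combined = combine_horizons(HorizonProfile(local),
                                    HorizonProfile(np.full(360, 20.0))).angles
        expected = np.full(360, 20.0)
        expected[42] = 40.0
        assert np.allclose(combined, expected)

    def test_combined_dominates_both_inputs(self, rng):
        a = HorizonProfile(rng.uniform(-10, 60, 360))
        b = HorizonProfile(rng.uniform(-10, 60, 360))
        c = combine_horizons(a, b).angles
        assert np.all(c >= a.angles) and np.all(c >= b.angles)

    def test_nan_local_falls_back_to_regional(self):
        local = HorizonProfile(np.full(360, np.nan))
        regional = HorizonProfile(np.full(360, 12.0))
        assert np.allclose(combine_horizons(local, regional).angles, 12.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_horizons(HorizonProfile(np.zeros(360)),
                             HorizonProfile(np.zeros(180), azimuth_step=2.0))


class TestHorizonToImage:
    def test_zero_horizon_is_all_sky(self):
        img = horizon_to_image(HorizonProfile(np.zeros(360)))
        assert img.sky.all()

    def test_ninety_degree_horizon_is_all_obstructed(self):
        img = horizon_to_image(HorizonProfile(np.full(360, 90.0)))
        assert not img.sky.any()

    def test_thirty_degree_horizon_thresholds_at_zenith_sixty(self):
        img = horizon_to_image(HorizonProfile(np.full(360, 30.0)))
        assert img.sky[:60].all()       # zenith centres 0.5..59.5 are sky
        assert not img.sky[60:].any()   # 60.5..89.5 obstructed

    def test_negative_horizon_floors_at_astronomical_horizon(self):
        img = horizon_to_image(HorizonProfile(np.full(360, -20.0)))
        assert img.sky.all()

    def test_columns_are_monotone(self, rng):
        prof = HorizonProfile(rng.uniform(0, 90, 360))
        img = horizon_to_image(prof)
        transitions = np.abs(np.diff(img.sky.astype(int), axis=0)).sum(axis=0)
        assert np.all(transitions <= 1)


class TestRenderPolar:
    def test_south_up_orientation(self):
        """A wall occluding the northern half appears in the lower half of
        the rendered (south-up) image."""
        angles = np.zeros(360)
        angles[:90] = 90.0   # azimuths 0–90 (north→east) fully obstructed
        angles[270:] = 90.0  # azimuths 270–360 (west→north)
        img = horizon_to_image(HorizonProfile(angles))
        rendered = img.render_polar(size=61)
        top = np.nanmean(rendered[:25])
        bottom = np.nanmean(rendered[36:])
        assert top > 0.9       # southern sky (top of page) open
        assert bottom < 0.1    # northern sky (bottom of page) blocked
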