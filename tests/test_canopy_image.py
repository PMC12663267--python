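"""Canopy ray marching, Beer–Lambert transmission, binarisation, composition."""

import numpy as np
import pytest

from hemirad import (
    HemisphericImage,
    ModelConfig,
    SceneSpec,
    TransmissionField,
    binarise_probability,
    canopy_horizon_and_thickness,
    compose_images,
    horizon_from_grid,
    horizon_to_image,
    interpolate_lambda,
    make_scene,
    transmission_probability,
)


def _scene_inputs(scene):
    local, _ = scene.terrain_grids()
    chm, mix, mask = scene.forest_grids()
    lam = {cond: interpolate_lambda(mix, cond) for cond in ("leaf_on", "leaf_off")}
    return local, chm, lam


class TestPathLengths:
    def test_no_canopy_gives_zero_paths(self, flat_scene):
        local, chm, lam = _scene_inputs(flat_scene)
        field = canopy_horizon_and_thickness(chm, local, flat_scene.spec.centre, lam)
        assert np.all(field.l == 0.0)
        assert np.all(field.canopy_top_horizon.angles == -90.0)

    def test_single_cuboid_crown_horizontal_ray(self):
        """A 2 m deep crown straddling the horizontal due-north ray adds
        l = 2 m for near-horizontal directions."""
        spec = SceneSpec(terrain_kind="flat", forest_kind="single_crown",
                         extent=60.0, crown_height=10.0, crown_width=2.0,
                         crown_offset=(0.0, 5.0))
        scene = make_scene(spec)
        local, chm, lam = _scene_inputs(scene)
        field = canopy_horizon_and_thickness(chm, local, spec.centre, lam)
        # most horizontal zenith bin (89.5°), due-north azimuth bin
        assert field.l[89, 0] == pytest.approx(2.0, abs=0.5)
        # due south there is no crown
        assert field.l[89, 180] == 0.0

    def test_vertical_ray_through_uniform_slab(self, slab_scene):
        local, chm, lam = _scene_inputs(slab_scene)
        field = canopy_horizon_and_thickness(chm, local, slab_scene.spec.centre, lam)
        assert np.allclose(field.l[0], 20.0, atol=0.5)

    def test_uniform_lambda_weighting_is_lambda_times_length(self, slab_scene):
        """With spatially constant λ the accumulated Σλ·l equals λ·l."""
        local, chm, lam = _scene_inputs(slab_scene)
        field = canopy_horizon_and_thickness(chm, local, slab_scene.spec.centre, lam)
        lam_on = lam["leaf_on"].values.flat[0]
        assert np.allclose(field.lambda_l["leaf_on"], lam_on * field.l, rtol=1e-9)

    def test_no_path_above_canopy_top_horizon(self, gapped_scene):
        local, chm, lam = _scene_inputs(gapped_scene)
        field = canopy_horizon_and_thickness(chm, local, gapped_scene.spec.centre, lam)
        elev = 90.0 - (np.arange(90) + 0.5)
        top = field.canopy_top_horizon.angles
        above = elev[:, None] > top[None, :]
        assert np.all(field.l[above] == 0.0)

    def test_point_outside_grids_rejected(self, slab_scene):
        local, chm, lam = _scene_inputs(slab_scene)
        with pytest.raises(ValueError, match="outside"):
            canopy_horizon_and_thickness(chm, local, (0.0, 0.0), lam)


class TestTransmission:
    def test_empty_path_transmits_fully(self, flat_scene):
        local, chm, lam = _scene_inputs(flat_scene)
        field = canopy_horizon_and_thickness(chm, local, flat_scene.spec.centre, lam)
        p = transmission_probability(field, condition="leaf_on").p
        assert np.all(p == 1.0)

    def test_beer_lambert_value(self, slab_scene):
        """G = 0.5, λ = 0.5, l = 2 → p = exp(−0.5) ≈ 0.6065."""
        config = ModelConfig(lambda_evergreen=0.5)
        local, chm, _ = _scene_inputs(slab_scene)
        _, mix, _ = slab_scene.forest_grids()
        lam = interpolate_lambda(mix, "leaf_on", config)
        field = canopy_horizon_and_thickness(chm, local, slab_scene.spec.centre,
                                             lam, config)
        # pick a direction and scale to the analytic case l = 2
        direction = (0, 0)
        l = field.l[direction]
        p = transmission_probability(field, config, "leaf_on").p[direction]
        assert p == pytest.approx(np.exp(-0.5 * 0.5 * l), rel=1e-9)
        assert np.exp(-0.5 * 0.5 * 2.0) == pytest.approx(0.6065, abs=1e-4)

    def test_doubling_path_squares_transmission(self):
        """log p is linear in l: doubling l doubles −log p."""
        from hemirad.canopy_image import PathLengthField
        from hemirad.terrain_horizon import HorizonProfile
        l = np.full((90, 360), 3.0)
        base = PathLengthField(l=l, lambda_l={"leaf_on": 0.4 * l},
                               canopy_top_horizon=HorizonProfile(np.zeros(360)))
        double = PathLengthField(l=2 * l, lambda_l={"leaf_on": 0.4 * 2 * l},
                                 canopy_top_horizon=HorizonProfile(np.zeros(360)))
        p1 = transmission_probability(base, condition="leaf_on").p
        p2 = transmission_probability(double, condition="leaf_on").p
        assert np.allclose(np.log(p2), 2 * np.log(p1))

    def test_adding_canopy_never_raises_transmission(self, gapped_scene):
        local, chm, lam = _scene_inputs(gapped_scene)
        field = canopy_horizon_and_thickness(chm, local, gapped_scene.spec.centre, lam)
        p_off = transmission_probability(field, condition="leaf_off").p
        p_on = transmission_probability(field, condition="leaf_on").p
        assert np.all(p_on <= p_off + 1e-12)


class TestBinarise:
    def test_certainty_endpoints(self):
        ones = TransmissionField(np.ones((90, 360)))
        zeros = TransmissionField(np.zeros((90, 360)))
        assert binarise_probability(ones, 0).sky.all()
        assert not binarise_probability(zeros, 0).sky.any()

    def test_expected_sky_fraction_calibrated(self):
        """p = 0.6 everywhere realises a sky fraction within 3 binomial σ."""
        field = TransmissionField(np.full((90, 360), 0.6))
        sigma = np.sqrt(0.6 * 0.4 / (90 * 360))
        for seed in range(20):
            frac = binarise_probability(field, seed).sky.mean()
            assert abs(frac - 0.6) < 3 * sigma

    def test_same_seed_is_bitwise_reproducible(self):
        field = TransmissionField(np.random.default_rng(5).random((90, 360)))
        a = binarise_probability(field, 42).sky
        b = binarise_probability(field, 42).sky
        assert np.array_equal(a, b)

    def test_threshold_mode_is_deterministic_cut(self):
        field = TransmissionField(np.array([[0.49, 0.5, 0.51]]).repeat(90, 0)
                                  .repeat(120, 1))
        img = binarise_probability(field, mode="threshold")
        assert not img.sky[:, :120].any()
        assert img.sky[:, 120:].all()

    def test_shared_draws_nest_leaf_conditions(self):
        """Same seed on a denser and a sparser canopy: the denser image's
        sky cells are a subset of the sparser image's."""
        rng = np.random.default_rng(3)
        p_off = rng.random((90, 360))
        p_on = p_off * rng.random((90, 360))
        on = binarise_probability(TransmissionField(p_on), 11).sky
        off = binarise_probability(TransmissionField(p_off), 11).sky
        assert not np.any(on & ~off)


class TestCompose:
    def test_all_sky_canopy_is_identity(self, rng):
        terrain = HemisphericImage(rng.random((90, 360)) > 0.3)
        canopy = HemisphericImage(np.ones((90, 360), dtype=bool))
        assert np.array_equal(compose_images(terrain, canopy).sky, terrain.sky)

    def test_obstructed_terrain_absorbs(self, rng):
        terrain = HemisphericImage(np.zeros((90, 360), dtype=bool))
        canopy = HemisphericImage(rng.random((90, 360)) > 0.3)
        assert not compose_images(terrain, canopy).sky.any()

    def test_sky_fraction_bounded_by_inputs(self, rng):
        a = HemisphericImage(rng.random((90, 360)) > 0.4)
        b = HemisphericImage(rng.random((90, 360)) > 0.6)
        c = compose_images(a, b)
        assert c.sky_fraction() <= min(a.sky_fraction(), b.sky_fraction())

    def test_grid_mismatch_rejected(self):
        a = HemisphericImage(np.ones((90, 360), dtype=bool))
        b = HemisphericImage(np.ones((45, 180), dtype=bool),
                             zenith_step=2.0, azimuth_step=2.0)
        with pytest.raises(ValueError):
            compose_images(a, b)
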