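"""Direct-density chain: thresholding, decomposition, reconstruction."""

import numpy as np
import pytest

from densityct.ddrecon import (DDConfig, ThicknessSinogram, assemble_red_sinogram,
                               bone_thickness, dd_reconstruct, decompose_water,
                               run_direct_density, threshold_bone,
                               _model_log_attenuation)
from densityct.phantoms import PhantomImage
from densityct.physics import ConfigurationError, make_spectrum
from densityct.projector import (Geometry, ReconImage, Sinogram, default_geometry,
                                 forward_project_image)


@pytest.fixture(scope="module")
def sp120():
    return make_spectrum(120)


@pytest.fixture(scope="module")
def cfg120(sp120):
    return DDConfig.for_spectrum(sp120)


class TestThresholdBone:
    def test_values_below_threshold_vanish(self, cfg120):
        img = ReconImage(np.full((8, 8), cfg120.bone_threshold * 0.5), 1.0,
                         "attenuation")
        assert np.abs(threshold_bone(img, cfg120).values).max() == 0.0

    def test_values_above_ramp_keep_full_excess(self, cfg120):
        v = cfg120.bone_threshold + 2 * cfg120.ramp_width
        img = ReconImage(np.full((8, 8), v), 1.0, "attenuation")
        out = threshold_bone(img, cfg120)
        assert out.values == pytest.approx(v - cfg120.bone_baseline)

    def test_ramp_midpoint_half_weight(self, cfg120):
        v = cfg120.bone_threshold + 0.5 * cfg120.ramp_width
        img = ReconImage(np.array([[v]]), 1.0, "attenuation")
        expected = 0.5 * (v - cfg120.bone_baseline)  # piecewise formula by hand
        assert threshold_bone(img, cfg120).values[0, 0] == pytest.approx(expected)

    def test_hard_threshold_zero_baseline_is_idempotent(self, cfg120):
        from dataclasses import replace
        hard = replace(cfg120, ramp_width=0.0, bone_baseline=0.0)
        rng = np.random.default_rng(3)
        img = ReconImage(rng.random((16, 16)) * 3 * hard.bone_threshold, 1.0,
                         "attenuation")
        once = threshold_bone(img, hard)
        twice = threshold_bone(once, hard)
        np.testing.assert_array_equal(once.values, twice.values)


class TestBoneThickness:
    def test_zero_sinogram_zero_thickness(self, cfg120):
        geo = Geometry(n_angles=8, n_detectors=21)
        s = Sinogram(np.zeros((8, 21)), geo, kind="linear")
        assert np.abs(bone_thickness(s, cfg120)).max() == 0.0

    def test_uniform_disk_central_ray_recovers_chord(self, cfg120):
        size, r = 96, 30.0
        x = np.arange(size) - (size - 1) / 2.0
        xx, yy = np.meshgrid(x, x)
        img = ReconImage(
            np.where(xx**2 + yy**2 <= r**2, cfg120.mu_bone_ref, 0.0), 1.0,
            "bone-mask")
        geo = Geometry(n_angles=2, n_detectors=141)
        d_b = bone_thickness(forward_project_image(img, geo), cfg120)
        assert d_b[0, 70] == pytest.approx(2 * r / 10.0, rel=0.01)

    def test_doubling_reference_halves_thickness(self, cfg120):
        from dataclasses import replace
        geo = Geometry(n_angles=2, n_detectors=5)
        s = Sinogram(np.full((2, 5), 1.3), geo, kind="linear")
        d1 = bone_thickness(s, cfg120)
        d2 = bone_thickness(s, replace(cfg120, mu_bone_ref=2 * cfg120.mu_bone_ref))
        np.testing.assert_allclose(d1, 2 * d2)


class TestDecomposeWater:
    def _sino(self, values):
        geo = Geometry(n_angles=values.shape[0], n_detectors=values.shape[1])
        return Sinogram(values, geo, kind="mu")

    def test_pure_water_round_trip(self, sp120, cfg120):
        target = _model_log_attenuation(np.array([10.0]), np.array([0.0]),
                                        sp120, cfg120)
        s = self._sino(target.reshape(1, 1))
        t = decompose_water(s, np.zeros((1, 1)), sp120, cfg120)
        assert t.d_w[0, 0] == pytest.approx(10.0, abs=5 * cfg120.solver_tolerance)

    def test_zero_attenuation_zero_water(self, sp120, cfg120):
        s = self._sino(np.zeros((1, 3)))
        t = decompose_water(s, np.zeros((1, 3)), sp120, cfg120)
        assert np.abs(t.d_w).max() == 0.0

    def test_water_plus_bone_against_grid_search(self, sp120, cfg120):
        d_b = np.array([2.0])
        target = _model_log_attenuation(np.array([10.0]), d_b, sp120, cfg120)
        s = self._sino(target.reshape(1, 1))
        t = decompose_water(s, d_b.reshape(1, 1), sp120, cfg120)
        # brute-force grid search oracle over d_w
        grid = np.linspace(0.0, 30.0, 30001)
        f = _model_log_attenuation(grid, np.full_like(grid, 2.0), sp120, cfg120)
        best = grid[np.argmin(np.abs(f - target))]
        assert t.d_w[0, 0] == pytest.approx(best, rel=0.01)

    def test_bone_overexplaining_clamps_water_at_zero(self, sp120, cfg120):
        small = _model_log_attenuation(np.array([0.5]), np.array([0.0]),
                                       sp120, cfg120)
        s = self._sino(small.reshape(1, 1))
        t = decompose_water(s, np.full((1, 1), 5.0), sp120, cfg120)
        assert t.d_w[0, 0] == 0.0

    def test_bound_saturates_instead_of_dumping(self, sp120, cfg120):
        target = _model_log_attenuation(np.array([20.0]), np.array([0.0]),
                                        sp120, cfg120)
        s = self._sino(target.reshape(1, 1))
        t = decompose_water(s, np.zeros((1, 1)), sp120, cfg120,
                            d_w_max=np.full((1, 1), 12.0))
        assert t.d_w[0, 0] == pytest.approx(12.0, abs=1e-3)

    def test_non_finite_sinogram_rejected(self, sp120, cfg120):
        geo = Geometry(n_angles=1, n_detectors=3)
        with pytest.raises(ConfigurationError):
            s = Sinogram(np.array([[0.0, np.nan, 0.0]]), geo)


class TestAssembleAndScale:
    def test_red_line_integral_formula(self, cfg120):
        geo = Geometry(n_angles=1, n_detectors=2)
        t = ThicknessSinogram(np.array([[10.0, 0.0]]), np.array([[0.0, 2.0]]), geo)
        s = assemble_red_sinogram(t, cfg120)
        assert s.values[0, 0] == pytest.approx(10.0)  # water RED = 1
        assert s.values[0, 1] == pytest.approx(2.0 * cfg120.red_bone)

    def test_additivity_over_thickness_sets(self, cfg120):
        geo = Geometry(n_angles=1, n_detectors=3)
        rng = np.random.default_rng(5)
        a_w, a_b = rng.random((1, 3)), rng.random((1, 3))
        b_w, b_b = rng.random((1, 3)), rng.random((1, 3))
        s_sum = assemble_red_sinogram(
            ThicknessSinogram(a_w + b_w, a_b + b_b, geo), cfg120)
        s_a = assemble_red_sinogram(ThicknessSinogram(a_w, a_b, geo), cfg120)
        s_b = assemble_red_sinogram(ThicknessSinogram(b_w, b_b, geo), cfg120)
        np.testing.assert_allclose(s_sum.values, s_a.values + s_b.values)

    def test_dd_image_value_scale(self, cfg120):
        # uniform RED-1 disk: reconstructed center maps to (1-0.994)*1000
        size, r = 96, 35.0
        x = np.arange(size) - (size - 1) / 2.0
        xx, yy = np.meshgrid(x, x)
        red = np.where(xx**2 + yy**2 <= r**2, 1.0, 0.0)
        geo = Geometry(n_angles=180, n_detectors=141)
        s_red = forward_project_image(ReconImage(red, 1.0, "red"), geo)
        s_red.kind = "red"
        img = dd_reconstruct(s_red, cfg120, output_size=size, pixel_size=1.0)
        mask = xx**2 + yy**2 <= (r / 2) ** 2
        assert img.values[mask].mean() == pytest.approx(6.0, abs=1.0)
        # RED 0.994 maps to exactly zero image value
        assert (0.994 - cfg120.dd_offset) * cfg120.dd_scale == 0.0


class TestFullChain:
    def test_air_phantom_interior_reads_minus_994(self, library, sp120):
        from densityct.phantoms import PhantomImage
        ph = PhantomImage(np.zeros((64, 64), dtype=int), 1.0, {0: library["air"]})
        res = run_direct_density(ph, sp120)
        interior = res.image.values[24:40, 24:40]
        assert interior.mean() == pytest.approx(-994.0, abs=2.0)

    def test_water_disk_recovers_unity_at_every_voltage(self, water_disk):
        geo = default_geometry(water_disk)
        for kvp in (80, 100, 120, 140):
            res = run_direct_density(water_disk, make_spectrum(kvp), geo)
            x = np.arange(96) - 47.5
            xx, yy = np.meshgrid(x, x)
            mask = xx**2 + yy**2 <= 17.0**2
            assert res.red_image.values[mask].mean() == pytest.approx(1.0, abs=0.02)

    def test_intermediates_are_retrievable_and_consistent(self, water_disk, sp120):
        res = run_direct_density(water_disk, sp120)
        assert res.s_mu.kind == "mu"
        assert res.s_red.kind == "red"
        assert res.bone_image.semantics == "bone-mask"
        np.testing.assert_allclose(
            res.red_image.values,
            res.image.values / res.config.dd_scale + res.config.dd_offset)


def test_config_validation(sp120):
    with pytest.raises(ConfigurationError):
        DDConfig.for_spectrum(sp120, threshold_hu=-10.0)
    with pytest.raises(ConfigurationError):
        DDConfig.for_spectrum(sp120, solver_tolerance=0.0)
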