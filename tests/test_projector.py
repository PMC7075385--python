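"""Virtual scanner: ray tracing, forward projection, FBP."""

import numpy as np
import pytest

from densityct.phantoms import PhantomImage
from densityct.physics import ConfigurationError, linear_attenuation, make_spectrum, WATER
from densityct.projector import (Geometry, ReconImage, Sinogram, default_geometry,
                                 fbp, forward_project, forward_project_image,
                                 material_path_lengths)

R_DISK = 35.0  # mm, radius of the water_disk fixture


class TestForwardProject:
    def test_vacuum_phantom_gives_zero_sinogram(self, library):
        from densityct.physics import Material
        vacuum = Material("vacuum", {"N": 1.0}, 1e-12)
        ph = PhantomImage(np.zeros((32, 32), dtype=int), 1.0, {0: vacuum})
        s = forward_project(ph, make_spectrum(120), default_geometry(ph))
        assert np.abs(s.values).max() < 1e-9

    def test_monoenergetic_central_ray_equals_chord(self, water_disk, mono60):
        geo = default_geometry(water_disk)
        s = forward_project(water_disk, mono60, geo)
        mu = float(linear_attenuation(WATER, 60.0))
        central = s.values[0, geo.n_detectors // 2]
        assert central == pytest.approx(mu * 2 * R_DISK / 10.0, rel=0.005)

    def test_polyenergetic_central_ray_against_quadrature(self, water_disk):
        # independent quadrature: -ln sum w exp(-mu_w(E) * 2R) from the
        # analytic chord, no ray tracing involved
        sp = make_spectrum(120)
        geo = default_geometry(water_disk)
        s = forward_project(water_disk, sp, geo)
        mu = np.asarray(linear_attenuation(WATER, sp.energies))
        expected = -np.log(np.sum(sp.weights * np.exp(-mu * 2 * R_DISK / 10.0)))
        assert s.values[0, geo.n_detectors // 2] == pytest.approx(expected, rel=0.005)

    def test_centered_disk_grid_symmetries_exact(self, water_disk, mono60):
        geo = Geometry(n_angles=4, angular_range=180.0, n_detectors=141,
                       detector_pitch=1.0)
        s = forward_project(water_disk, mono60, geo)
        # 0 vs 90 degrees and 45 vs 135 degrees share the square grid's
        # dihedral symmetry; mirrored detector order for the conjugates
        np.testing.assert_allclose(s.values[0], s.values[2], atol=1e-9)
        np.testing.assert_allclose(s.values[1], s.values[3][::-1], atol=1e-9)

    def test_noise_reproducible_and_scales_with_photons(self, water_disk):
        sp = make_spectrum(120)
        geo = default_geometry(water_disk)
        chords = material_path_lengths(water_disk, geo)
        kw = dict(path_lengths=chords)
        a = forward_project(water_disk, sp, geo, photons=2e5, seed=11, **kw)
        b = forward_project(water_disk, sp, geo, photons=2e5, seed=11, **kw)
        np.testing.assert_array_equal(a.values, b.values)
        clean = forward_project(water_disk, sp, geo, **kw)
        lo = forward_project(water_disk, sp, geo, photons=1e5, seed=1, **kw)
        hi = forward_project(water_disk, sp, geo, photons=4e5, seed=2, **kw)
        ratio = np.var(lo.values - clean.values) / np.var(hi.values - clean.values)
        assert ratio == pytest.approx(4.0, rel=0.2)

    def test_negative_photon_count_rejected(self, water_disk):
        with pytest.raises(ConfigurationError):
            forward_project(water_disk, make_spectrum(120),
                            default_geometry(water_disk), photons=-1.0)


class TestReprojection:
    def test_zero_image_zero_sinogram(self):
        img = ReconImage(np.zeros((32, 32)), 1.0, "attenuation")
        geo = Geometry(n_angles=8, n_detectors=49)
        assert np.abs(forward_project_image(img, geo).values).max() == 0.0

    def test_uniform_disk_central_ray_is_value_times_chord(self):
        size, v, r = 96, 0.3, 30.0
        x = np.arange(size) - (size - 1) / 2.0
        xx, yy = np.meshgrid(x, x)
        img = ReconImage(np.where(xx**2 + yy**2 <= r**2, v, 0.0), 1.0,
                         "attenuation")
        geo = Geometry(n_angles=4, n_detectors=141)
        s = forward_project_image(img, geo)
        assert s.values[0, 70] == pytest.approx(v * 2 * r / 10.0, rel=0.005)

    def test_linearity_on_random_images(self):
        rng = np.random.default_rng(0)
        geo = Geometry(n_angles=6, n_detectors=25)
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        pa = forward_project_image(ReconImage(a, 1.0, "attenuation"), geo).values
        pb = forward_project_image(ReconImage(b, 1.0, "attenuation"), geo).values
        pab = forward_project_image(
            ReconImage(2 * a - 3 * b, 1.0, "attenuation"), geo).values
        np.testing.assert_allclose(pab, 2 * pa - 3 * pb, atol=1e-9)

    def test_matches_explicit_matrix_on_random_image(self):
        # brute-force operator matrix from unit-pixel images
        rng = np.random.default_rng(1)
        geo = Geometry(n_angles=3, n_detectors=13)
        n = 8
        cols = []
        for i in range(n * n):
            e = np.zeros(n * n)
            e[i] = 1.0
            cols.append(forward_project_image(
                ReconImage(e.reshape(n, n), 1.0, "attenuation"), geo).values.ravel())
        matrix = np.column_stack(cols)
        x = rng.random((n, n))
        direct = forward_project_image(ReconImage(x, 1.0, "attenuation"), geo)
        np.testing.assert_allclose(direct.values.ravel(), matrix @ x.ravel(),
                                   rtol=1e-9, atol=1e-12)


class TestFBP:
    def test_zero_sinogram_zero_image(self):
        geo = Geometry(n_angles=90, n_detectors=49)
        s = Sinogram(np.zeros((90, 49)), geo)
        assert np.abs(fbp(s).values).max() == 0.0

    def test_uniform_disk_plateau_recovered_within_one_percent(
            self, water_disk, mono60):
        geo = default_geometry(water_disk)
        s = forward_project(water_disk, mono60, geo)
        img = fbp(s, output_size=96, pixel_size=1.0)
        mu = float(linear_attenuation(WATER, 60.0))
        x = np.arange(96) - 47.5
        xx, yy = np.meshgrid(x, x)
        mask = xx**2 + yy**2 <= (R_DISK / 2.0) ** 2
        assert img.values[mask].mean() == pytest.approx(mu, rel=0.01)

    def test_linearity_of_the_operator(self, water_disk, mono60):
        geo = default_geometry(water_disk)
        s = forward_project(water_disk, mono60, geo)
        one = fbp(s, output_size=64, pixel_size=1.0).values
        scaled = fbp(Sinogram(3.0 * s.values, geo), output_size=64,
                     pixel_size=1.0).values
        np.testing.assert_allclose(scaled, 3.0 * one, rtol=1e-9, atol=1e-12)

    def test_round_trip_rmse_within_two_percent_on_smooth_image(self):
        size = 128
        x = np.arange(size) - (size - 1) / 2.0
        xx, yy = np.meshgrid(x, x)
        smooth = np.exp(-(xx**2 + yy**2) / (2 * 18.0**2))
        geo = Geometry(n_angles=180, n_detectors=187)
        s = forward_project_image(ReconImage(smooth, 1.0, "attenuation"), geo)
        back = fbp(s, output_size=size, pixel_size=1.0).values
        rmse = np.sqrt(np.mean((back - smooth) ** 2))
        assert rmse <= 0.02 * np.ptp(smooth)

    def test_insufficient_angular_range_rejected(self):
        geo = Geometry(n_angles=45, angular_range=90.0, n_detectors=49)
        with pytest.raises(ConfigurationError):
            fbp(Sinogram(np.zeros((45, 49)), geo))

    def test_unknown_apodization_rejected(self):
        geo = Geometry(n_angles=90, n_detectors=49)
        with pytest.raises(ConfigurationError):
            fbp(Sinogram(np.zeros((90, 49)), geo), apodization="butter")

    def test_agrees_with_reference_iradon(self, water_disk, mono60):
        # independent cross-check of the reconstruction chain against
        # scikit-image's parallel-beam implementation
        skimage = pytest.importorskip("skimage.transform")
        geo = Geometry(n_angles=180, n_detectors=97, detector_pitch=1.0)
        s = forward_project(water_disk, mono60, geo)
        ours = fbp(s, apodization="ramp", output_size=96, pixel_size=1.0).values
        theirs = skimage.iradon(s.values.T, theta=geo.angles_deg,
                                filter_name="ramp", circle=False,
                                output_size=96) * 10.0  # per-pixel -> per-cm
        x = np.arange(96) - 47.5
        xx, yy = np.meshgrid(x, x)
        mask = xx**2 + yy**2 <= 25.0**2
        np.testing.assert_allclose(ours[mask], theirs[mask], atol=0.01)


def test_geometry_validation():
    with pytest.raises(ConfigurationError):
        Geometry(n_angles=0)
    with pytest.raises(ConfigurationError):
        Geometry(detector_pitch=-1.0)


def test_material_path_lengths_central_ray_chords(water_disk):
    geo = default_geometry(water_disk)
    chords = material_path_lengths(water_disk, geo)
    central = chords[1, 0, geo.n_detectors // 2]  # label 1 = water disk
    assert central == pytest.approx(2 * R_DISK / 10.0, rel=0.005)
    # every ray's total chord is bounded by the grid diagonal
    total = chords.sum(axis=0)
    assert total.max() <= np.hypot(*water_disk.shape) * water_disk.pixel_size / 10.0 + 1e-9
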