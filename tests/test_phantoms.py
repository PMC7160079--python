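"""Generator correctness: every phantom is checked against analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from ctiq.phantoms import (PhantomTruth, averaging_kernel, blurred_disc_profile,
                           default_lc_layout, insert_layout,
                           simulate_foil_stack, simulate_insert_module,
                           simulate_low_contrast_module, simulate_noise_volume,
                           simulate_rod_image, simulate_wire_image)
from ctiq.volume import CTIQError


class TestWire:
    def test_centroid_matches_subpixel_position(self):
        pos = (0.123, -0.217)
        vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=0.2),
                                     grid_size=128, pixel_pitch=0.1,
                                     wire_position=pos)
        img = vol.voxels[0]
        xx, yy = np.meshgrid(vol.x_coords(), vol.y_coords())
        cx = (xx * img).sum() / img.sum()
        cy = (yy * img).sum() / img.sum()
        assert abs(cx - pos[0]) < 1e-3 and abs(cy - pos[1]) < 1e-3

    def test_flux_conserved_under_blur(self):
        sums = []
        for sigma in (0.1, 0.2, 0.4):
            vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=sigma),
                                         grid_size=128, pixel_pitch=0.1)
            sums.append(vol.voxels.sum())
        assert np.ptp(sums) / sums[0] < 1e-3

    def test_second_moment(self):
        # var per axis of the PSF image = sigma^2 + (d/4)^2 (uniform disc term)
        sigma, d = 0.2, 0.05
        vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=sigma,
                                                  wire_diameter=d),
                                     grid_size=256, pixel_pitch=0.02)
        img = vol.voxels[0]
        x = vol.x_coords()
        w = img.sum(axis=0)
        var_x = (w * x ** 2).sum() / w.sum() - ((w * x).sum() / w.sum()) ** 2
        assert var_x == pytest.approx(sigma ** 2 + d ** 2 / 16, rel=2e-3)

    def test_unresolvable_configuration_rejected(self):
        with pytest.raises(CTIQError):
            simulate_wire_image(PhantomTruth(psf_sigma=0.0, wire_diameter=1e-5),
                                grid_size=64, pixel_pitch=0.5)

    def test_wire_near_border_rejected(self):
        with pytest.raises(CTIQError):
            simulate_wire_image(PhantomTruth(psf_sigma=0.2), grid_size=64,
                                pixel_pitch=0.05, wire_position=(1.5, 0.0))


class TestRod:
    def test_interior_value(self):
        truth = PhantomTruth(psf_sigma=0.2, rod_radius=6.0, rod_contrast=990.0,
                             background_hu=50.0)
        vol, _ = simulate_rod_image(truth, grid_size=256, pixel_pitch=0.1)
        centre = vol.voxels[0, 128, 128]
        assert centre == pytest.approx(50.0 + 990.0, rel=1e-3)

    def test_zero_contrast_is_uniform(self):
        truth = PhantomTruth(psf_sigma=0.2, rod_radius=6.0, rod_contrast=0.0)
        vol, _ = simulate_rod_image(truth, grid_size=128, pixel_pitch=0.2)
        assert np.ptp(vol.voxels) == 0.0

    def test_radial_profile_matches_blurred_disc_oracle(self):
        truth = PhantomTruth(psf_sigma=0.25, rod_radius=6.0, rod_contrast=1000.0)
        vol, _ = simulate_rod_image(truth, grid_size=256, pixel_pitch=0.1)
        img = vol.voxels[0]
        x = vol.x_coords()
        y = vol.y_coords()
        row0 = np.argmin(np.abs(y))
        for col in range(130, 200, 7):
            r = abs(x[col])
            expected = 1000.0 * blurred_disc_profile(r, 6.0, 0.25)[0]
            assert img[row0, col] == pytest.approx(expected, abs=5.0)  # 0.5%

    def test_rod_touching_border_rejected(self):
        with pytest.raises(CTIQError):
            simulate_rod_image(PhantomTruth(rod_radius=6.0), grid_size=64,
                               pixel_pitch=0.2)


class TestNoise:
    def _roi_vars(self, vol, n=32):
        vars_ = []
        for sl in vol.voxels:
            for r in range(0, sl.shape[0] - n + 1, n):
                for c in range(0, sl.shape[1] - n + 1, n):
                    vars_.append(sl[r:r + n, c:c + n].var(ddof=1))
        return np.array(vars_)

    def test_white_noise_variance(self, white_noise_volume):
        vol, truth = white_noise_volume
        v = self._roi_vars(vol)
        se = v.std(ddof=1) / np.sqrt(v.size)
        assert abs(v.mean() - truth.noise_sigma_white ** 2) < 3 * se

    def test_averaging_kernel_halves_variance(self):
        # 2x1 mean kernel: sum of squared taps = 1/2
        truth = PhantomTruth(noise_sigma_white=10.0,
                             noise_kernel=averaging_kernel((1, 2)), rng_seed=9)
        vol, _ = simulate_noise_volume(truth, grid_size=256, pixel_pitch=0.5,
                                       n_slices=4)
        v = self._roi_vars(vol)
        se = v.std(ddof=1) / np.sqrt(v.size)
        assert abs(v.mean() - 50.0) < 3 * se

    def test_seed_determinism(self):
        a, _ = simulate_noise_volume(PhantomTruth(noise_sigma_white=10.0,
                                                  rng_seed=7), grid_size=64)
        b, _ = simulate_noise_volume(PhantomTruth(noise_sigma_white=10.0,
                                                  rng_seed=7), grid_size=64)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestFoil:
    def test_half_maximum_at_half_fwhm(self):
        # gaussian profile: amplitude at z = +-fwhm/2 is half the peak
        truth = PhantomTruth(slice_fwhm=0.4, rod_radius=6.0)
        vol, _ = simulate_foil_stack(truth, z_increment=0.1, z_extent=4.0)
        amps = vol.voxels[:, 32, 32] - vol.voxels[0, 32, 32]
        z = vol.z_positions()
        peak = amps.max()
        for zz in (+0.2, -0.2):
            k = np.argmin(np.abs(z - zz))
            assert amps[k] == pytest.approx(peak / 2, abs=1e-6 * peak)

    @pytest.mark.parametrize("shape", ["gaussian", "trapezoid"])
    def test_z_integral_matches_quadrature(self, shape):
        truth = PhantomTruth(slice_fwhm=0.45, rod_radius=6.0,
                             slice_profile=shape)
        vol, _ = simulate_foil_stack(truth, z_increment=0.05, z_extent=4.0)
        amps = vol.voxels[:, 32, 32]
        from ctiq.phantoms import _slice_profile
        ref, _ = quad(lambda z: _slice_profile(truth, np.array([z]))[0],
                      -2.0, 2.0)
        est = amps.sum() * vol.dz / amps.max()
        assert est == pytest.approx(ref, rel=1e-3)

    def test_symmetry_about_foil(self):
        vol, _ = simulate_foil_stack(PhantomTruth(slice_fwhm=0.45,
                                                  rod_radius=6.0),
                                     z_increment=0.1, z_extent=4.0)
        amps = vol.voxels[:, 32, 32]
        np.testing.assert_allclose(amps, amps[::-1], atol=1e-9)

    def test_preconditions(self):
        with pytest.raises(CTIQError):
            simulate_foil_stack(PhantomTruth(slice_fwhm=0.25), z_increment=0.1)
        with pytest.raises(CTIQError):
            simulate_foil_stack(PhantomTruth(slice_fwhm=0.45), z_increment=0.1,
                                z_extent=1.0)


class TestLowContrastModule:
    def test_nominal_amplitudes_recovered(self):
        # 1% of the 1000-HU scale is 10 HU; noiseless blurred discs keep their
        # plateau for diameters well above the PSF width
        truth = PhantomTruth(psf_sigma=0.3, noise_sigma_white=0.0)
        vol, t = simulate_low_contrast_module(truth)
        img = vol.voxels[0]
        for obj in t.lc_layout:
            if obj["diameter"] < 10 * truth.psf_sigma:
                continue
            row, col = vol.phys_to_pixel(obj["x"], obj["y"])
            plateau = img[int(round(row)), int(round(col))]
            assert plateau == pytest.approx(10.0 * obj["contrast_pct"], rel=0.02)

    def test_overlap_rejected(self):
        layout = [{"x": 0, "y": 0, "diameter": 10, "contrast_pct": 1.0},
                  {"x": 4, "y": 0, "diameter": 10, "contrast_pct": 0.5}]
        with pytest.raises(CTIQError):
            simulate_low_contrast_module(PhantomTruth(lc_layout=layout))

    def test_seed_determinism(self):
        t = dict(noise_sigma_white=5.0, rng_seed=3)
        a, _ = simulate_low_contrast_module(PhantomTruth(**t))
        b, _ = simulate_low_contrast_module(PhantomTruth(**t))
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_default_layout_structure(self):
        layout = default_lc_layout()
        assert len(layout) == 27  # 3 contrast levels x 9 diameters
        assert {o["contrast_pct"] for o in layout} == {1.0, 0.5, 0.3}


class TestInsertModule:
    def test_noiseless_nominal_exact(self):
        truth = PhantomTruth(psf_sigma=0.0, noise_sigma_white=0.0)
        vol, t = simulate_insert_module(truth)
        for m, pos in insert_layout(t).items():
            row, col = vol.phys_to_pixel(pos["x"], pos["y"])
            assert vol.voxels[0, int(round(row)), int(round(col))] == \
                t.insert_hus[m]

    def test_noisy_roi_mean_within_standard_error(self):
        from ctiq.hu_qa import measure_insert_hu
        truth = PhantomTruth(psf_sigma=0.0, noise_sigma_white=10.0, rng_seed=2)
        vol, t = simulate_insert_module(truth)
        measured = measure_insert_hu(vol, insert_layout(t), roi_diameter=10.0)
        n_px = np.pi * 25.0 / (0.5 * 0.5)
        for m, value in measured.items():
            assert abs(value - t.insert_hus[m]) < 4 * 10.0 / np.sqrt(n_px)

    def test_unknown_material_rejected(self):
        truth = PhantomTruth(insert_hus={"air": -1000.0, "bone": 1200.0})
        with pytest.raises(CTIQError, match="bone"):
            simulate_insert_module(truth)
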