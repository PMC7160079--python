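"""Wire and circular-edge MTF estimation against the Gaussian closed form."""

import math

import numpy as np
import pytest

from ctiq.mtf import (CircularEdgeMTF, MTFCurve, WireMTF, mtf_from_circular_edge,
                      mtf_from_wire, mtf_percent_frequency, mtf_summary,
                      mtf_vs_position, wire_aperture_mtf)
from ctiq.phantoms import (PhantomTruth, gaussian_mtf,
                           gaussian_mtf_percent_frequency, simulate_rod_image,
                           simulate_wire_image)
from ctiq.volume import CTIQError, ImageVolume

WIRE_OPTS = dict(roi_size=64, annulus_inner=24, annulus_outer=30)


class TestPercentFrequency:
    def test_analytic_gaussian_lookup(self):
        # sigma = 0.1874 mm: f50 = 1.00 lp/mm, f10 = 1.82 lp/mm (closed form)
        sigma = 0.1874
        f = np.linspace(0, 3, 1201)
        curve = MTFCurve(f, gaussian_mtf(f, sigma))
        assert mtf_percent_frequency(curve, 50) == pytest.approx(
            gaussian_mtf_percent_frequency(sigma, 50), rel=5e-4)
        assert mtf_percent_frequency(curve, 50) == pytest.approx(1.00, abs=0.005)
        assert mtf_percent_frequency(curve, 10) == pytest.approx(1.82, abs=0.01)

    def test_threshold_not_reached(self):
        curve = MTFCurve(np.linspace(0, 2, 50), np.ones(50))
        with pytest.raises(CTIQError, match="threshold not reached"):
            mtf_percent_frequency(curve, 50)

    def test_percent_domain(self):
        curve = MTFCurve(np.linspace(0, 2, 50), np.linspace(1, 0, 50))
        for bad in (0, 100, -5, 120):
            with pytest.raises(CTIQError):
                mtf_percent_frequency(curve, bad)

    def test_first_downward_crossing_wins(self):
        # noisy non-monotone curve: the earliest crossing is reported
        f = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        m = np.array([1.0, 0.4, 0.6, 0.3, 0.1])
        assert mtf_percent_frequency(MTFCurve(f, m), 50) < 0.5


class TestCurveValidation:
    def test_must_be_normalised(self):
        with pytest.raises(CTIQError):
            MTFCurve(np.array([0.0, 1.0]), np.array([0.9, 0.5]))

    def test_frequencies_increasing(self):
        with pytest.raises(CTIQError):
            MTFCurve(np.array([0.0, 1.0, 0.5]), np.array([1.0, 0.8, 0.6]))


class TestWireMethod:
    def test_recovers_gaussian_f50(self, wire_default):
        vol, truth = wire_default
        curve = mtf_from_wire(vol, **WIRE_OPTS)
        ref = gaussian_mtf_percent_frequency(truth.psf_sigma, 50)
        assert mtf_percent_frequency(curve, 50) == pytest.approx(ref, rel=0.02)

    def test_full_curve_matches_closed_form(self, wire_default):
        vol, truth = wire_default
        curve = mtf_from_wire(vol, **WIRE_OPTS)
        ref = gaussian_mtf(curve.frequencies, truth.psf_sigma)
        f10 = gaussian_mtf_percent_frequency(truth.psf_sigma, 10)
        sel = curve.frequencies <= f10
        assert np.max(np.abs(curve.modulation[sel] - ref[sel])) < 0.02

    def test_normalised_at_zero(self, wire_default):
        vol, _ = wire_default
        curve = mtf_from_wire(vol, **WIRE_OPTS)
        assert curve.modulation[0] == 1.0
        assert curve.frequencies[-1] <= vol.nyquist + 1e-12

    def test_wire_correction_is_algebraic_inverse(self, wire_default):
        vol, _ = wire_default
        corrected = mtf_from_wire(vol, correct_wire=True, **WIRE_OPTS)
        plain = mtf_from_wire(vol, correct_wire=False, **WIRE_OPTS)
        back = corrected.modulation * wire_aperture_mtf(corrected.frequencies,
                                                        0.05)
        np.testing.assert_allclose(back, plain.modulation, atol=1e-12)

    def test_near_delta_wire_flat_after_correction(self):
        # PSF -> 0 with the wire on a pixel centre: near-flat MTF
        vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=0.0),
                                     grid_size=97, pixel_pitch=0.05)
        curve = mtf_from_wire(vol)
        sel = curve.frequencies <= vol.nyquist / 2
        assert np.all(curve.modulation[sel] >= 0.99)

    def test_noise_robustness_of_f50(self):
        # doubling the noise moves the 50% frequency by < 5% (20 seeds)
        ref = gaussian_mtf_percent_frequency(0.1874, 50)
        for sigma_n in (5.0, 10.0):
            f50s = []
            for seed in range(20):
                truth = PhantomTruth(psf_sigma=0.1874,
                                     noise_sigma_white=sigma_n, rng_seed=seed)
                vol, _ = simulate_wire_image(truth, grid_size=128,
                                             pixel_pitch=0.1)
                curve = mtf_from_wire(vol, **WIRE_OPTS)
                f50s.append(mtf_percent_frequency(curve, 50))
            assert abs(np.mean(f50s) - ref) / ref < 0.05

    def test_no_wire_found(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.normal(0, 5, (1, 64, 64)), 0.1, 0.1, 0.5)
        with pytest.raises(CTIQError, match="no wire"):
            mtf_from_wire(vol)

    def test_crop_exceeding_image(self):
        vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=0.1),
                                     grid_size=24, pixel_pitch=0.1)
        with pytest.raises(CTIQError):
            mtf_from_wire(vol, roi_size=32)


class TestEdgeMethod:
    def test_recovers_gaussian_f50(self):
        truth = PhantomTruth(psf_sigma=0.1874, rod_radius=6.0)
        vol, _ = simulate_rod_image(truth, grid_size=256, pixel_pitch=0.1)
        curve = mtf_from_circular_edge(vol, window_mm=12.0)
        ref = gaussian_mtf_percent_frequency(0.1874, 50)
        assert mtf_percent_frequency(curve, 50) == pytest.approx(ref, rel=0.03)

    def test_ideal_binary_edge_near_flat(self):
        # razor-sharp disc: modulation stays >= 0.95 up to Nyquist/2
        n, pitch = 256, 0.1
        x = (np.arange(n) - (n - 1) / 2) * pitch
        img = 1000.0 * (np.hypot(x[:, None], x[None, :]) <= 6.0)
        vol = ImageVolume(img[None], pitch, pitch, 0.5)
        curve = mtf_from_circular_edge(vol)
        sel = curve.frequencies <= vol.nyquist / 2
        assert np.all(curve.modulation[sel] >= 0.95)

    def test_f50_decreases_with_blur(self):
        f50s = []
        for sigma in (0.15, 0.25, 0.40):
            vol, _ = simulate_rod_image(PhantomTruth(psf_sigma=sigma,
                                                     rod_radius=6.0),
                                        grid_size=256, pixel_pitch=0.1)
            curve = mtf_from_circular_edge(vol, window_mm=12.0)
            f50s.append(mtf_percent_frequency(curve, 50))
        assert f50s[0] > f50s[1] > f50s[2]

    def test_centre_refinement(self):
        truth = PhantomTruth(psf_sigma=0.2, rod_radius=6.0)
        vol, _ = simulate_rod_image(truth, grid_size=256, pixel_pitch=0.1,
                                    rod_centre=(1.37, -2.11))
        est = CircularEdgeMTF().fit(vol)
        assert est.centre_mm_[0] == pytest.approx(1.37, abs=0.05)
        assert est.centre_mm_[1] == pytest.approx(-2.11, abs=0.05)
        assert est.radius_mm_ == pytest.approx(6.0, abs=0.1)
        assert est.fit_residual_px_ <= 0.5

    def test_truncated_rod_rejected(self):
        n, pitch = 64, 0.2
        x = (np.arange(n) - (n - 1) / 2) * pitch
        img = 1000.0 * (np.hypot(x[:, None], (x - 5.0)[None, :]) <= 6.0)
        vol = ImageVolume(img[None], pitch, pitch, 0.5)
        with pytest.raises(CTIQError, match="truncated|border"):
            mtf_from_circular_edge(vol)


class TestCrossMethodAndPosition:
    def test_wire_and_edge_agree_on_shared_truth(self):
        sigma = 0.1874
        wire_vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=sigma),
                                          grid_size=128, pixel_pitch=0.1)
        rod_vol, _ = simulate_rod_image(PhantomTruth(psf_sigma=sigma,
                                                     rod_radius=6.0),
                                        grid_size=256, pixel_pitch=0.1)
        f50_wire = mtf_percent_frequency(mtf_from_wire(wire_vol, **WIRE_OPTS), 50)
        f50_edge = mtf_percent_frequency(
            mtf_from_circular_edge(rod_vol, window_mm=12.0), 50)
        assert abs(f50_wire - f50_edge) / f50_edge < 0.03

    def test_mtf_vs_position_monotone(self):
        # PSF widening with offset (off-centre blur): f50 strictly decreasing
        vols = {}
        for off, sigma in [(0.0, 0.15), (50.0, 0.22), (100.0, 0.30)]:
            vols[off], _ = simulate_rod_image(PhantomTruth(psf_sigma=sigma,
                                                           rod_radius=6.0),
                                              grid_size=256, pixel_pitch=0.1)
        table = mtf_vs_position(vols, window_mm=12.0)
        f50s = [mtf_percent_frequency(c, 50) for _, c in table]
        assert [o for o, _ in table] == [0.0, 50.0, 100.0]
        assert f50s[0] > f50s[1] > f50s[2]

    def test_single_offset(self):
        vol, _ = simulate_rod_image(PhantomTruth(psf_sigma=0.2, rod_radius=6.0),
                                    grid_size=256, pixel_pitch=0.1)
        table = mtf_vs_position({0.0: vol})
        assert len(table) == 1

    def test_error_carries_offset_label(self):
        bad = ImageVolume(np.zeros((1, 32, 32)), 0.2, 0.2, 0.5)
        with pytest.raises(CTIQError, match="15"):
            mtf_vs_position({15.0: bad})

    def test_summary_handles_unreached_thresholds(self):
        vol, _ = simulate_wire_image(PhantomTruth(psf_sigma=0.0),
                                     grid_size=97, pixel_pitch=0.05)
        s = mtf_summary(mtf_from_wire(vol))
        assert s["f50"] is None  # near-delta system never falls to 50%
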