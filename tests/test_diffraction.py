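"""Detector q-mapping, integration, peak/orientation fits, collagen maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonevasc import (AzimuthalProfile, DetectorGeometry, DiffractionSimSpec,
                      RadialProfile, azimuthal_integrate, build_collagen_map,
                      fit_collagen_peak, fit_orientation, q_map,
                      radial_integrate, simulate_diffraction_pattern,
                      simulate_scan_grid)
from bonevasc.diffraction import polar_rebin
from bonevasc.diffsim import expected_orientation_degree


def angdiff(a, b):
    """Angular distance modulo 180 degrees."""
    return np.abs((np.asarray(a) - np.asarray(b) + 90.0) % 180.0 - 90.0)


class TestQMap:
    def test_beam_center_pixel_q_zero(self):
        geom = DetectorGeometry(shape=(65, 65), beam_center=(32.0, 32.0))
        q, _ = q_map(geom)
        assert q[32, 32] == 0.0

    def test_r_equals_L_closed_form(self):
        # at r = L the scattering angle 2theta = 45 deg
        geom = DetectorGeometry(distance_mm=1.0, pixel_size_mm=1.0,
                                shape=(3, 3), beam_center=(1.0, 1.0))
        q, _ = q_map(geom)
        expected = 4 * np.pi * np.sin(np.deg2rad(22.5)) / geom.wavelength_nm
        assert q[1, 2] == pytest.approx(expected, rel=1e-12)

    def test_hand_computed_value_at_100_pixels(self):
        # lambda = 0.0976 nm, L = 1.1 m, 50 um pixels, r = 100 px = 5 mm:
        # 2theta = atan(5 / 1100), q = 4 pi sin(theta) / lambda
        geom = DetectorGeometry(beam_center=(1024.0, 1024.0))
        q, _ = q_map(geom)
        theta = 0.5 * np.arctan(5.0 / 1100.0)
        assert q[1024, 1124] == pytest.approx(
            4 * np.pi * np.sin(theta) / 0.0976, rel=1e-6)

    def test_phi_quadrants(self):
        geom = DetectorGeometry(shape=(65, 65), beam_center=(32.0, 32.0))
        _, phi = q_map(geom)
        assert phi[32, 50] == pytest.approx(0.0)
        assert phi[50, 32] == pytest.approx(90.0)
        assert phi[32, 10] == pytest.approx(180.0)

    @given(st.integers(1, 31))
    @settings(max_examples=20, deadline=None)
    def test_q_increases_with_radius(self, r):
        geom = DetectorGeometry(shape=(65, 65), beam_center=(32.0, 32.0),
                                distance_mm=20.0)
        q, _ = q_map(geom)
        assert q[32, 32 + r] > q[32, 32 + r - 1]

    def test_beam_center_outside_rejected(self):
        with pytest.raises(ValueError):
            DetectorGeometry(shape=(16, 16), beam_center=(100.0, 0.0))


class TestIntegration:
    def test_constant_pattern_flat_profiles(self, sim_geometry):
        pat = np.full(sim_geometry.shape, 7.0)
        rp = radial_integrate(pat, sim_geometry, q_range=(0.5, 9.0))
        assert np.allclose(rp.intensity[rp.counts > 0], 7.0)
        ap = azimuthal_integrate(pat, sim_geometry)
        assert np.allclose(ap.intensity[ap.counts > 0], 7.0)

    def test_ring_lands_in_peak_bin(self, sim_spec, sim_geometry):
        pat = simulate_diffraction_pattern(sim_spec)
        rp = radial_integrate(pat, sim_geometry, n_bins=100,
                              q_range=(3.0, 8.0))
        qmax = rp.q[np.nanargmax(np.where(rp.counts > 0, rp.intensity,
                                          -np.inf))]
        assert abs(qmax - sim_spec.q_c_true) < 0.2

    def test_oriented_pattern_peaks_at_truth_angles(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry,
                                  orientation_angle_true=30.0,
                                  aligned_fraction_true=0.8)
        ap = azimuthal_integrate(simulate_diffraction_pattern(spec),
                                 sim_geometry)
        top = ap.phi[np.argsort(ap.intensity)[-6:]]
        assert np.all(np.minimum(angdiff(top, 30.0), angdiff(top, 30.0)) < 20)

    def test_out_of_range_q_window_rejected(self, sim_geometry):
        pat = np.zeros(sim_geometry.shape)
        with pytest.raises(ValueError):
            azimuthal_integrate(pat, sim_geometry, q_window=(100.0, 110.0))
        with pytest.raises(ValueError):
            radial_integrate(pat, sim_geometry, q_range=(100.0, 110.0))

    def test_polar_rebin_conserves_counts(self, sim_spec, sim_geometry):
        pat = simulate_diffraction_pattern(sim_spec)
        hist = polar_rebin(pat, sim_geometry, n_q=50, n_phi=36)
        assert hist.sum() == pytest.approx(pat.sum(), rel=1e-9)


class TestSimulator:
    def test_isotropic_when_unaligned(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry,
                                  aligned_fraction_true=0.0)
        ap = azimuthal_integrate(simulate_diffraction_pattern(spec),
                                 sim_geometry)
        iv = ap.intensity[ap.counts > 0]
        # square-pixel binning of the ring leaves a few percent of scatter
        assert (iv.max() - iv.min()) / iv.mean() < 0.05

    def test_no_peak_gives_pure_background(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry, peak_amplitude=0.0)
        pat = simulate_diffraction_pattern(spec)
        q, _ = q_map(sim_geometry)
        assert np.allclose(pat, spec.background(q), rtol=1e-12)

    def test_half_turn_symmetry_without_noise(self, sim_spec, sim_geometry):
        ap = azimuthal_integrate(simulate_diffraction_pattern(sim_spec),
                                 sim_geometry, n_bins=36)
        half = len(ap.phi) // 2
        good = (ap.counts[:half] > 0) & (ap.counts[half:] > 0)
        assert np.allclose(ap.intensity[:half][good],
                           ap.intensity[half:][good], rtol=0.02)

    def test_deterministic_noise(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry, poisson_noise=True,
                                  rng_seed=5)
        assert np.array_equal(simulate_diffraction_pattern(spec),
                              simulate_diffraction_pattern(spec))

    def test_ring_outside_detector_rejected(self):
        geom = DetectorGeometry(shape=(64, 64), distance_mm=2000.0,
                                pixel_size_mm=0.05)
        with pytest.raises(ValueError):
            simulate_diffraction_pattern(DiffractionSimSpec(geometry=geom))


class TestPeakFit:
    def test_noiseless_parameter_recovery(self, sim_spec, sim_geometry):
        rp = radial_integrate(simulate_diffraction_pattern(sim_spec),
                              sim_geometry, n_bins=200, q_range=(0.5, 9.5))
        fit = fit_collagen_peak(rp)
        assert fit.ok
        assert fit.q_c == pytest.approx(sim_spec.q_c_true, rel=1e-3)
        assert fit.sigma_q == pytest.approx(sim_spec.peak_sigma_q, rel=0.05)

    @pytest.mark.parametrize("bkg_model, coeffs", [
        ("poly2", (120.0, -8.0, 0.2)),
        ("powerlaw", (400.0, 0.8)),
    ])
    def test_background_models(self, sim_geometry, bkg_model, coeffs):
        spec = DiffractionSimSpec(geometry=sim_geometry,
                                  background_model=bkg_model,
                                  background_coeffs=coeffs)
        rp = radial_integrate(simulate_diffraction_pattern(spec),
                              sim_geometry, n_bins=200, q_range=(0.5, 9.5))
        fit = fit_collagen_peak(rp, background_model=bkg_model)
        assert fit.ok
        assert fit.q_c == pytest.approx(spec.q_c_true, rel=5e-3)

    def test_lateral_spacing_identity(self, sim_spec, sim_geometry):
        rp = radial_integrate(simulate_diffraction_pattern(sim_spec),
                              sim_geometry, n_bins=200, q_range=(0.5, 9.5))
        fit = fit_collagen_peak(rp)
        assert abs(fit.lateral_spacing_nm * fit.q_c - 2 * np.pi) < 1e-12
        # a 5.6 nm^-1 ring corresponds to ~1.12 nm lateral packing
        assert fit.lateral_spacing_nm == pytest.approx(2 * np.pi / 5.6,
                                                       rel=2e-3)

    def test_no_peak_flagged(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry, peak_amplitude=0.0)
        rp = radial_integrate(simulate_diffraction_pattern(spec),
                              sim_geometry, n_bins=200, q_range=(0.5, 9.5))
        fit = fit_collagen_peak(rp)
        assert not fit.ok
        assert abs(fit.peak_area) < 0.05 * 400.0  # negligible vs default amp

    def test_window_too_small_raises(self, sim_spec, sim_geometry):
        rp = radial_integrate(simulate_diffraction_pattern(sim_spec),
                              sim_geometry, n_bins=20, q_range=(0.5, 9.5))
        with pytest.raises(ValueError):
            fit_collagen_peak(rp, window=(5.5, 5.7))

    def test_noisy_recovery_within_half_percent(self, sim_geometry):
        errs = []
        for seed in range(100):
            spec = DiffractionSimSpec(geometry=sim_geometry,
                                      poisson_noise=True, rng_seed=900 + seed)
            rp = radial_integrate(simulate_diffraction_pattern(spec),
                                  sim_geometry, n_bins=150,
                                  q_range=(0.5, 9.5))
            fit = fit_collagen_peak(rp)
            errs.append(abs(fit.q_c - spec.q_c_true) / spec.q_c_true)
        assert np.median(errs) < 0.005


class TestOrientationFit:
    def test_flat_profile_degree_zero(self):
        phi = np.arange(0, 360, 5.0) + 2.5
        ap = AzimuthalProfile(phi, np.full_like(phi, 50.0),
                              np.ones_like(phi))
        fit = fit_orientation(ap)
        assert fit.degree == 0.0
        assert fit.ok

    def test_angle_recovery_within_two_degrees(self, sim_geometry):
        for angle in (0.0, 30.0, 117.0):
            spec = DiffractionSimSpec(geometry=sim_geometry,
                                      orientation_angle_true=angle,
                                      poisson_noise=True, rng_seed=11)
            ap = azimuthal_integrate(simulate_diffraction_pattern(spec),
                                     sim_geometry)
            fit = fit_orientation(ap)
            assert angdiff(fit.orientation_angle_deg, angle) < 2.0

    def test_degree_matches_analytic_oracle(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry)
        ap = azimuthal_integrate(simulate_diffraction_pattern(spec),
                                 sim_geometry)
        fit = fit_orientation(ap)
        want = expected_orientation_degree(spec, ap.q_window)
        assert fit.degree == pytest.approx(want, rel=0.10)

    def test_degree_monotone_in_aligned_fraction(self, sim_geometry):
        degrees = []
        for f in (0.2, 0.5, 0.8):
            spec = DiffractionSimSpec(geometry=sim_geometry,
                                      aligned_fraction_true=f)
            ap = azimuthal_integrate(simulate_diffraction_pattern(spec),
                                     sim_geometry)
            degrees.append(fit_orientation(ap).degree)
        assert degrees[0] < degrees[1] < degrees[2]

    def test_ratio_invariant_under_common_scaling(self):
        phi = np.arange(0, 360, 5.0) + 2.5
        from bonevasc.diffraction import wrapped_gaussian_pair
        iv = 40.0 + wrapped_gaussian_pair(phi, 60.0, 45.0, 20.0)
        f1 = fit_orientation(AzimuthalProfile(phi, iv, np.ones_like(phi)))
        f2 = fit_orientation(AzimuthalProfile(phi, 2 * iv, np.ones_like(phi)))
        assert f2.degree == pytest.approx(f1.degree, rel=1e-3)


class TestCollagenMap:
    def test_constant_grid_constant_maps(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry)
        pats = simulate_scan_grid(spec, np.ones((2, 2)),
                                  np.full((2, 2), 40.0),
                                  np.full((2, 2), 0.5))
        cm = build_collagen_map(pats, sim_geometry)
        assert cm.quality.all()
        assert np.ptp(cm.amount) < 0.01 * cm.amount.mean()
        assert np.ptp(cm.angle_deg) < 0.5

    def test_zero_amount_position_masked(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry)
        amount = np.array([[1.0, 0.0]])
        pats = simulate_scan_grid(spec, amount, np.full((1, 2), 30.0),
                                  np.full((1, 2), 0.5))
        cm = build_collagen_map(pats, sim_geometry)
        assert cm.quality[0, 0]
        assert not cm.quality[0, 1]

    def test_map_shape_mismatch_rejected(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry)
        with pytest.raises(ValueError):
            simulate_scan_grid(spec, np.ones((2, 2)), np.ones((3, 2)),
                               np.ones((2, 2)))

    def test_step_edge_angle_field_recovered(self, sim_geometry):
        spec = DiffractionSimSpec(geometry=sim_geometry, poisson_noise=True,
                                  rng_seed=3)
        gy, gx = 4, 6
        angle = np.where(np.arange(gx)[None, :] < gx // 2, 0.0, 90.0) \
            * np.ones((gy, 1))
        pats = simulate_scan_grid(spec, np.ones((gy, gx)), angle,
                                  np.full((gy, gx), 0.6))
        cm = build_collagen_map(pats, sim_geometry)
        err = angdiff(cm.angle_deg, angle)
        away = np.c_[err[:, :gx // 2 - 1], err[:, gx // 2 + 1:]]
        assert away.max() < 2.0
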