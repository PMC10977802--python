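"""Acoustic module: bowl tiling, Rayleigh–Sommerfeld sum, angular spectrum."""

import numpy as np
import pytest

from hifusim.acoustic import (
    AcousticMedium,
    CalibrationError,
    InvalidGeometryError,
    asa_propagate,
    calibrate_to_focal_intensity,
    discretize_bowl,
    intensity_field,
    oneil_on_axis_pressure,
    propagate_volume,
    rs_pressure,
    spherical_cap_area,
)


class TestDiscretizeBowl:
    def test_total_area_matches_analytic_cap(self):
        g = discretize_bowl(130.0, 64.0, 1.0)
        cap = spherical_cap_area(130.0, 64.0)
        assert g.total_area_mm2 == pytest.approx(cap, rel=0.02)

    def test_halving_subelement_quadruples_count(self):
        coarse = discretize_bowl(40.0, 15.0, 1.0, 0.7)
        fine = discretize_bowl(40.0, 15.0, 1.0, 0.35)
        ratio = fine.n_elements / coarse.n_elements
        assert 4.0 * 0.8 <= ratio <= 4.0 * 1.2

    def test_centers_on_focal_sphere(self):
        g = discretize_bowl(60.0, 25.0, 1.0)
        r = np.linalg.norm(g.centers_mm, axis=1)
        assert np.allclose(r, 60.0, atol=1e-9)

    @pytest.mark.parametrize(
        "F,a", [(130.0, 0.0), (0.0, 64.0), (-10.0, 5.0), (50.0, 60.0)]
    )
    def test_invalid_geometry_rejected(self, F, a):
        with pytest.raises(InvalidGeometryError):
            discretize_bowl(F, a, 1.0)

    def test_too_coarse_subelement_refused(self):
        # λ/2 at 1 MHz in water is ~0.74 mm
        with pytest.raises(InvalidGeometryError, match="coarser"):
            discretize_bowl(40.0, 15.0, 1.0, 2.0)


class TestRayleighSommerfeld:
    def test_on_axis_matches_oneil_closed_form(self, small_bowl, water_lossless):
        """Independent analytic oracle for the focused-bowl axial field."""
        F = small_bowl.focal_length_mm
        z = np.linspace(0.5 * F, 1.5 * F, 41)
        targets = np.column_stack([np.zeros_like(z), np.zeros_like(z), z - F])
        p = rs_pressure(small_bowl, water_lossless, targets)
        p_ref = oneil_on_axis_pressure(z, F, small_bowl.aperture_radius_mm, 1.0,
                                       water_lossless)
        err = np.abs(np.abs(p) - np.abs(p_ref)) / np.abs(p_ref)
        assert err.max() < 0.01

    def test_linearity_in_drive(self, small_bowl, water_lossless):
        targets = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, -5.0]])
        p1 = rs_pressure(small_bowl, water_lossless, targets)
        p2 = rs_pressure(small_bowl.scaled(2.0), water_lossless, targets)
        assert np.allclose(p2, 2.0 * p1, rtol=1e-12)

    def test_sum_of_drives_gives_sum_of_fields(self, small_bowl, water_lossless):
        rng = np.random.default_rng(0)
        d1 = rng.normal(size=small_bowl.n_elements) + 0j
        d2 = rng.normal(size=small_bowl.n_elements) + 0j
        import dataclasses

        targets = np.array([[0.0, 0.0, 0.0], [0.5, -0.5, 3.0]])
        g1 = dataclasses.replace(small_bowl, drive=d1)
        g2 = dataclasses.replace(small_bowl, drive=d2)
        g12 = dataclasses.replace(small_bowl, drive=d1 + d2)
        p = rs_pressure(g12, water_lossless, targets)
        assert np.allclose(
            p,
            rs_pressure(g1, water_lossless, targets)
            + rs_pressure(g2, water_lossless, targets),
            rtol=1e-10,
        )

    def test_attenuation_reduces_focal_pressure(self, small_bowl):
        focus = np.array([[0.0, 0.0, 0.0]])
        lossless = AcousticMedium(1482.0, 994.0, 0.0)
        lossy = AcousticMedium(1482.0, 994.0, 0.5)
        p0 = abs(rs_pressure(small_bowl, lossless, focus)[0])
        p1 = abs(rs_pressure(small_bowl, lossy, focus)[0])
        assert p1 < p0

    def test_target_on_element_center_is_singular(self, small_bowl, water_lossless):
        with pytest.raises(ValueError, match="singular"):
            rs_pressure(small_bowl, water_lossless,
                        small_bowl.centers_mm[:1])


class TestAngularSpectrum:
    def _gaussian_plane(self, n=128, dx=0.3, sigma=2.0):
        x = (np.arange(n) - (n - 1) / 2) * dx
        X, Y = np.meshgrid(x, x)
        return np.exp(-(X**2 + Y**2) / (2 * sigma**2)).astype(complex), dx

    def test_zero_step_is_identity(self, water_lossless):
        p, dx = self._gaussian_plane()
        out = asa_propagate(p, dx, 0.0, 1.0, water_lossless)
        assert np.array_equal(out, p)

    def test_backward_propagation_rejected(self, water_lossless):
        p, dx = self._gaussian_plane()
        with pytest.raises(ValueError, match="backward"):
            asa_propagate(p, dx, -1.0, 1.0, water_lossless)

    def test_semigroup_two_half_steps(self, water_lossless):
        p, dx = self._gaussian_plane()
        one = asa_propagate(p, dx, 8.0, 1.0, water_lossless)
        half = asa_propagate(p, dx, 4.0, 1.0, water_lossless)
        two = asa_propagate(half, dx, 4.0, 1.0, water_lossless)
        assert np.max(np.abs(one - two)) / np.max(np.abs(one)) < 1e-6

    def test_hybrid_matches_direct_rs_in_focal_region(
        self, small_bowl, water_lossless
    ):
        """RS seed + ASA marching agrees with pointwise RS at the focus."""
        n, dx = 128, 0.2
        x = (np.arange(n) - (n - 1) / 2) * dx
        vol = propagate_volume(
            small_bowl, water_lossless, x, x,
            np.array([-12.0, -8.0, -4.0, -2.0, 0.0]),
        )
        X, Y = np.meshgrid(x, x)
        direct = rs_pressure(
            small_bowl, water_lossless,
            np.stack([X, Y, np.zeros_like(X)], axis=-1),
        )
        m = np.abs(direct)
        region = m >= 0.5 * m.max()
        err = np.abs(np.abs(vol[-1]) - m)[region] / m[region]
        assert err.max() < 0.02


class TestIntensity:
    def test_zero_pressure_gives_zero_intensity(self, water_lossless):
        f = intensity_field(np.zeros((3, 3), dtype=complex), water_lossless)
        assert np.all(f.I == 0)

    def test_quadratic_in_pressure(self, water_lossless):
        p = np.array([[1.0 + 0j, 2.0 + 0j]])
        f1 = intensity_field(p, water_lossless)
        f2 = intensity_field(2 * p, water_lossless)
        assert np.allclose(f2.I, 4 * f1.I)

    def test_plane_wave_formula(self):
        med = AcousticMedium(1482.0, 994.0, 0.0)
        f = intensity_field(np.array([1.0 + 0j]), med)
        expected_w_m2 = 1.0 / (2 * 994.0 * 1482.0)
        assert f.I[0] == pytest.approx(expected_w_m2 * 1e-4, rel=1e-12)


class TestCalibration:
    def test_recalibration_is_idempotent(self, small_bowl, water_lossless):
        g1, _ = calibrate_to_focal_intensity(small_bowl, water_lossless, 1.0)
        _, factor2 = calibrate_to_focal_intensity(g1, water_lossless, 1.0)
        assert factor2 == pytest.approx(1.0, abs=1e-6)

    def test_peak_intensity_hits_target(self, small_bowl, water_lossless):
        g, _ = calibrate_to_focal_intensity(small_bowl, water_lossless, 1.0)
        z = np.linspace(-10, 10, 81)
        p = rs_pressure(
            g, water_lossless,
            np.column_stack([np.zeros_like(z), np.zeros_like(z), z]),
        )
        peak = np.max(np.abs(p) ** 2) / (2 * 994.0 * 1482.0) * 1e-4
        assert 0.999e3 <= peak <= 1.001e3  # kW/cm² target on a W/cm² scale

    def test_amplitude_ratio_between_preset_intensities(
        self, small_bowl, water_lossless
    ):
        gA, _ = calibrate_to_focal_intensity(small_bowl, water_lossless, 0.8)
        gB, _ = calibrate_to_focal_intensity(small_bowl, water_lossless, 1.0)
        ratio = abs(gA.drive[0]) / abs(gB.drive[0])
        assert ratio == pytest.approx(np.sqrt(0.8), rel=1e-9)

    def test_zero_drive_cannot_calibrate(self, small_bowl, water_lossless):
        with pytest.raises(CalibrationError):
            calibrate_to_focal_intensity(
                small_bowl.scaled(0.0), water_lossless, 1.0
            )
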