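"""Optical thicknesses, phase functions, transmissions and the sky transfer."""

import math

import numpy as np
import pytest

from lampspec.atmosphere import (
    AtmosphereConfig,
    SceneGeometry,
    aerosol_tau,
    combined_phase,
    config_from_file,
    extinction_profile,
    hg_phase,
    normalize_at,
    path_transmission,
    rayleigh_phase,
    rayleigh_tau,
    scattering_angle,
    sky_transfer,
)
from lampspec.core import GRID, SpectralCurve

CFG = AtmosphereConfig()


def sphere_integral(phase_at_theta):
    theta = np.linspace(0.0, 180.0, 8001)
    rad = np.radians(theta)
    return 2 * math.pi * np.trapezoid(phase_at_theta(theta) * np.sin(rad), rad)


class TestOpticalThickness:
    def test_rayleigh_strictly_decreasing(self):
        tau = rayleigh_tau(GRID)
        assert np.all(np.diff(tau) < 0)

    def test_rayleigh_dispersion_ratio(self):
        # ~lambda^-4 with weak correction terms.
        assert 6 <= rayleigh_tau(400.0) / rayleigh_tau(650.0) <= 8

    def test_rayleigh_matches_hand_evaluation_at_550(self):
        lam = 0.55  # micrometres
        expected = 0.008569 * lam**-4 * (1 + 0.0113 * lam**-2 + 0.00013 * lam**-4)
        assert rayleigh_tau(550.0) == pytest.approx(expected, abs=1e-6)

    def test_aerosol_reference_value(self):
        assert aerosol_tau(CFG.lambda_ref, CFG) == pytest.approx(0.2)

    def test_aerosol_angstrom_law(self):
        flat = AtmosphereConfig(angstrom=0.0)
        assert aerosol_tau(700.0, flat) == pytest.approx(0.2)
        one = AtmosphereConfig(angstrom=1.0)
        assert aerosol_tau(2 * one.lambda_ref, one) == pytest.approx(0.1)

    def test_rayleigh_vs_aerosol_crossover(self):
        # Molecular column dominates in the blue, aerosols in the red.
        assert rayleigh_tau(400.0) > aerosol_tau(400.0, CFG)
        assert rayleigh_tau(650.0) < aerosol_tau(650.0, CFG)


class TestExtinctionProfile:
    def test_column_integral_recovers_total_tau(self):
        z = np.geomspace(1e-4, 400.0, 60000)
        for lam in (420.0, 550.0, 700.0):
            integral = np.trapezoid(extinction_profile(lam, z, CFG), z)
            assert integral == pytest.approx(
                rayleigh_tau(lam) + aerosol_tau(lam, CFG), abs=1e-4
            )

    def test_molecular_part_scale_height(self):
        lam = 550.0
        pure = AtmosphereConfig(tau_a0=0.0)
        k0 = extinction_profile(lam, 0.0, pure)
        k_h = extinction_profile(lam, pure.molecular_scale_height, pure)
        assert k_h == pytest.approx(k0 / math.e, rel=1e-12)

    def test_blue_extinction_exceeds_red_at_ground(self):
        assert extinction_profile(400.0, 0.0, CFG) > extinction_profile(650.0, 0.0, CFG)


class TestPathTransmission:
    def test_zero_length_path(self):
        assert path_transmission(550.0, (1, 2, 0.5), (1, 2, 0.5), CFG) == 1.0

    def test_vertical_column(self):
        total = rayleigh_tau(550.0) + aerosol_tau(550.0, CFG)
        t = path_transmission(550.0, (0, 0, 0), (0, 0, 300.0), CFG, n_samples=6000)
        assert t == pytest.approx(math.exp(-total), abs=1e-4)

    def test_secant_law_at_60_degrees(self):
        total = rayleigh_tau(550.0) + aerosol_tau(550.0, CFG)
        x = 300.0 * math.tan(math.radians(60.0))
        t = path_transmission(550.0, (0, 0, 0), (x, 0, 300.0), CFG, n_samples=8000)
        assert t == pytest.approx(math.exp(-2 * total), rel=0.01)


class TestScatteringAngle:
    def test_identical_directions(self):
        assert scattering_angle(30.0, 40.0, 30.0, 40.0) == pytest.approx(0.0, abs=1e-9)

    def test_opposed_horizontal_directions(self):
        assert scattering_angle(90.0, 0.0, 90.0, 180.0) == pytest.approx(180.0)

    def test_agrees_with_cartesian_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            z1, z2 = rng.uniform(0, 180, 2)
            a1, a2 = rng.uniform(0, 360, 2)

            def unit(z, a):
                z, a = math.radians(z), math.radians(a)
                return np.array(
                    [math.sin(z) * math.cos(a), math.sin(z) * math.sin(a), math.cos(z)]
                )

            oracle = math.degrees(
                math.acos(np.clip(unit(z1, a1) @ unit(z2, a2), -1, 1))
            )
            assert scattering_angle(z1, a1, z2, a2) == pytest.approx(oracle, abs=1e-9)


class TestPhaseFunctions:
    def test_rayleigh_normalized(self):
        assert sphere_integral(rayleigh_phase) == pytest.approx(1.0, abs=1e-6)

    def test_rayleigh_forward_to_side_ratio_is_two(self):
        assert rayleigh_phase(0.0) / rayleigh_phase(90.0) == pytest.approx(2.0)

    def test_rayleigh_forward_backward_symmetry(self):
        assert rayleigh_phase(0.0) == pytest.approx(rayleigh_phase(180.0))

    def test_hg_isotropic_limit(self):
        theta = np.linspace(0, 180, 19)
        np.testing.assert_allclose(hg_phase(theta, 0.0), 1 / (4 * math.pi))

    def test_hg_normalized(self):
        assert sphere_integral(lambda t: hg_phase(t, 0.8)) == pytest.approx(1.0, abs=1e-6)

    def test_hg_asymmetry_parameter_is_cosine_mean(self):
        theta = np.linspace(0.0, 180.0, 40001)
        rad = np.radians(theta)
        mean_cos = (
            2
            * math.pi
            * np.trapezoid(hg_phase(theta, 0.8) * np.cos(rad) * np.sin(rad), rad)
        )
        assert mean_cos == pytest.approx(0.8, abs=1e-4)

    def test_hg_rejects_invalid_g(self):
        with pytest.raises(ValueError):
            hg_phase(90.0, 1.0)

    def test_combined_degenerates_to_rayleigh_without_aerosols(self):
        pure = AtmosphereConfig(tau_a0=0.0)
        theta = np.linspace(0, 180, 37)
        np.testing.assert_allclose(
            combined_phase(550.0, theta, 1.0, pure), rayleigh_phase(theta), rtol=1e-12
        )

    def test_combined_degenerates_to_hg_at_high_altitude_aerosol_dominance(self):
        # With a vanishing molecular column the mixture is pure aerosol.
        aero = AtmosphereConfig(tau_a0=0.2, molecular_scale_height=1e-6)
        theta = np.linspace(0, 180, 37)
        np.testing.assert_allclose(
            combined_phase(550.0, theta, 5.0, aero), hg_phase(theta, aero.g), rtol=1e-9
        )

    def test_combined_mixture_normalized(self):
        for z in (0.0, 1.0, 10.0):
            integ = sphere_integral(lambda t: combined_phase(550.0, t, z, CFG))
            assert integ == pytest.approx(1.0, abs=1e-5)


class TestSkyTransfer:
    def test_no_scatterers_no_skyglow(self):
        # Remove aerosols entirely and dilute the molecular column to nothing:
        # the received skyglow collapses by many orders of magnitude.
        void = AtmosphereConfig(tau_a0=0.0, molecular_scale_height=1e9)
        tf_void = sky_transfer(5.0, "clear", void)
        tf_ref = sky_transfer(5.0, "clear")
        assert np.all(tf_void.curve.values < 1e-6 * tf_ref.curve.values)

    def test_linear_in_source_spectrum(self):
        from lampspec.core import multiply

        tf = sky_transfer(5.0, "clear")
        spd = SpectralCurve(GRID.copy(), 1.0 + np.sin(GRID / 50.0) ** 2)
        received = multiply(spd, tf.curve)
        received2 = multiply(spd.scaled(2.0), tf.curve)
        np.testing.assert_allclose(received2.values, 2 * received.values, rtol=1e-12)

    def test_blue_enhancement_fades_with_distance(self, clear_transfers):
        def blue_red(tf):
            return tf.curve.value_at(450) / tf.curve.value_at(650)

        assert blue_red(clear_transfers[30]) < blue_red(clear_transfers[0])

    def test_energy_sanity(self, clear_transfers):
        # Relative units: received scattered radiance never exceeds the unit
        # source output for any wavelength or distance.
        for tf in clear_transfers.values():
            assert np.all(tf.curve.values <= 1.0)
            assert np.all(tf.curve.values >= 0.0)

    def test_quadrature_step_doubling_below_half_percent(self):
        for sky, d in (("clear", 0.0), ("clear", 10.0), ("cloudy", 2.0)):
            t1 = sky_transfer(d, sky, n_steps=100).curve.values
            t2 = sky_transfer(d, sky, n_steps=200).curve.values
            assert np.max(np.abs(t2 - t1) / t1) < 0.005

    def test_cloudy_requires_cloud_base(self):
        from dataclasses import replace

        cfg = replace(AtmosphereConfig(), cloud_base=None)
        with pytest.raises(ValueError, match="cloud_base"):
            sky_transfer(1.0, "cloudy", cfg)

    def test_observer_views_agree_in_sign_of_blue_boost(self):
        # All observer modes see a blue-enhanced sky near the source.
        for view in ("zenith", "dome", "hemisphere"):
            tf = sky_transfer(0.0, "clear", geom=SceneGeometry(view=view))
            assert tf.curve.value_at(450) / tf.curve.value_at(650) > 1.5


class TestNormalizeAt:
    def test_pins_value_to_one(self, clear_transfers):
        c = normalize_at(clear_transfers[5].curve, 550.0)
        assert c.value_at(550.0) == pytest.approx(1.0)

    def test_idempotent(self, clear_transfers):
        once = normalize_at(clear_transfers[5].curve, 550.0)
        twice = normalize_at(once, 550.0)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    def test_constant_curve_becomes_all_ones(self):
        const = SpectralCurve(GRID.copy(), np.full_like(GRID, 3.7), "transfer")
        np.testing.assert_allclose(normalize_at(const, 550.0).values, 1.0)

    def test_zero_at_anchor_rejected(self):
        c = SpectralCurve(GRID.copy(), np.where(GRID < 600, 1.0, 0.0), "transfer")
        with pytest.raises(ValueError, match="zero"):
            normalize_at(c, 700.0)


class TestConfigFile:
    def test_round_trip_overrides(self, tmp_path):
        p = tmp_path / "atmo.cfg"
        p.write_text("tau_a0 = 0.1\ng = 0.7\ncloud_base = 2.0\n# comment\n")
        cfg = config_from_file(p)
        assert cfg.tau_a0 == 0.1 and cfg.g == 0.7 and cfg.cloud_base == 2.0
        assert cfg.angstrom == 1.0  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "atmo.cfg"
        p.write_text("tau_typo = 0.1\n")
        with pytest.raises(ValueError, match="unknown configuration key"):
            config_from_file(p)
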