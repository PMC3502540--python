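"""Closed-form FCS model relations: diffusion times, amplitudes, conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcshpa.fcs_core import (
    AVOGADRO,
    ConfocalVolume,
    CorrelationCurve,
    DiffusingSpecies,
    calibrate_confocal_volume,
    calibrate_radial,
    concentration_to_particles,
    diffusion_time_from_coefficient,
    one_component_model,
    particles_to_concentration,
    two_component_model,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestDiffusionTime:
    @pytest.mark.parametrize(
        "d_cm2_s, r_um, expected_us",
        [
            # IgG antibody via Stokes-Einstein rounds to 200 us
            (3.7e-7, 0.17, 195.27),
            # rhodamine 6G calibration standard
            (2.8e-6, 0.17, 25.80),
        ],
    )
    def test_known_species(self, d_cm2_s, r_um, expected_us):
        tau = diffusion_time_from_coefficient(d_cm2_s, r_um)
        assert tau * 1e6 == pytest.approx(expected_us, rel=1e-3)

    def test_igg_time_rounds_to_200_us(self):
        tau_us = diffusion_time_from_coefficient(3.7e-7, 0.17) * 1e6
        assert round(tau_us, -1) == 200

    @given(d=positive, r=positive)
    @settings(max_examples=50, deadline=None)
    def test_calibration_round_trip(self, d, r):
        tau = diffusion_time_from_coefficient(d * 1e-7, r)
        assert calibrate_radial(d * 1e-7, tau) == pytest.approx(r, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            diffusion_time_from_coefficient(bad, 0.17)
        with pytest.raises(ValueError):
            diffusion_time_from_coefficient(2.8e-6, bad)


class TestConfocalCalibration:
    def test_rhodamine_calibration_reproduces_geometry(self):
        # tau_D of rhodamine 6G computed from the inverse relation
        tau = diffusion_time_from_coefficient(2.8e-6, 0.17)
        vol = calibrate_confocal_volume(tau, 2.8e-6, structural_parameter=5.18)
        assert vol.radial_r_um == pytest.approx(0.17, rel=1e-6)
        assert vol.axial_z_um == pytest.approx(0.88, rel=5e-3)

    def test_square_root_law(self):
        vol1 = calibrate_confocal_volume(25.8e-6, 2.8e-6, 5.18)
        vol4 = calibrate_confocal_volume(4 * 25.8e-6, 2.8e-6, 5.18)
        assert vol4.radial_r_um == pytest.approx(2 * vol1.radial_r_um, rel=1e-12)

    def test_structural_parameter_invariant_enforced(self):
        with pytest.raises(ValueError):
            ConfocalVolume(radial_r_um=0.17, axial_z_um=0.88, structural_parameter=3.0)
        # the printed geometry rounds to 5 and is accepted
        vol = ConfocalVolume()
        assert round(vol.axial_z_um / vol.radial_r_um) == vol.structural_parameter


class TestOneComponentModel:
    def test_amplitude(self):
        assert one_component_model(0.0, 4.0, 220e-6, 5.0) == pytest.approx(1.25)

    def test_value_at_tau_d(self):
        # G(tau_D) = 1 + 0.5/sqrt(1 + 1/25) for N = 1, s = 5
        expected = 1.0 + 0.5 / np.sqrt(1.04)
        assert one_component_model(220e-6, 1.0, 220e-6, 5.0) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.4903, abs=5e-5)

    def test_long_lag_asymptote(self):
        assert one_component_model(1e6 * 220e-6, 3.0, 220e-6, 5.0) == pytest.approx(
            1.0, abs=1e-2
        )

    @given(n=positive, tau_d=positive, s=st.floats(min_value=1, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_amplitude_law_and_monotonicity(self, n, tau_d, s):
        taus = np.logspace(-3, 3, 40) * tau_d * 1e-3
        g = one_component_model(taus, n, tau_d * 1e-3, s)
        assert one_component_model(0.0, n, tau_d * 1e-3, s) - 1 == pytest.approx(
            1 / n, rel=1e-12
        )
        assert np.all(np.diff(g) < 0)
        assert np.all(g > 1)


class TestTwoComponentModel:
    def test_amplitude_independent_of_y(self):
        for y in (0.0, 0.3, 1.0):
            assert two_component_model(0.0, 10.0, y, 220e-6, 483e-6, 5.0) == (
                pytest.approx(1.1)
            )

    @pytest.mark.parametrize("y, tau_ref", [(0.0, 220e-6), (1.0, 483e-6)])
    def test_reduces_to_one_component(self, y, tau_ref):
        taus = np.logspace(-6, -1, 30)
        g2 = two_component_model(taus, 7.0, y, 220e-6, 483e-6, 5.0)
        g1 = one_component_model(taus, 7.0, tau_ref, 5.0)
        np.testing.assert_allclose(g2, g1, rtol=1e-14)

    def test_printed_mixture_value(self):
        # hand-evaluated at tau = tau_D1 = 220 us, N' = 10, Y = 0.25
        assert two_component_model(
            220e-6, 10.0, 0.25, 220e-6, 483e-6, 5.0
        ) == pytest.approx(1.0538, abs=1e-4)

    @given(y=st.floats(min_value=0, max_value=1), n=positive, tau=positive)
    @settings(max_examples=50, deadline=None)
    def test_equal_times_collapse_mixture(self, y, n, tau):
        taus = np.logspace(-2, 2, 20) * tau * 1e-3
        g2 = two_component_model(taus, n, y, tau * 1e-3, tau * 1e-3, 5.0)
        g1 = one_component_model(taus, n, tau * 1e-3, 5.0)
        np.testing.assert_allclose(g2, g1, rtol=1e-12)

    def test_rejects_mole_fraction_outside_unit_interval(self):
        for y in (-0.1, 1.1):
            with pytest.raises(ValueError):
                two_component_model(1e-4, 10.0, y, 220e-6, 483e-6, 5.0)


class TestConcentrationConversion:
    def test_printed_conversion_factor(self):
        # N_A x V_eff = 30.115e7 particles per mol/l for the 5e-16 l volume
        assert AVOGADRO * 5e-16 == pytest.approx(30.115e7, rel=1e-12)

    def test_single_particle(self):
        assert particles_to_concentration(1.0, 5e-16) == pytest.approx(
            3.32e-9, rel=1e-3
        )

    def test_zero(self):
        assert particles_to_concentration(0.0) == 0.0

    @given(c=st.floats(min_value=1e-12, max_value=1e-3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, c):
        back = particles_to_concentration(concentration_to_particles(c))
        assert back == pytest.approx(c, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            particles_to_concentration(-1.0)


class TestDomainTypes:
    def test_curve_validation(self):
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([1e-6, 1e-6]), np.array([1.1, 1.05]))
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([1e-6, 2e-6]), np.array([1.1, np.nan]))
        with pytest.raises(ValueError):
            CorrelationCurve(
                np.array([1e-6, 2e-6]), np.array([1.1, 1.05]),
                stderr=np.array([0.01, -0.01]),
            )

    def test_curve_csv_round_trip(self, tmp_path):
        curve = CorrelationCurve(
            np.array([1e-6, 2e-6, 4e-6]), np.array([1.2, 1.15, 1.1]),
            stderr=np.array([0.01, 0.01, 0.02]),
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = CorrelationCurve.from_csv(path)
        np.testing.assert_allclose(back.lags_s, curve.lags_s)
        np.testing.assert_allclose(back.g, curve.g)
        np.testing.assert_allclose(back.stderr, curve.stderr)

    def test_species_consistency_check(self):
        vol = ConfocalVolume()
        tau_ok = diffusion_time_from_coefficient(3.7e-7, vol.radial_r_um)
        DiffusingSpecies("IgG", 3.7e-7, tau_ok, vol)  # consistent: no error
        with pytest.raises(ValueError):
            DiffusingSpecies("IgG", 3.7e-7, 2 * tau_ok, vol)
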