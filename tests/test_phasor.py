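"""Phasor transform, universal-circle geometry, calibration, lifetimes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phasorflim as pf
from phasorflim.phasor import phase_modulation

from conftest import (
    continuous_phasor,
    delta_stack,
    geometric_series_phasor,
    make_params,
)


class TestPhasorTransform:
    def test_delta_decay_lands_at_one_zero(self, params56):
        field = pf.phasor_transform(delta_stack(), params56)
        assert np.all(field.g == 1.0)
        assert np.all(field.s == 0.0)
        assert not field.calibrated

    def test_uniform_decay_lands_at_origin(self, params56):
        counts = np.full((3, 3, 56), 10.0)
        field = pf.phasor_transform(pf.FlimStack(counts=counts), params56)
        assert np.allclose(field.g, 0.0, atol=1e-12)
        assert np.allclose(field.s, 0.0, atol=1e-12)

    def test_noiseless_exponential_matches_geometric_series_oracle(self, params56):
        tau = 2.0
        stack = pf.simulate_stack(
            pf.GroundTruth(components=((tau, 1.0),), poisson_noise=False),
            (2, 2), params56,
        )
        field = pf.phasor_transform(stack, params56)
        z = geometric_series_phasor(tau, 56)
        assert field.g[0, 0] == pytest.approx(0.5244, abs=1e-4)
        assert field.s[0, 0] == pytest.approx(0.4721, abs=1e-4)
        assert abs(complex(field.g[0, 0], field.s[0, 0]) - z) < 1e-12

    def test_zero_intensity_pixel_is_undefined(self, params56):
        counts = np.zeros((2, 2, 56))
        counts[0, 0, 0] = 100.0
        field = pf.phasor_transform(pf.FlimStack(counts=counts), params56)
        assert np.isnan(field.g[1, 1]) and np.isnan(field.s[1, 1])
        assert field.g[0, 0] == 1.0

    def test_all_zero_stack_warns_and_is_undefined(self, params56):
        with pytest.warns(UserWarning, match="no photons"):
            field = pf.phasor_transform(
                pf.FlimStack(counts=np.zeros((2, 2, 56))), params56
            )
        assert np.all(np.isnan(field.g))

    def test_bin_count_mismatch_rejected(self, params56):
        with pytest.raises(ValueError, match="bins"):
            pf.phasor_transform(pf.FlimStack(counts=np.ones((2, 2, 32))), params56)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_linearity_summed_decays_give_weighted_mean_phasor(self, seed):
        """The phasor of a summed decay is the intensity-weighted average
        of the component phasors — the linear-combination law behind
        two-species mixing."""
        params = make_params(16)
        rng = np.random.default_rng(seed)
        h1 = rng.uniform(0.0, 50.0, 16)
        h2 = rng.uniform(0.0, 50.0, 16) + 1.0
        stacks = [
            pf.FlimStack(counts=h.reshape(1, 1, 16)) for h in (h1, h2, h1 + h2)
        ]
        f1, f2, f12 = (pf.phasor_transform(s, params) for s in stacks)
        w1, w2 = h1.sum(), h2.sum()
        expected_g = (w1 * f1.g + w2 * f2.g) / (w1 + w2)
        expected_s = (w1 * f1.s + w2 * f2.s) / (w1 + w2)
        assert f12.g[0, 0] == pytest.approx(expected_g[0, 0], abs=1e-12)
        assert f12.s[0, 0] == pytest.approx(expected_s[0, 0], abs=1e-12)

    @pytest.mark.parametrize("harmonic", [2, 3])
    def test_harmonic_n_equals_scaled_frequency_transform(self, harmonic):
        """Transforming at harmonic n is the same sum with ω replaced by
        nω, checked against the closed form at the scaled frequency."""
        params = make_params(56, harmonic=harmonic)
        stack = pf.simulate_stack(
            pf.GroundTruth(components=((1.5, 1.0),), poisson_noise=False),
            (1, 1), params,
        )
        field = pf.phasor_transform(stack, params)
        z = geometric_series_phasor(1.5, 56, harmonic=harmonic)
        assert abs(complex(field.g[0, 0], field.s[0, 0]) - z) < 1e-12


class TestPhaseModulation:
    @pytest.mark.parametrize(
        "g, s, phi, m",
        [
            (1.0, 0.0, 0.0, 1.0),
            (0.5, 0.5, np.pi / 4, np.sqrt(2) / 2),
            # theoretical fluorescein phasor at 80 MHz
            (0.19516589606986018, 0.3963283601776546, 1.1132191339602084,
             0.44177584369209255),
        ],
    )
    def test_polar_decomposition(self, params56, g, s, phi, m):
        field = pf.PhasorField(
            g=np.array([[g]]), s=np.array([[s]]),
            intensity=np.array([[1.0]]), params=params56,
        )
        phi_map, m_map = phase_modulation(field)
        assert phi_map[0, 0] == pytest.approx(phi, abs=1e-12)
        assert m_map[0, 0] == pytest.approx(m, abs=1e-12)

    def test_undefined_pixels_stay_undefined(self, params56):
        field = pf.PhasorField(
            g=np.array([[np.nan]]), s=np.array([[np.nan]]),
            intensity=np.array([[0.0]]), params=params56,
        )
        phi, m = phase_modulation(field)
        assert np.isnan(phi[0, 0]) and np.isnan(m[0, 0])


class TestTheoreticalPhasor:
    def test_zero_lifetime_at_one_zero(self, params56):
        assert pf.theoretical_phasor(0.0, params56) == (1.0, 0.0)

    @pytest.mark.parametrize(
        "tau, expected_g, expected_s",
        [(4.04, 0.1952, 0.3964), (0.4, 0.9611, 0.1933)],
    )
    def test_known_lifetime_locations(self, params56, tau, expected_g, expected_s):
        g, s = pf.theoretical_phasor(tau, params56)
        assert g == pytest.approx(expected_g, abs=1e-4)
        assert s == pytest.approx(expected_s, abs=1e-4)

    @given(tau=st.floats(0.0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_single_exponentials_fall_on_universal_semicircle(self, tau):
        params = make_params(56)
        g, s = pf.theoretical_phasor(tau, params)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)
        assert s >= 0.0

    def test_long_lifetime_limit_approaches_origin(self, params56):
        g, s = pf.theoretical_phasor(1e9, params56)
        assert abs(g) < 1e-12 and abs(s) < 1e-6

    def test_negative_lifetime_rejected(self, params56):
        with pytest.raises(ValueError):
            pf.theoretical_phasor(-1.0, params56)


class TestCalibration:
    def test_delta_reference_gives_identity_transform(self, params56):
        calib = pf.compute_calibration(delta_stack(), 0.0, params56)
        assert calib.phase_offset_rad == 0.0
        assert calib.modulation_factor == 1.0

    def test_noiseless_fluorescein_reference_offsets(self, params56):
        """Discrete-binning residual of a 4.04 ns standard at 56 bins,
        frozen from the geometric-series oracle."""
        ref = pf.make_reference_stack(4.04, params56)
        calib = pf.compute_calibration(ref, 4.04, params56)
        assert calib.phase_offset_rad == pytest.approx(-0.0555832, abs=1e-6)
        assert calib.modulation_factor == pytest.approx(0.9994756, abs=1e-6)

    def test_distorted_reference_composes_with_instrument_terms(self, params56):
        """A reference with programmed instrument distortion yields the
        undistorted calibration plus the phase term and divided by the
        modulation gain."""
        clean = pf.compute_calibration(
            pf.make_reference_stack(4.04, params56), 4.04, params56
        )
        distorted = pf.compute_calibration(
            pf.make_reference_stack(
                4.04, params56, instrument_phase_rad=0.3,
                instrument_modulation=0.9,
            ),
            4.04, params56,
        )
        assert distorted.phase_offset_rad == pytest.approx(
            clean.phase_offset_rad + 0.3, abs=1e-9
        )
        assert distorted.modulation_factor == pytest.approx(
            clean.modulation_factor / 0.9, abs=1e-9
        )

    def test_threshold_excludes_dim_reference_pixels(self, params56):
        counts = np.zeros((2, 1, 56))
        counts[0, 0, 0] = 1000.0  # bright delta pixel
        counts[1, 0, :] = 1.0  # dim uniform pixel
        stack = pf.FlimStack(counts=counts)
        calib = pf.compute_calibration(stack, 0.0, params56, threshold=500.0)
        assert calib.phase_offset_rad == 0.0
        assert calib.modulation_factor == 1.0

    def test_no_pixels_above_threshold_rejected(self, params56):
        with pytest.raises(ValueError, match="threshold"):
            pf.compute_calibration(delta_stack(photons=10.0), 0.0, params56,
                                   threshold=100.0)

    def test_self_calibration_reproduces_theoretical_reference(self, params56):
        """Applying the calibration to the reference's own field maps its
        aggregate phasor onto the theoretical phasor of the reference."""
        ref = pf.make_reference_stack(4.04, params56)
        calib = pf.compute_calibration(ref, 4.04, params56)
        field = pf.apply_calibration(pf.phasor_transform(ref, params56), calib)
        g_t, s_t = pf.theoretical_phasor(4.04, params56)
        assert field.g[0, 0] == pytest.approx(g_t, abs=1e-12)
        assert field.s[0, 0] == pytest.approx(s_t, abs=1e-12)

    def test_identity_transform_leaves_field_unchanged(self, params56):
        field = pf.phasor_transform(delta_stack(), params56)
        calibrated = pf.apply_calibration(
            field, pf.CalibrationTransform.identity(harmonic=1)
        )
        np.testing.assert_array_equal(calibrated.g, field.g)
        np.testing.assert_array_equal(calibrated.s, field.s)
        np.testing.assert_array_equal(calibrated.intensity, field.intensity)
        assert calibrated.calibrated

    def test_double_calibration_rejected(self, params56):
        field = pf.phasor_transform(delta_stack(), params56)
        calib = pf.CalibrationTransform.identity(harmonic=1)
        with pytest.raises(ValueError, match="already calibrated"):
            pf.apply_calibration(pf.apply_calibration(field, calib), calib)

    def test_harmonic_mismatch_rejected(self, params56):
        field = pf.phasor_transform(delta_stack(), params56)
        calib = pf.CalibrationTransform.identity(harmonic=2)
        with pytest.raises(ValueError, match="harmonic"):
            pf.apply_calibration(field, calib)

    def test_cross_lifetime_calibration_near_theory(self, params56):
        """A 2 ns stack calibrated with a 4.04 ns reference lands within
        discretization error of the theoretical 2 ns phasor."""
        calib = pf.compute_calibration(
            pf.make_reference_stack(4.04, params56), 4.04, params56
        )
        stack = pf.simulate_stack(
            pf.GroundTruth(components=((2.0, 1.0),), poisson_noise=False),
            (2, 2), params56,
        )
        field = pf.apply_calibration(pf.phasor_transform(stack, params56), calib)
        g_t, s_t = pf.theoretical_phasor(2.0, params56)
        assert abs(field.g[0, 0] - g_t) < 1e-2
        assert abs(field.s[0, 0] - s_t) < 1e-2


class TestLifetimeMaps:
    def _field_at(self, g, s, params, intensity=1.0):
        return pf.PhasorField(
            g=np.array([[float(g)]]), s=np.array([[float(s)]]),
            intensity=np.array([[intensity]]), params=params, calibrated=True,
        )

    def test_semicircle_pixel_has_equal_phase_and_modulation_lifetimes(
        self, params56
    ):
        g, s = pf.theoretical_phasor(4.04, params56)
        maps = pf.lifetime_maps(self._field_at(g, s, params56))
        assert maps.taup_ns[0, 0] == pytest.approx(4.04, abs=1e-9)
        assert maps.taum_ns[0, 0] == pytest.approx(4.04, abs=1e-9)

    def test_interior_point_lifetimes(self, params56):
        maps = pf.lifetime_maps(self._field_at(0.5, 0.5, params56))
        assert maps.taup_ns[0, 0] == pytest.approx(1.9894, abs=1e-4)
        assert maps.taum_ns[0, 0] == pytest.approx(1.9894, abs=1e-4)

    def test_overmodulated_pixel_policy(self, params56):
        maps = pf.lifetime_maps(self._field_at(1.1, 0.0, params56))
        assert maps.taup_ns[0, 0] == 0.0
        assert np.isnan(maps.taum_ns[0, 0])

    def test_negative_phase_gives_undefined_phase_lifetime(self, params56):
        maps = pf.lifetime_maps(self._field_at(0.5, -0.1, params56))
        assert np.isnan(maps.taup_ns[0, 0])

    def test_zero_modulation_gives_undefined_lifetimes(self, params56):
        maps = pf.lifetime_maps(self._field_at(0.0, 0.0, params56))
        assert np.isnan(maps.taup_ns[0, 0]) and np.isnan(maps.taum_ns[0, 0])

    def test_uncalibrated_field_rejected(self, params56):
        field = pf.phasor_transform(delta_stack(), params56)
        with pytest.raises(ValueError, match="calibrated"):
            pf.lifetime_maps(field)
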