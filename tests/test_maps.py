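import numpy as np
import pytest

from helpers import exact_vfa_invert
from mpmkit.core_io import AcquisitionMetadata
from mpmkit.maps import (
    CalibrationError,
    DegenerateProtocolError,
    SpoilingCoefficients,
    apply_spoiling_correction,
    b1_correct_mt,
    calibrate_pd,
    compute_amplitude,
    compute_mt_sat,
    compute_r1,
)
from mpmkit.phantom import ernst_signal, mt_flash_signal

META_PD = AcquisitionMetadata("PDw", 6.0, 25.0, (2.3,))
META_T1 = AcquisitionMetadata("T1w", 21.0, 25.0, (2.3,))
META_MT = AcquisitionMetadata("MTw", 6.0, 25.0, (2.3,), mt_pulse=True)


def _intercepts(a=1000.0, r1=1.0, ft=1.0):
    s_pd = ernst_signal(a, r1, ft * META_PD.flip_angle_rad, 25.0)
    s_t1 = ernst_signal(a, r1, ft * META_T1.flip_angle_rad, 25.0)
    return np.full((2, 2, 2), s_pd), np.full((2, 2, 2), s_t1)


class TestR1AndAmplitude:
    def test_rational_approximation_error_is_small_and_quantified(self):
        # exact Ernst forward signals: the rational inversion lands within
        # 1.5% of truth while the exact closed-form inversion is exact
        s_pd, s_t1 = _intercepts(a=1000.0, r1=1.0)
        r1, v = compute_r1(s_pd, s_t1, META_PD, META_T1)
        a, va = compute_amplitude(s_pd, s_t1, META_PD, META_T1)
        assert v.all() and va.all()
        assert r1[0, 0, 0] == pytest.approx(0.99, abs=0.005)  # ~1% low
        assert abs(r1[0, 0, 0] - 1.0) < 0.015
        assert abs(a[0, 0, 0] - 1000.0) / 1000.0 < 0.015
        a_ex, r1_ex = exact_vfa_invert(
            s_pd, s_t1, META_PD.flip_angle_rad, META_T1.flip_angle_rad, 25.0
        )
        np.testing.assert_allclose(r1_ex, 1.0, rtol=1e-9)
        np.testing.assert_allclose(a_ex, 1000.0, rtol=1e-9)

    def test_unit_transmit_field_argument_is_identity(self):
        s_pd, s_t1 = _intercepts()
        r1_none, _ = compute_r1(s_pd, s_t1, META_PD, META_T1, ft=None)
        r1_ones, _ = compute_r1(s_pd, s_t1, META_PD, META_T1, ft=np.ones((2, 2, 2)))
        np.testing.assert_array_equal(r1_none, r1_ones)

    def test_r1_symmetric_under_input_swap(self):
        s_pd, s_t1 = _intercepts(r1=0.8)
        r1_a, _ = compute_r1(s_pd, s_t1, META_PD, META_T1)
        r1_b, _ = compute_r1(s_t1, s_pd, META_T1, META_PD)
        np.testing.assert_allclose(r1_a, r1_b, rtol=1e-12)

    def test_amplitude_is_homogeneous_degree_one(self):
        s_pd, s_t1 = _intercepts()
        a1, _ = compute_amplitude(s_pd, s_t1, META_PD, META_T1)
        a2, _ = compute_amplitude(2 * s_pd, 2 * s_t1, META_PD, META_T1)
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-12)

    def test_identical_effective_angles_raise_degenerate_error(self):
        s_pd, s_t1 = _intercepts()
        meta_same = AcquisitionMetadata("T1w", 6.0, 25.0, (2.3,))
        with pytest.raises(DegenerateProtocolError):
            compute_r1(s_pd, s_t1, META_PD, meta_same)

    def test_nonpositive_denominator_is_masked(self):
        s_pd = np.full((1, 1, 1), 10.0)
        s_t1 = np.full((1, 1, 1), 1000.0)  # unphysical: T1w >> PDw signal
        r1, valid = compute_r1(s_pd, s_t1, META_PD, META_T1)
        assert not valid[0, 0, 0] and r1[0, 0, 0] == 0.0


class TestMtSaturation:
    def test_zero_saturation_recovered_exactly(self):
        a, r1 = 1000.0, 1.0
        s_mt = np.full((2, 2, 2), mt_flash_signal(a, r1, 0.0, META_MT.flip_angle_rad, 25.0))
        delta, v = compute_mt_sat(s_mt, np.full_like(s_mt, a), np.full_like(s_mt, r1), META_MT)
        assert v.all()
        np.testing.assert_allclose(delta, 0.0, atol=1e-9)

    @pytest.mark.parametrize("delta_true", [0.5, 2.0, 4.0])
    def test_forward_inverse_round_trip(self, delta_true):
        a, r1 = 1000.0, 1.0
        s_mt = np.full((2, 2, 2), mt_flash_signal(a, r1, delta_true, META_MT.flip_angle_rad, 25.0))
        delta, _ = compute_mt_sat(s_mt, np.full_like(s_mt, a), np.full_like(s_mt, r1), META_MT)
        np.testing.assert_allclose(delta, delta_true, rtol=1e-6)

    def test_nonpositive_signal_masked(self):
        s_mt = np.zeros((1, 1, 1))
        delta, v = compute_mt_sat(s_mt, np.ones_like(s_mt), np.ones_like(s_mt), META_MT)
        assert not v.any() and delta[0, 0, 0] == 0.0


class TestMtB1Correction:
    def test_unit_field_and_zero_constant_are_identities(self):
        delta = np.full((3, 3, 3), 2.0)
        out1, _ = b1_correct_mt(delta, np.ones_like(delta), c=0.4)
        out2, _ = b1_correct_mt(delta, np.linspace(0.8, 1.2, 27).reshape(3, 3, 3), c=0.0)
        np.testing.assert_allclose(out1, delta, rtol=1e-12)
        np.testing.assert_array_equal(out2, delta)

    def test_correction_reduces_transmit_induced_dispersion(self):
        # simulate the MT steady state over an fT grid, recompute delta with
        # the biased local angle, then correct: the corrected map's
        # coefficient of variation must shrink
        a, r1, delta_true = 1000.0, 1.0, 2.0
        ft = np.linspace(0.8, 1.2, 9).reshape(1, 1, 9)
        alpha = META_MT.flip_angle_rad * ft
        s_mt = mt_flash_signal(a, r1, delta_true, alpha, 25.0)
        # reconstruct assuming the *nominal* angle (fT unknown to the fitter)
        delta_app, _ = compute_mt_sat(s_mt, np.full_like(s_mt, a), np.full_like(s_mt, r1), META_MT)
        corrected, _ = b1_correct_mt(delta_app, ft, c=0.4)
        cv = lambda x: x.std() / x.mean()
        assert cv(corrected) < cv(delta_app)

    def test_unstable_denominator_masked(self):
        delta = np.ones((1, 1, 2))
        ft = np.array([[[1.0, 3.0]]])
        _, valid = b1_correct_mt(delta, ft, c=0.4)
        assert valid[0, 0, 0] and not valid[0, 0, 1]

    def test_invalid_constant_rejected(self):
        with pytest.raises(ValueError):
            b1_correct_mt(np.ones((1, 1, 1)), None, c=1.0)


class TestSpoilingCorrection:
    def test_absent_coefficients_is_identity(self):
        r1 = np.full((2, 2, 2), 1.1)
        out, valid = apply_spoiling_correction(r1, None, None)
        np.testing.assert_array_equal(out, r1)
        assert valid.all()

    def test_identity_coefficients_are_identity(self):
        r1 = np.full((2, 2, 2), 1.1)
        out, _ = apply_spoiling_correction(r1, np.ones_like(r1), SpoilingCoefficients())
        np.testing.assert_allclose(out, r1, rtol=1e-12)

    def test_linear_coefficients_identity_at_nominal_field(self):
        # Acoef(1) = 0, Bcoef(1) = 1 built from linear polynomials
        coeffs = SpoilingCoefficients(a_poly=(-50.0, 50.0), b_poly=(0.9, 0.1))
        r1 = np.full((2, 2, 2), 0.9)
        out, _ = apply_spoiling_correction(r1, np.ones_like(r1), coeffs)
        np.testing.assert_allclose(out, r1, rtol=1e-12)

    def test_nonpositive_corrected_t1_masked(self):
        coeffs = SpoilingCoefficients(a_poly=(-5000.0,), b_poly=(1.0,))
        r1 = np.full((1, 1, 1), 1.0)  # T1 = 1000 ms -> corrected -4000 ms
        out, valid = apply_spoiling_correction(r1, np.ones_like(r1), coeffs)
        assert not valid.any() and out[0, 0, 0] == 0.0


class TestPdCalibration:
    def test_mask_mean_hits_target_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(500, 1500, size=(6, 6, 6))
        mask = a > 800
        pd = calibrate_pd(a, mask, target_pu=100.0)
        assert pd[mask].mean() == pytest.approx(100.0, rel=1e-9)

    def test_scale_invariance_and_ratio_preservation(self):
        a = np.ones((4, 4, 4))
        a[:2] = 0.8
        mask = np.ones_like(a, dtype=bool)
        pd1 = calibrate_pd(a, mask, 100.0)
        pd2 = calibrate_pd(7.3 * a, mask, 100.0)
        np.testing.assert_allclose(pd1, pd2, rtol=1e-12)
        assert pd1[0, 0, 0] / pd1[3, 0, 0] == pytest.approx(0.8, rel=1e-12)

    def test_empty_mask_and_zero_mean_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_pd(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(CalibrationError):
            calibrate_pd(np.zeros((2, 2, 2)), np.ones((2, 2, 2), dtype=bool))
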