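"""Constitutive-model responses: frozen values, limits, and the GL oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gamma

from organrheo.models import (
    FKVParams,
    ParameterDomainError,
    SFKVParams,
    SLSParams,
    StrainHistory,
    fkv_complex_modulus,
    gl_stress_response,
    sfkv_complex_modulus,
    sfkv_relaxation_modulus,
    sls_complex_modulus,
)

FREQS = np.geomspace(0.05, 50, 10)


class TestSFKVModulus:
    @pytest.mark.parametrize(
        "k_kpa, alpha, f, expected_kpa",
        [
            (2.00, 0.13, 80.0, 3.46),   # published heart extrapolation
            (0.88, 0.12, 300.0, 1.71),  # published kidney extrapolation
        ],
    )
    def test_storage_matches_published_extrapolations(self, k_kpa, alpha, f, expected_kpa):
        mod = sfkv_complex_modulus(SFKVParams.from_kpa(k_kpa, alpha), f)
        assert mod.storage[0] / 1e3 == pytest.approx(expected_kpa, abs=0.005)

    def test_alpha_zero_degenerates_to_spring(self):
        mod = sfkv_complex_modulus(SFKVParams(k_alpha=750.0, alpha=0.0), FREQS)
        np.testing.assert_allclose(mod.storage, 750.0)
        np.testing.assert_allclose(mod.loss, 0.0, atol=1e-12)

    def test_loss_modulus_frozen_value(self):
        # K=0.88 kPa.s^a, a=0.12, eta=7.58 Pa.s at 1 Hz -> 0.17248 kPa
        mod = sfkv_complex_modulus(SFKVParams.from_kpa(0.88, 0.12, 7.58), 1.0)
        assert mod.loss[0] / 1e3 == pytest.approx(0.172476, rel=1e-4)

    def test_rad_convention_differs(self):
        p = SFKVParams.from_kpa(0.88, 0.12, 7.58)
        hz = sfkv_complex_modulus(p, 1.0, "hz").storage[0]
        rad = sfkv_complex_modulus(p, 1.0, "rad").storage[0]
        assert rad == pytest.approx(hz * (2 * np.pi) ** 0.12, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        k=st.floats(1e2, 1e4),
        alpha=st.floats(0.01, 1.0),
        eta=st.floats(0.0, 50.0),
    )
    def test_nonnegative_and_monotone_storage(self, k, alpha, eta):
        mod = sfkv_complex_modulus(SFKVParams(k, alpha, eta), FREQS)
        assert np.all(mod.storage >= 0) and np.all(mod.loss >= 0)
        assert np.all(np.diff(mod.storage) > 0)  # strictly increasing for alpha > 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(alpha=st.floats(0.01, 0.99), f1=st.floats(0.1, 100), f2=st.floats(0.1, 100))
    def test_power_law_scaling_of_storage(self, alpha, f1, f2):
        p = SFKVParams(880.0, alpha, eta=12.0)  # eta only enters the loss
        g1 = sfkv_complex_modulus(p, f1).storage[0]
        g2 = sfkv_complex_modulus(p, f2).storage[0]
        assert g1 / g2 == pytest.approx((f1 / f2) ** alpha, rel=1e-12)

    @pytest.mark.parametrize("bad", [dict(k_alpha=-1, alpha=0.1), dict(k_alpha=1, alpha=1.2),
                                     dict(k_alpha=1, alpha=0.1, eta=-1), dict(k_alpha=np.nan, alpha=0.1)])
    def test_parameter_domain_errors(self, bad):
        with pytest.raises(ParameterDomainError):
            SFKVParams(**bad)


class TestFKVModulus:
    def test_hand_evaluated_point(self):
        mod = fkv_complex_modulus(FKVParams(k_alpha=1.0, alpha=0.5, g=1.0), 1.0)
        assert mod.storage[0] == pytest.approx(1 + np.cos(np.pi / 4), rel=1e-12)
        assert mod.loss[0] == pytest.approx(np.sin(np.pi / 4), rel=1e-12)

    def test_alpha_one_is_kelvin_voigt(self):
        # springpot -> dashpot: storage = G, loss = K*f, at 10 frequencies
        mod = fkv_complex_modulus(FKVParams(k_alpha=3.0, alpha=1.0, g=0.0), FREQS)
        np.testing.assert_allclose(mod.storage, 0.0, atol=1e-12)
        np.testing.assert_allclose(mod.loss, 3.0 * FREQS, rtol=1e-12)

    def test_degenerate_spring(self):
        mod = fkv_complex_modulus(FKVParams(k_alpha=1e-12, alpha=0.5, g=5000.0), FREQS)
        np.testing.assert_allclose(mod.storage, 5000.0, rtol=1e-9)


def test_sfkv_alpha_zero_equals_kelvin_voigt_solid():
    # S-FKV with alpha=0: storage = K, loss = eta*f, at 10 frequencies
    mod = sfkv_complex_modulus(SFKVParams(k_alpha=900.0, alpha=0.0, eta=8.0), FREQS)
    np.testing.assert_allclose(mod.storage, 900.0, rtol=1e-12)
    np.testing.assert_allclose(mod.loss, 8.0 * FREQS, rtol=1e-12)


class TestSLSModulus:
    def test_pure_spring_when_series_arm_absent(self):
        mod = sls_complex_modulus(SLSParams(g1=1000.0, g2=0.0, eta=0.0), FREQS)
        np.testing.assert_allclose(mod.storage, 1000.0)
        np.testing.assert_allclose(mod.loss, 0.0)

    def test_high_frequency_limit(self):
        mod = sls_complex_modulus(SLSParams(g1=1000.0, g2=500.0, eta=100.0), 1e9)
        assert mod.storage[0] == pytest.approx(1500.0, rel=1e-6)

    def test_hand_evaluated_at_unit_f_tau(self):
        # g1=g2=1, f*tau=1 -> storage 1.5, loss 0.5
        mod = sls_complex_modulus(SLSParams(g1=1.0, g2=1.0, eta=1.0), 1.0)
        assert mod.storage[0] == pytest.approx(1.5, rel=1e-12)
        assert mod.loss[0] == pytest.approx(0.5, rel=1e-12)

    def test_undefined_relaxation_time_rejected(self):
        with pytest.raises(ParameterDomainError):
            SLSParams(g1=1.0, g2=0.0, eta=5.0)


class TestRelaxationModulus:
    def test_alpha_zero_is_constant(self):
        p = SFKVParams(880.0, 0.0)
        t = np.array([0.5, 1.0, 7.0])
        np.testing.assert_allclose(sfkv_relaxation_modulus(p, t), 880.0)

    def test_frozen_kidney_value_at_one_second(self):
        p = SFKVParams.from_kpa(0.88, 0.12)
        assert sfkv_relaxation_modulus(p, 1.0) == pytest.approx(880.0 / gamma(0.88), rel=1e-12)
        assert sfkv_relaxation_modulus(p, 1.0) / 1e3 == pytest.approx(0.81, abs=0.005)

    def test_power_law_decade_scaling(self):
        p = SFKVParams.from_kpa(2.00, 0.13)
        g1, g10 = sfkv_relaxation_modulus(p, np.array([1.0, 10.0]))
        assert g10 == pytest.approx(g1 / 10**0.13, rel=1e-12)

    def test_strictly_decreasing_for_fractional_order(self):
        t = np.linspace(0.2, 10, 50)
        g = sfkv_relaxation_modulus(SFKVParams(500.0, 0.3, 4.0), t)
        assert np.all(np.diff(g) < 0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            sfkv_relaxation_modulus(SFKVParams(500.0, 0.3), 0.0)


class TestGLOracle:
    """The Grünwald–Letnikov discretization against the closed forms."""

    def test_alpha_zero_reduces_to_spring_dashpot(self):
        t = np.linspace(0.0, 2.0, 21)
        eps = 0.001 * np.sin(t)
        hist = StrainHistory(times=t, strains=eps, strain_amplitude=0.001)
        p = SFKVParams(k_alpha=800.0, alpha=0.0, eta=10.0)
        out = gl_stress_response(p, hist, dt=0.1)
        eps_grid = np.interp(out.times, t, eps)
        rate = np.diff(np.concatenate(([0.0], eps_grid))) / 0.1
        np.testing.assert_allclose(out.stress, 800.0 * eps_grid + 10.0 * rate, rtol=1e-10)

    def test_alpha_one_ramp_gives_constant_stress(self):
        # springpot -> dashpot: a constant strain rate r yields stress K*r
        r = 0.002
        t = np.linspace(0.0, 5.0, 11)
        hist = StrainHistory(times=t, strains=r * t, strain_amplitude=r * 5)
        out = gl_stress_response(SFKVParams(k_alpha=700.0, alpha=1.0, eta=0.0), hist, dt=0.01)
        np.testing.assert_allclose(out.stress[1:], 700.0 * r, rtol=1e-9)

    def test_step_response_converges_to_relaxation_modulus(self, organ_profile):
        # oracle-vs-closed-form within 2% over t in [1, 10] s at dt = 1 ms
        p = organ_profile.params
        hist = StrainHistory.step(0.001, 10.0)
        out = gl_stress_response(p, hist, dt=0.001)
        sel = out.times >= 1.0
        numeric = out.stress[sel] / 0.001
        closed = sfkv_relaxation_modulus(p, out.times[sel])
        assert np.max(np.abs(numeric - closed) / closed) < 0.02

    def test_resolution_error_when_dt_too_coarse(self):
        hist = StrainHistory(times=np.arange(5.0), strains=np.ones(5) * 1e-3, strain_amplitude=1e-3)
        with pytest.raises(ValueError, match="spacing"):
            gl_stress_response(SFKVParams(500.0, 0.2), hist, dt=2.0)
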