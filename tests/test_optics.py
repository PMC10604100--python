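"""Unit tests for the ZMW optical calculus: cutoff theory, quantum yield,
lifetime, detection efficiency, detected signal and enhancement averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zmwell import (
    ALEXA488,
    DipoleEmissionProfile,
    ExcitationProfile,
    FluorophoreSpec,
    SignalModel,
    detected_signal,
    detection_efficiency,
    lifetime_from_rates,
    quantum_yield,
    relative_rates,
)
from zmwell.optics import (
    average_enhancement,
    cutoff_wavelength,
    evanescent_decay_length,
    signal_averaged_lifetime,
)


class TestCutoffTheory:
    @pytest.mark.parametrize(
        "d, expected", [(100.0, 170.0), (0.0, 0.0), (280.0, 476.0)]
    )
    def test_cutoff_is_1p7_d(self, d, expected):
        assert cutoff_wavelength(d) == pytest.approx(expected)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            cutoff_wavelength(-1.0)

    def test_decay_length_value(self):
        # d = 100 nm, 488 nm in water: first-order closed form
        assert evanescent_decay_length(100.0, 488.0, 1.33) == pytest.approx(
            15.2655, abs=0.001
        )

    def test_decay_length_diverges_at_cutoff(self):
        # lambda_m -> lambda_c from above: decay length grows without bound
        lam_m = 488.0 / 1.33
        d_at_cutoff = lam_m / 1.7
        assert evanescent_decay_length(d_at_cutoff * 0.9999, 488.0, 1.33) > 1e3

    def test_decay_length_increasing_in_diameter(self):
        ds = np.linspace(50.0, 200.0, 10)
        lams = [evanescent_decay_length(d, 488.0, 1.33) for d in ds]
        assert np.all(np.diff(lams) > 0)

    def test_propagating_regime_flagged(self):
        with pytest.raises(ValueError, match="propagating"):
            evanescent_decay_length(280.0, 488.0, 1.33)


def _emission(z, p_total, p_ff, p_down):
    z = np.asarray(z, float)
    mk = lambda v: np.full_like(z, v) if np.isscalar(v) else np.asarray(v, float)
    return DipoleEmissionProfile(
        z_nm=z, p_total=mk(p_total), p_ff=mk(p_ff), p_ff_down=mk(p_down)
    )


class TestRates:
    def test_free_space(self):
        gr, gl = relative_rates(_emission([0.0, 1.0], 1.0, 1.0, 0.5))
        assert np.allclose(gr, 1.0)
        assert np.allclose(gl, 0.0)

    def test_partial_absorption(self):
        # P_r = 2, P_ff = 1: half of the emitted power is absorbed, so the
        # escaping radiative rate is 1 and the loss rate is 1
        gr, gl = relative_rates(_emission([0.0], 2.0, 1.0, 1.0))
        assert gr[0] == pytest.approx(1.0)
        assert gl[0] == pytest.approx(1.0)

    def test_loss_nonnegative_and_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            _emission([0.0], 1.0, 2.0, 0.5)  # P_ff > P_r


class TestQuantumYield:
    def test_free_space_identity_alexa(self, alexa):
        assert quantum_yield(1.0, 0.0, alexa) == pytest.approx(0.8)

    def test_strong_quenching(self, alexa):
        assert quantum_yield(1.0, 1e9, alexa) < 1e-8

    def test_moderate_loss(self, alexa):
        # gr = 1, gloss = 3, Phi0 = 0.8: Phi = 1 / (1 + 3 + 0.25) = 1/4.25
        assert quantum_yield(1.0, 3.0, alexa) == pytest.approx(1.0 / 4.25)

    @given(phi0=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_free_space_identity_any_phi0(self, phi0):
        f = FluorophoreSpec("x", phi0, 3.0, 488.0, 525.0)
        assert quantum_yield(1.0, 0.0, f) == pytest.approx(phi0, rel=1e-12)

    @given(
        phi0=st.floats(0.05, 1.0),
        gr=st.floats(0.1, 10.0),
        gl=st.sampled_from([0.0, 0.5, 1.0, 5.0]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_loss(self, phi0, gr, gl):
        f = FluorophoreSpec("x", phi0, 3.0, 488.0, 525.0)
        assert quantum_yield(gr, gl, f) >= quantum_yield(gr, gl + 0.5, f)

    def test_invalid_rates_rejected(self, alexa):
        with pytest.raises(ValueError):
            quantum_yield(-0.1, 0.0, alexa)


class TestLifetime:
    def test_free_space_alexa(self, alexa):
        assert lifetime_from_rates(0.8, 1.0, alexa) == pytest.approx(4.0)

    def test_proportional_to_phi(self, alexa):
        t1 = lifetime_from_rates(0.8, 1.0, alexa)
        t2 = lifetime_from_rates(0.4, 1.0, alexa)
        assert t2 == pytest.approx(t1 / 2)

    def test_quenched_value(self, alexa):
        phi = quantum_yield(1.0, 3.0, alexa)
        assert lifetime_from_rates(phi, 1.0, alexa) == pytest.approx(
            phi * 4.0 / 0.8
        )

    def test_zero_rate_rejected(self, alexa):
        with pytest.raises(ValueError):
            lifetime_from_rates(0.5, 0.0, alexa)


class TestDetectionEfficiency:
    def test_half_space_free(self):
        assert detection_efficiency(0.5, 1.0) == pytest.approx(0.5)

    def test_opaque_reflector(self):
        assert detection_efficiency(1.0, 1.0) == pytest.approx(1.0)

    def test_monotone_in_leakage(self):
        downs = np.linspace(1.0, 0.5, 6)
        etas = detection_efficiency(downs, 1.0)
        assert np.all(np.diff(etas) < 0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            detection_efficiency(0.0, 0.0)


class TestDetectedSignal:
    def test_zero_factor(self):
        z = np.zeros(4)
        assert np.allclose(detected_signal(z, np.ones(4), np.ones(4)), 0.0)

    def test_free_space_reference(self, alexa):
        s = detected_signal([1.0], [0.5], [alexa.quantum_yield])
        assert s[0] == pytest.approx(0.5 * 0.8)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detected_signal(np.ones(3), np.ones(4), np.ones(4))


class TestAverages:
    def test_weighted_mean_of_constant(self):
        z = np.linspace(0, 10, 11)
        s = np.exp(-z)
        assert average_enhancement(np.full_like(z, 2.5), s, z) == pytest.approx(2.5)

    def test_two_point_enhancement(self):
        assert average_enhancement([1.0, 3.0], [1.0, 1.0], [0.0, 1.0]) == (
            pytest.approx(2.0)
        )

    def test_two_point_lifetime(self):
        assert signal_averaged_lifetime([2.0, 4.0], [1.0, 1.0], [0.0, 1.0]) == (
            pytest.approx(3.0)
        )

    def test_bounded_by_extremes(self, rng):
        z = np.linspace(0, 5, 40)
        tau = 1.0 + rng.random(40) * 4.0
        s = 0.1 + rng.random(40)
        m = signal_averaged_lifetime(tau, s, z)
        assert tau.min() <= m <= tau.max()

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            signal_averaged_lifetime([1.0, 2.0], [0.0, 0.0], [0.0, 1.0])


class TestSignalModel:
    def _free_space_model(self, alexa, h=100.0):
        z = np.linspace(-h, 200.0, 61)
        exc = ExcitationProfile(z_nm=z, intensity=np.ones_like(z))
        emi = _emission(z, 1.0, 1.0, 0.5)
        return SignalModel.from_profiles(exc, emi, alexa, overmill_depth_nm=h)

    def test_free_space_all_identities(self, alexa):
        m = self._free_space_model(alexa)
        assert np.allclose(m.phi, alexa.quantum_yield)
        assert np.allclose(m.tau_ns, alexa.lifetime_ns)
        assert np.allclose(m.eta, 0.5)
        assert np.allclose(m.zeta, 1.0)
        assert m.average_enhancement() == pytest.approx(1.0)
        assert m.signal_averaged_lifetime() == pytest.approx(4.0)

    def test_grid_mismatch_rejected(self, alexa):
        z = np.linspace(-100, 200, 31)
        exc = ExcitationProfile(z_nm=z, intensity=np.ones_like(z))
        emi = _emission(z[:-1], 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            SignalModel.from_profiles(exc, emi, alexa, 100.0)

    def test_rescaling_invariance(self, alexa):
        # scaling I_ex and the Eq.-6 reference together leaves zeta unchanged
        h = 100.0
        z = np.linspace(-h, 200.0, 61)
        emi = _emission(z, 1.0, 1.0, 0.5)
        m1 = SignalModel.from_profiles(
            ExcitationProfile(z_nm=z, intensity=np.ones_like(z)), emi, alexa, h
        )
        m2 = SignalModel.from_profiles(
            ExcitationProfile(z_nm=z, intensity=3.0 * np.ones_like(z)),
            emi,
            alexa,
            h,
            i_ex0=3.0,
        )
        assert np.allclose(m1.zeta, m2.zeta)


def test_profile_validation():
    with pytest.raises(ValueError):
        ExcitationProfile(z_nm=[0.0, 0.0], intensity=[1.0, 1.0])
    with pytest.raises(ValueError):
        ExcitationProfile(z_nm=[0.0, 1.0], intensity=[1.0, -1.0])
    with pytest.raises(ValueError):
        _emission([0.0], 1.0, 0.5, 0.8)  # down > ff
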