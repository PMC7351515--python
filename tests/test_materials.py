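"""Constitutive-law unit tests: frozen scalar oracles and shape properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myofem.materials import (
    AponeurosisParams,
    EcmParams,
    FiberParams,
    active_stress,
    aponeurosis_energy,
    aponeurosis_pk2,
    ecm_anisotropic_energy,
    ecm_anisotropic_stress,
    fiber_total_stress,
    titin_stress,
    volume_penalty_energy,
)

ECM = EcmParams()
UNCLAMPED = FiberParams(clamp_titin_nonnegative=False)


def E_with(**comps):
    E = np.zeros((3, 3))
    idx = {"e11": (0, 0), "e22": (1, 1), "e33": (2, 2),
           "e12": (0, 1), "e23": (1, 2), "e31": (2, 0)}
    for name, val in comps.items():
        i, j = idx[name]
        E[i, j] = E[j, i] = val
    return E


class TestEcm:
    def test_energy_at_rest_is_constant_offset(self):
        # six components each contribute k at zero strain
        assert ecm_anisotropic_energy(E_with(), ECM) == pytest.approx(0.30)

    def test_energy_fiber_stretch_scalar_oracle(self):
        # 5k + k*(exp(0.6) - 0.6), evaluated independently
        expected = 5 * 0.05 + 0.05 * (np.exp(0.6) - 0.6)
        assert ecm_anisotropic_energy(E_with(e22=0.1), ECM) == pytest.approx(
            expected, rel=1e-12
        )

    def test_stress_zero_at_rest(self):
        assert np.allclose(ecm_anisotropic_stress(E_with(), ECM), 0.0)

    def test_stress_fiber_component_scalar_oracle(self):
        S = ecm_anisotropic_stress(E_with(e22=0.1), ECM)
        assert S[1, 1] == pytest.approx(0.05 * 6 * (np.exp(0.6) - 1), rel=1e-12)

    def test_energy_finite_on_physical_range(self, rng):
        for _ in range(50):
            E = rng.uniform(-0.5, 0.5, size=(3, 3))
            E = 0.5 * (E + E.T)
            assert np.isfinite(ecm_anisotropic_energy(E, ECM))

    def test_stress_matches_energy_finite_difference(self, rng):
        """Every stress component is dW/de_ij on random strain states."""
        h = 1e-6
        idx = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0)]
        for _ in range(100):
            E = rng.uniform(-0.3, 0.3, size=(3, 3))
            E = 0.5 * (E + E.T)
            S = ecm_anisotropic_stress(E, ECM)
            for i, j in idx:
                Ep, Em = E.copy(), E.copy()
                Ep[i, j] = Ep[j, i] = E[i, j] + h
                Em[i, j] = Em[j, i] = E[i, j] - h
                fd = (
                    ecm_anisotropic_energy(Ep, ECM)
                    - ecm_anisotropic_energy(Em, ECM)
                ) / (2 * h)
                assert S[i, j] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_normal_stress_is_asymmetric_shear_is_odd(self):
        for eps in (0.05, 0.15, 0.3):
            s_plus = ecm_anisotropic_stress(E_with(e22=eps), ECM)[1, 1]
            s_minus = ecm_anisotropic_stress(E_with(e22=-eps), ECM)[1, 1]
            assert abs(s_plus) != pytest.approx(abs(s_minus), rel=1e-3)
            t_plus = ecm_anisotropic_stress(E_with(e12=eps), ECM)[0, 1]
            t_minus = ecm_anisotropic_stress(E_with(e12=-eps), ECM)[0, 1]
            assert t_minus == pytest.approx(-t_plus, rel=1e-12)


class TestVolumePenalty:
    def test_exact_incompressibility_gives_zero(self):
        w = volume_penalty_energy(np.ones(8), np.ones(8), ECM)
        assert np.allclose(w, 0.0)

    def test_single_perturbed_point_scalar_oracle(self):
        I3 = np.ones(8)
        I3[0] = 1.1
        w = volume_penalty_energy(I3, np.ones(8), ECM)
        # I3avg = 1.0125; 5*0.01 + 20*0.0125^2
        assert w[0] == pytest.approx(0.053125, rel=1e-12)
        assert w[1] == pytest.approx(20 * 0.0125**2, rel=1e-12)

    def test_uniform_deviation_combines_both_weights(self):
        c = 1.07
        w = volume_penalty_energy(np.full(8, c), np.ones(8), ECM)
        assert np.allclose(w, (ECM.Ss + ECM.Sf) * (c - 1) ** 2)

    def test_element_inversion_rejected(self):
        with pytest.raises(ValueError, match="inversion"):
            volume_penalty_energy([1.0, -0.1] + [1.0] * 6, np.ones(8), ECM)


class TestFiberStress:
    def test_active_peak_is_unity_at_optimum(self):
        assert active_stress(0.0, 1.0) == 1.0

    def test_passive_state_produces_no_active_stress(self):
        assert active_stress(0.37, 0.0) == 0.0
        assert active_stress(-0.2, 0.0) == 0.0

    def test_active_branches_scalar_oracle(self):
        assert active_stress(0.2, 1.0) == pytest.approx(np.exp(-6 * 0.04), rel=1e-12)
        assert active_stress(-0.2, 1.0) == pytest.approx(
            np.exp(30 * (-0.008)), rel=1e-12
        )

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-0.45, 0.6), st.floats(0.0, 1.0))
    def test_active_is_a_hill_peaking_at_zero_strain(self, eps, b3):
        val = float(active_stress(eps, b3))
        assert val <= b3 + 1e-15
        if abs(eps) > 1e-3 and b3 > 0:
            assert val < b3

    def test_titin_zero_for_shortening_parabola_for_lengthening(self):
        assert titin_stress(-0.1, UNCLAMPED) == 0.0
        assert titin_stress(1.0, UNCLAMPED) == pytest.approx(0.539, rel=1e-12)
        assert titin_stress(0.5, UNCLAMPED) == pytest.approx(0.138, rel=1e-12)

    def test_titin_clamp_removes_negative_offset(self):
        # the printed parabola is slightly negative just above zero strain
        assert titin_stress(0.0, UNCLAMPED) == pytest.approx(-0.002)
        assert titin_stress(0.0, FiberParams()) == 0.0
        assert titin_stress(0.1, FiberParams()) == pytest.approx(
            0.522 * 0.01 + 0.019 * 0.1 - 0.002
        )

    def test_total_stress_is_sum_of_active_and_titin(self):
        assert fiber_total_stress(0.0, 1.0, UNCLAMPED) == pytest.approx(0.998)
        assert fiber_total_stress(-0.2, 1.0, UNCLAMPED) == pytest.approx(
            np.exp(30 * (-0.008)), rel=1e-12
        )
        assert fiber_total_stress(0.3, 0.0, UNCLAMPED) == pytest.approx(
            0.522 * 0.09 + 0.019 * 0.3 - 0.002, rel=1e-12
        )

    def test_fully_passive_shortening_is_stress_free(self):
        assert fiber_total_stress(-0.25, 0.0) == 0.0


class TestAponeurosis:
    def test_reference_state_energy_and_stress_vanish(self):
        p = AponeurosisParams()
        assert aponeurosis_energy(np.eye(3), p) == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(aponeurosis_pk2(np.eye(3), p), 0.0, atol=1e-12)

    def test_isochoric_deformation_has_no_bulk_term(self):
        lam = 1.2
        F = np.diag([lam, 1 / lam, 1.0])
        soft = AponeurosisParams(poisson=0.0)
        stiff = AponeurosisParams(poisson=0.45)
        assert aponeurosis_energy(F, soft) == pytest.approx(
            aponeurosis_energy(F, stiff), rel=1e-12
        )

    def test_bulk_is_always_derived(self):
        p = AponeurosisParams(a10=2.0, a01=1.0, poisson=0.25)
        assert p.bulk == pytest.approx(2 * 3.0 / 0.5)

    def test_inverted_configuration_rejected(self):
        with pytest.raises(ValueError, match="Jacobian"):
            aponeurosis_energy(np.diag([1.0, -1.0, 1.0]), AponeurosisParams())

    def test_stiffness_ratio_to_passive_muscle_fiber_tangent(self):
        """Aponeurosis small-strain modulus >= 50x the passive muscle
        fiber-direction tangent k*a22^2 at zero strain."""
        p = AponeurosisParams()
        muscle_tangent = ECM.k * ECM.a22**2
        assert p.youngs_small_strain >= 50.0 * muscle_tangent
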