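"""Ogden stress evaluation, strain-energy consistency, validity screen and
biaxial fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortauq import (
    OgdenModel,
    OgdenParams,
    StressStrainCurve,
    fit_ogden,
    is_valid_material,
    ogden_stress,
    strain_energy,
    synth_biaxial_curves,
)

from conftest import random_valid_params


def _fd_stress_oracle(params, lam, protocol, h=1e-6):
    """Independent oracle: Cauchy stress from a central finite difference of
    the strain-energy density composed with the protocol kinematics.

    Equibiaxial (l, l, l^-2): sigma = (l/2) dW/dl; uniaxial (l, l^-1/2,
    l^-1/2): sigma = l dW/dl.
    """
    if protocol == "equibiaxial":
        def W(l):
            return strain_energy(params, l, l, l**-2)
        factor = lam / 2.0
    else:
        def W(l):
            return strain_energy(params, l, l**-0.5, l**-0.5)
        factor = lam
    return factor * (W(lam + h) - W(lam - h)) / (2 * h)


class TestOgdenStress:
    def test_zero_at_reference_state(self, nominal_params):
        for protocol in ("equibiaxial", "uniaxial"):
            assert ogden_stress(nominal_params, 1.0, protocol) == pytest.approx(0.0, abs=1e-14)

    def test_neo_hookean_reduction(self):
        # single term mu=1 MPa, alpha=2: sigma_eq(1.2) = 1.2^2 - 1.2^-4
        p = OgdenParams(1.0, 2.0, 0.0, 1.0)
        expected = 1.2**2 - 1.2**-4
        assert ogden_stress(p, 1.2, "equibiaxial") == pytest.approx(expected, rel=1e-12)
        expected_uni = 1.2**2 - 1.2**-1
        assert ogden_stress(p, 1.2, "uniaxial") == pytest.approx(expected_uni, rel=1e-12)

    @pytest.mark.parametrize("protocol", ["equibiaxial", "uniaxial"])
    def test_matches_strain_energy_derivative(self, nominal_params, protocol):
        # nominal parameters at a small stretch, plus 50 random valid sets
        # over a stretch grid: analytic stress equals the energy-derivative
        # oracle to 1e-6 relative.
        assert ogden_stress(nominal_params, 1.05, protocol) == pytest.approx(
            _fd_stress_oracle(nominal_params, 1.05, protocol), rel=1e-6
        )
        rng = np.random.default_rng(42)
        grid = np.linspace(1.01, 1.4, 7)
        for _ in range(50):
            p = random_valid_params(rng)
            for lam in grid:
                sig = ogden_stress(p, lam, protocol)
                assert sig == pytest.approx(
                    _fd_stress_oracle(p, lam, protocol), rel=1e-6, abs=1e-9
                )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mu1=st.floats(-10, 10),
        a1=st.floats(0.5, 30),
        mu2=st.floats(-10, 10),
        a2=st.floats(0.5, 30),
    )
    def test_reference_state_stress_free_property(self, mu1, a1, mu2, a2):
        p = OgdenParams(mu1, a1, mu2, a2)
        assert abs(ogden_stress(p, 1.0, "equibiaxial")) < 1e-12
        assert abs(ogden_stress(p, 1.0, "uniaxial")) < 1e-12

    def test_positive_initial_stiffness_when_ground_state_valid(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = random_valid_params(rng)
            h = 1e-7
            slope = (ogden_stress(p, 1 + h) - ogden_stress(p, 1.0)) / h
            assert slope > 0

    def test_domain_errors(self, nominal_params):
        with pytest.raises(ValueError):
            ogden_stress(nominal_params, -0.5)
        with pytest.raises(ValueError):
            OgdenParams(1.0, 0.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            OgdenParams(np.inf, 1.0, 1.0, 2.0)


class TestValidity:
    def test_nominal_parameter_set(self, nominal_params):
        # mu0 = 4.6 > 0 but mu2*alpha2 = -7.52 < 0
        assert nominal_params.mu0 == pytest.approx(4.6)
        assert is_valid_material(nominal_params, "ground_state").valid
        verdict = is_valid_material(nominal_params, "strict_hill")
        assert not verdict.valid
        assert "mu2*alpha2 > 0" in verdict.violated

    @pytest.mark.parametrize("mode", ["ground_state", "strict_hill"])
    def test_negative_ground_state_invalid(self, mode):
        verdict = is_valid_material(OgdenParams(-1.0, 2.0, -1.0, 2.0), mode)
        assert not verdict.valid
        assert "mu1 + mu2 > 0" in verdict.violated


class TestCurve:
    def test_invariants(self):
        with pytest.raises(ValueError):
            StressStrainCurve(np.array([1.0, 1.1]), np.array([0.0]))
        with pytest.raises(ValueError):
            StressStrainCurve(np.array([1.1, 1.0]), np.array([0.0, 0.1]))
        with pytest.raises(ValueError):
            StressStrainCurve(np.array([0.9, 1.1]), np.array([0.0, 0.1]))


class TestFitting:
    def test_noiseless_recovery_example(self):
        truth = OgdenParams(3.0, 8.0, -0.2, 15.0)
        c1, c2 = synth_biaxial_curves(truth, n_points=20, lam_max=1.3)
        res = fit_ogden([c1, c2], init=OgdenParams(3.3, 8.8, -0.22, 16.5))
        assert res.converged
        assert res.rmse < 1e-6
        for got, want in zip(res.params.as_array(), truth.as_array()):
            assert got == pytest.approx(want, rel=0.05)

    def test_noiseless_recovery_many_seeds(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            truth = random_valid_params(rng)
            c1, c2 = synth_biaxial_curves(truth, n_points=20, lam_max=1.3)
            init = OgdenParams(*(truth.as_array() * 1.1))
            res = fit_ogden([c1, c2], init=init, seed=1)
            assert res.rmse < 1e-6

    def test_nested_neo_hookean_fit(self):
        p = OgdenParams(1.0, 2.0, 0.0, 1.0)
        lam = np.linspace(1.0, 1.3, 15)
        curve = StressStrainCurve(lam, ogden_stress(p, lam, "equibiaxial"))
        res = fit_ogden(curve, init=OgdenParams(0.8, 2.5, -0.05, 4.0))
        assert np.allclose(res.predict(curve), curve.stresses, atol=1e-4)

    def test_rmse_recomputed_from_residuals(self):
        truth = OgdenParams(3.0, 8.0, -0.2, 15.0)
        c1, _ = synth_biaxial_curves(truth, noise_sd=0.01, seed=5)
        res = fit_ogden(c1, init=truth)
        assert res.rmse == pytest.approx(
            float(np.sqrt(np.mean(res.residuals**2))), rel=1e-12
        )

    def test_too_few_points(self):
        curve = StressStrainCurve(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="6 data points"):
            OgdenModel(curve)
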