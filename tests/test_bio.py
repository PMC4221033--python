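"""Unit and property tests of the NPZD closures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alborun import bio
from alborun.bio import BioParams, BioState


conc = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestLimitations:
    @pytest.mark.parametrize(
        "N, expected",
        [(0.0, 0.0), (0.5, 0.5), (1.5, 0.75)],
    )
    def test_nutrient_limitation_values(self, params, N, expected):
        assert bio.nutrient_limitation(N, params) == pytest.approx(expected, abs=1e-12)

    def test_nutrient_limitation_monotone_and_bounded(self, params):
        N = np.linspace(0, 100, 2001)
        f = bio.nutrient_limitation(N, params)
        assert np.all(np.diff(f) > 0)
        assert f[0] == 0.0 and np.all(f < 1.0)

    def test_light_limitation_values(self, params):
        assert bio.light_limitation(0.0, params) == 0.0
        # slope alpha_I at the origin
        eps = 1e-8
        assert bio.light_limitation(eps, params) / eps == pytest.approx(params.alpha_I, rel=1e-6)
        assert bio.light_limitation(40.0, params) == pytest.approx(1 - np.exp(-1.2), rel=1e-12)
        assert bio.light_limitation(1e9, params) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("func", [bio.nutrient_limitation, bio.light_limitation])
    def test_negative_input_rejected(self, params, func):
        with pytest.raises(ValueError):
            func(-0.1, params)


class TestLightProfile:
    def test_clear_water_closed_form(self, params):
        # uniform 10 m layers, no phytoplankton: I = I_s exp(-k_w z) at midpoints
        dz = np.full(30, 10.0)
        z_mid = np.cumsum(dz) - 5.0
        I = bio.light_profile(np.zeros(30), dz, params)
        assert np.allclose(I, 40.0 * np.exp(-0.05 * z_mid), rtol=1e-12)
        # at 20 m depth (midpoint of a single 40 m layer): k_w*z = 1 -> 40/e
        I40 = bio.light_profile(np.zeros(1), np.array([40.0]), params)
        assert I40[0] == pytest.approx(40.0 * np.exp(-1.0), rel=1e-12)

    def test_self_shading_attenuation_coefficient(self, params):
        # uniform P=1: effective extinction k_w + k_b = 0.09 m^-1
        dz = np.full(10, 5.0)
        I = bio.light_profile(np.ones(10), dz, params)
        ratio = I[1:] / I[:-1]
        assert np.allclose(ratio, np.exp(-0.09 * 5.0), rtol=1e-12)

    def test_strictly_decreasing_and_surface_value(self, params):
        rng = np.random.default_rng(7)
        P = rng.random((8, 4, 3))
        dz = np.linspace(5, 30, 8)
        I = bio.light_profile(P, dz, params)
        assert np.all(np.diff(I, axis=0) < 0)
        assert np.all(I <= params.I_s)

    def test_bad_thickness_rejected(self, params):
        with pytest.raises(ValueError):
            bio.light_profile(np.zeros(3), np.array([10.0, -1.0, 10.0]), params)


class TestGrazing:
    def test_no_food(self, params):
        assert bio.grazing(0.0, 0.0, 1.0, params) == (0.0, 0.0)

    def test_saturation_at_max_rate(self, params):
        G_P, G_D = bio.grazing(1e12, 0.0, 1.0, params)
        assert G_P == pytest.approx(0.5, rel=1e-9)
        assert G_D == 0.0

    def test_shared_saturation_arithmetic(self, params):
        G_P, G_D = bio.grazing(1.0, 0.5, 1.0, params)
        assert G_P == pytest.approx(0.5 * 1.0 / (0.5 + 1.0 + 0.25), rel=1e-12)
        assert G_D == pytest.approx(0.5 * 0.25 / (0.5 + 1.0 + 0.25), rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(P=conc, D=conc, Z=conc)
    def test_bounded_by_rZ_and_linear_in_Z(self, P, D, Z):
        params = BioParams()
        G_P, G_D = bio.grazing(P, D, Z, params)
        assert G_P >= 0 and G_D >= 0
        assert G_P + G_D <= params.r_Z * Z * (1 + 1e-12)
        G_P2, G_D2 = bio.grazing(P, D, 2 * Z, params)
        assert G_P2 == pytest.approx(2 * G_P, rel=1e-9, abs=1e-15)
        assert G_D2 == pytest.approx(2 * G_D, rel=1e-9, abs=1e-15)


class TestSinking:
    @pytest.mark.parametrize("D, expected", [(0.0, 0.0), (0.2, 4.0), (1e12, 8.0)])
    def test_values(self, params, D, expected):
        assert bio.sinking_velocity(D, params) == pytest.approx(expected, rel=1e-9)

    def test_monotone(self, params):
        D = np.linspace(0, 10, 500)
        w = bio.sinking_velocity(D, params)
        assert np.all(np.diff(w) > 0)
        assert np.all(w < params.w_Dmax)


class TestSourceTerms:
    def test_zero_state(self, params):
        t = bio.source_terms(BioState(0.0, 0.0, 0.0, 0.0), 40.0, params)
        assert (t.dN, t.dP, t.dZ, t.dD) == (0.0, 0.0, 0.0, 0.0)

    def test_pure_remineralization(self, params):
        t = bio.source_terms(BioState(0.0, 0.0, 0.0, 1.0), 40.0, params)
        assert t.dN == pytest.approx(0.25, rel=1e-12)
        assert t.dD == pytest.approx(-0.25, rel=1e-12)
        assert t.dP == 0.0 and t.dZ == 0.0

    def test_closure_with_unit_zooplankton(self, params):
        t = bio.source_terms(BioState(1.3, 0.7, 1.0, 0.2), 40.0, params)
        assert t.dN + t.dP + t.dZ + t.dD == pytest.approx(-0.05, rel=1e-10)

    def test_closure_identity_bulk_random_states(self, params):
        """Tendencies sum to -(1-beta)*m_Z*Z^2 over a large random sample."""
        rng = np.random.default_rng(42)
        n = 1_000_000
        s = BioState(*(rng.random(n) * 20 for _ in range(4)))
        I = rng.random(n) * 200
        t = bio.source_terms(s, I, params)
        total = t.dN + t.dP + t.dZ + t.dD
        expected = -(1 - params.beta) * params.m_Z * s.Z**2
        scale = np.maximum(np.abs(t.dN), 1.0)
        assert np.max(np.abs(total - expected) / scale) < 1e-12

    def test_injectable_closures(self, params):
        """Alternative light/grazing shapes propagate through source_terms."""
        flat_light = lambda I, p: np.ones_like(np.asarray(I, dtype=float))
        t = bio.source_terms(BioState(1e9, 1.0, 0.0, 0.0), 0.0, params, light_fn=flat_light)
        assert t.dP == pytest.approx(params.r_P * 1.0 - params.m_P, rel=1e-9)


class TestBioParams:
    def test_defaults_are_calibrated_winter_values(self):
        p = BioParams()
        assert (p.r_P, p.m_P, p.m_Z, p.mu_Z) == (1.3, 0.06, 0.10, 0.05)
        assert (p.gamma, p.beta, p.eps, p.K_N) == (0.7, 0.5, 0.25, 0.5)
        assert (p.alpha_I, p.k_w, p.k_b, p.I_s) == (0.03, 0.05, 0.04, 40.0)
        assert (p.r_Z, p.K_Z, p.a1, p.a2) == (0.5, 0.5, 1.0, 0.5)
        assert (p.S_D, p.w_Dmax) == (0.2, 8.0)

    @pytest.mark.parametrize("bad", [{"K_N": -0.5}, {"gamma": 1.5}, {"r_P": float("nan")}])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            BioParams(**bad)
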