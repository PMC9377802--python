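"""Flux conversion, diffusion, bath exchange, volume dynamics, reversals."""

import numpy as np
import pytest

from slenet import constants as cn
from slenet import geometry as gm
from slenet.ion_dynamics import (bath_flux, longitudinal_diffusion,
                                 membrane_flux, osmolarities,
                                 radial_diffusion, refresh_reversals,
                                 volume_step)

SOMA = gm.PY_SOMA_GEOM


class TestMembraneFlux:
    def test_zero_current_zero_flux(self):
        assert membrane_flux(0.0, SOMA.surface, 1, SOMA.v_in, SOMA.v_out) == (0.0, 0.0)

    def test_dimensional_analysis_oracle(self):
        """Independent SI-unit conversion of a 1e-4 mA/cm^2 outward K+
        current on the pyramidal-soma geometry."""
        current = 1e-4            # mA/cm^2
        amps = current * 1e-3 / 1e-4 * (SOMA.surface * 1e-12)   # A (SI)
        mol_per_s = amps / 96485.332
        molar_per_s = mol_per_s / (SOMA.v_out * 1e-15)          # mol/L/s
        expected_mm_per_ms = molar_per_s  # 1 M/s == 1 mM/ms
        _, j_out = membrane_flux(current, SOMA.surface, 1, SOMA.v_in, SOMA.v_out)
        assert j_out == pytest.approx(expected_mm_per_ms, rel=1e-9)

    def test_mass_balance_and_volume_scaling(self):
        j_in, j_out = membrane_flux(0.3, SOMA.surface, 2, SOMA.v_in, SOMA.v_out)
        assert j_in * SOMA.v_in + j_out * SOMA.v_out == pytest.approx(
            0.0, abs=1e-12 * abs(j_in * SOMA.v_in))
        _, j_half = membrane_flux(0.3, SOMA.surface, 2, SOMA.v_in, 2 * SOMA.v_out)
        assert j_half == pytest.approx(j_out / 2, rel=1e-12)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            membrane_flux(0.1, SOMA.surface, 0, SOMA.v_in, SOMA.v_out)


class TestLongitudinalDiffusion:
    def test_zero_gradient(self):
        assert longitudinal_diffusion(5.0, 5.0, 1.96, 37.0, 235.0,
                                      100.0, 200.0) == (0.0, 0.0)

    def test_two_box_analytic_relaxation(self):
        """An isolated two-compartment system relaxes exponentially to the
        volume-weighted mean with rate D*S/L*(1/Va + 1/Vb)."""
        d_coef, s, dist = 1.96, 37.0, 235.0
        va, vb = 3534.0, 16729.0
        ca, cb = 10.0, 2.0
        dt = 0.5
        rate = d_coef * s / dist * (1 / va + 1 / vb)
        mean = (ca * va + cb * vb) / (va + vb)
        steps = 2000
        x, y = ca, cb
        for _ in range(steps):
            ja, jb = longitudinal_diffusion(x, y, d_coef, s, dist, va, vb)
            x, y = x + ja * dt, y + jb * dt
        expected = mean + (ca - mean) * np.exp(-rate * steps * dt)
        assert x == pytest.approx(expected, rel=1e-3)
        # total mass exactly conserved by the pair
        assert x * va + y * vb == pytest.approx(ca * va + cb * vb, rel=1e-12)

    def test_flux_follows_gradient(self):
        ja, jb = longitudinal_diffusion(1.0, 5.0, 2.0, 30.0, 100.0, 50.0, 50.0)
        assert ja > 0 > jb


class TestRadialDiffusion:
    def test_uniform_field_and_ring_conservation(self):
        conc = np.array([4.0, 4.0, 4.0])
        vols = np.array([100.0, 150.0, 80.0])
        pairs = [(0, 1), (1, 2), (2, 0)]
        s = np.array([10.0, 10.0, 10.0])
        dr = np.array([40.0, 40.0, 40.0])
        assert np.all(radial_diffusion(conc, vols, pairs, s, dr, 1.96) == 0.0)
        conc = np.array([8.0, 3.0, 5.0])
        out = radial_diffusion(conc, vols, pairs, s, dr, 1.96)
        assert np.dot(out, vols) == pytest.approx(0.0, abs=1e-12)

    def test_two_shell_hand_value(self):
        contact = 0.16 * SOMA.shell_surface
        out = radial_diffusion(np.array([9.0, 3.5]),
                               np.array([SOMA.v_out, SOMA.v_out]),
                               [(0, 1)], np.array([contact]),
                               np.array([40.0]), 1.96)
        expected = 1.96 * (3.5 - 9.0) * contact / (40.0 * SOMA.v_out)
        assert out[0] == pytest.approx(expected, rel=1e-12)
        assert out[1] == -out[0]


class TestBathFlux:
    def test_equilibrium_and_sign(self):
        assert bath_flux(3.5, 3.5, 1.96, SOMA.shell_surface, 4.0, SOMA.v_out) == 0.0
        assert bath_flux(9.0, 3.5, 1.96, SOMA.shell_surface, 4.0, SOMA.v_out) < 0
        assert bath_flux(2.0, 3.5, 1.96, SOMA.shell_surface, 4.0, SOMA.v_out) > 0

    def test_single_exponential_relaxation(self):
        rate = 1.96 * SOMA.shell_surface / (cn.BATH_SCALE * 4.0 * SOMA.v_out)
        x, dt = 9.0, 1.0
        for _ in range(1000):
            x += bath_flux(x, 3.5, 1.96, SOMA.shell_surface, 4.0, SOMA.v_out) * dt
        expected = 3.5 + (9.0 - 3.5) * np.exp(-rate * 1000 * dt)
        assert x == pytest.approx(expected, rel=1e-3)


class TestVolumeStep:
    def test_osmotic_equilibrium_is_stationary(self):
        ci = cn.C_IN_REST.copy()
        co = cn.C_OUT_REST.copy()
        ci2, co2, vi, vo = volume_step(ci, co, 100.0, 15.0, 0.05)
        # the printed composition balances to within the free-calcium term
        assert vi == pytest.approx(100.0, abs=5e-8)
        assert vo == pytest.approx(15.0, abs=5e-8)
        assert np.allclose(ci2, ci, rtol=1e-9)
        assert np.allclose(co2, co, rtol=1e-9)

    def test_pure_volume_step_conserves_mass_exactly(self):
        ci = cn.C_IN_REST * 1.1     # hypertonic interior
        co = cn.C_OUT_REST.copy()
        vi0, vo0 = 100.0, 15.0
        ci2, co2, vi, vo = volume_step(ci, co, vi0, vo0, 0.05)
        assert vi > vi0 and vo < vo0            # interior swells
        assert vi + vo == pytest.approx(vi0 + vo0, rel=1e-15)
        assert np.allclose(ci2 * vi, ci * vi0, rtol=1e-12)
        assert np.allclose(co2 * vo, co * vo0, rtol=1e-12)
        assert np.all(ci2 < ci)                 # dilution

    def test_floor_stops_shrinkage(self):
        ci = cn.C_IN_REST * 2.0
        co = cn.C_OUT_REST.copy()
        vi0 = 100.0
        vo0 = cn.ECS_FRACTION_MIN * vi0 * 1.0001
        _, _, vi, vo = volume_step(ci, co, vi0, vo0, 10.0)
        assert vi == vi0 and vo == vo0

    def test_rest_osmolarities_balance(self):
        pi_i, pi_o = osmolarities(cn.C_IN_REST, cn.C_OUT_REST)
        # balanced up to the 5e-5 mM free-calcium contribution
        assert pi_i == pytest.approx(pi_o, abs=1e-4)
        assert pi_i == pytest.approx(305.5, abs=0.01)


class TestReversals:
    def test_six_printed_values(self):
        rev = refresh_reversals()
        printed = {"Na": 69.4, "K": -84.5, "Cl": -81.8, "Ca": 139.3,
                   "HCO3": -13.4, "GABAa": -69.5}
        for ion, value in printed.items():
            assert rev[ion] == pytest.approx(value, abs=0.1), ion

    def test_ratio_invariance(self):
        rev = refresh_reversals()
        ci = {"Na": 20.0, "K": 174.0, "Cl": 12.0, "Ca": 1e-4, "HCO3": 30.0}
        co = {"Na": 280.0, "K": 7.0, "Cl": 270.0, "Ca": 4.0, "HCO3": 50.0}
        doubled = refresh_reversals(ci, co)
        for ion in ("Na", "K", "Cl", "Ca", "HCO3"):
            assert doubled[ion] == pytest.approx(rev[ion], abs=1e-9)

    def test_potassium_elevation_closed_form(self):
        base = refresh_reversals()
        ci = {"Na": 10.0, "K": 87.0, "Cl": 6.0, "Ca": 5e-5, "HCO3": 15.0}
        co = {"Na": 140.0, "K": 10.0, "Cl": 135.0, "Ca": 2.0, "HCO3": 25.0}
        elevated = refresh_reversals(ci, co)
        shift = cn.RTF * np.log(10.0 / 3.5)
        assert elevated["K"] - base["K"] == pytest.approx(shift, rel=1e-9)
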