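"""Membrane machinery: Nernst, pumps, cotransport, buffers, synapses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slenet import constants as cn
from slenet.biophysics import (ca_free_from_total, ca_total_from_free,
                               conductance_set, effective_conductances,
                               gaba_reversal, gabaa_currents, glia_flux,
                               glia_k2, kcc2_currents, membrane_currents,
                               nernst, pump_currents, pump_flux,
                               syn_conductance, SynapseSpec)
from slenet.gating import PY_SOMA, steady_gates
from slenet.ion_dynamics import refresh_reversals

finite_conc = st.floats(0.01, 500.0)


class TestNernst:
    def test_printed_sodium_and_potassium_reversals(self):
        assert nernst(140.0, 10.0, 1) == pytest.approx(69.4, abs=0.05)
        assert nernst(3.5, 87.0, 1) == pytest.approx(-84.5, abs=0.05)

    def test_identity_concentrations_give_zero(self):
        for x, z in [(3.5, 1), (10.0, 2), (87.0, -1)]:
            assert nernst(x, x, z) == 0.0

    @given(finite_conc, finite_conc)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_swap(self, a, b):
        assert nernst(a, b, 1) == pytest.approx(-nernst(b, a, 1), abs=1e-9)

    def test_nonpositive_concentration_raises(self):
        with pytest.raises(ValueError, match="concentration"):
            nernst(0.0, 10.0, 1)
        with pytest.raises(ValueError, match="concentration"):
            nernst(140.0, -1.0, 1)


class TestGabaReversal:
    def test_printed_value(self):
        rev = refresh_reversals()
        assert gaba_reversal(rev["Cl"], rev["HCO3"], 0.18) == pytest.approx(
            -69.5, abs=0.1)

    def test_degenerate_and_pure_chloride(self):
        assert gaba_reversal(-70.0, -70.0, 0.4) == -70.0
        assert gaba_reversal(-81.8, -13.4, 0.0) == -81.8

    @given(st.floats(-100, 0), st.floats(-100, 0), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_result_between_inputs(self, ecl, ehco3, p):
        e = gaba_reversal(ecl, ehco3, p)
        assert min(ecl, ehco3) - 1e-9 <= e <= max(ecl, ehco3) + 1e-9

    def test_permeability_out_of_range_raises(self):
        with pytest.raises(ValueError, match="P"):
            gaba_reversal(-80.0, -13.0, 1.2)


class TestPump:
    def test_half_saturation_algebra(self):
        assert pump_flux(cn.KM_NA, cn.KM_K, cn.KM_K, cn.KM_NA) == pytest.approx(
            1.0 / 32.0)

    def test_saturates_to_one(self):
        assert pump_flux(1e9, 1e9, cn.KM_K, cn.KM_NA) == pytest.approx(1.0, rel=1e-6)

    def test_rest_flux_value(self):
        # (1 + 2/3.5)^-2 (1 + 1)^-3
        assert pump_flux(10.0, 3.5, 2.0, 10.0) == pytest.approx(0.050620, rel=1e-4)

    @given(finite_conc, finite_conc, st.floats(1e-4, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_three_to_two_stoichiometry(self, na, k, imax):
        ina, ik = pump_currents(na, k, imax)
        assert ina + 1.5 * ik == pytest.approx(0.0, abs=1e-15)
        assert ina >= 0 >= ik

    def test_flux_monotone_in_both_arguments(self):
        grid = np.linspace(1.0, 100.0, 40)
        along_na = [pump_flux(x, 3.5, cn.KM_K, cn.KM_NA) for x in grid]
        along_k = [pump_flux(10.0, x, cn.KM_K, cn.KM_NA) for x in grid]
        assert np.all(np.diff(along_na) > 0)
        assert np.all(np.diff(along_k) > 0)


class TestKCC2:
    def test_zero_at_unit_ratio(self):
        ik, icl = kcc2_currents(10.0, 10.0, 5.0, 5.0)
        assert ik == 0.0 and icl == 0.0

    def test_rest_value(self):
        ik, icl = kcc2_currents(87.0, 3.5, 6.0, 135.0, 0.002)
        assert ik == pytest.approx(0.002 * math.log(522.0 / 472.5), rel=1e-12)
        assert ik == pytest.approx(1.99e-4, rel=0.01)

    @given(finite_conc, finite_conc, finite_conc, finite_conc)
    @settings(max_examples=50, deadline=None)
    def test_electroneutral_pairing_and_linearity(self, ki, ko, cli, clo):
        ik, icl = kcc2_currents(ki, ko, cli, clo, 0.002)
        assert ik + icl == 0.0
        ik2, _ = kcc2_currents(ki, ko, cli, clo, 0.004)
        assert ik2 == pytest.approx(2 * ik, rel=1e-12)


class TestGlia:
    def test_sigmoid_midpoint(self):
        assert glia_k2(16.0, cn.K1_GLIA) == pytest.approx(cn.K1_GLIA / 2)

    def test_empty_buffer_no_flux(self):
        j, db, dkb = glia_flux(3.5, 0.0, 0.0)
        assert j == db == dkb == 0.0

    def test_buffer_conservation_and_equilibrium_ratio(self):
        j, db, dkb = glia_flux(3.5, 1000.0, 100.0)
        assert db + dkb == 0.0
        ratio = glia_k2(3.5, cn.K1_GLIA) * 3.5 / cn.K1_GLIA
        assert ratio == pytest.approx(1.589e-4, rel=0.01)
        # at that ratio the flux vanishes
        b = cn.B_MAX / (1.0 + ratio)
        j_eq, _, _ = glia_flux(3.5, b, cn.B_MAX - b)
        assert j_eq == pytest.approx(0.0, abs=1e-12)


class TestCalciumBuffer:
    def test_zero_maps_to_zero(self):
        assert ca_total_from_free(0.0) == 0.0

    def test_printed_rest_total(self):
        assert ca_total_from_free(5e-5) == pytest.approx(9.75e-3, rel=0.01)

    def test_monotone_and_roundtrip(self):
        grid = np.linspace(0.0, 1.0, 201)
        tot = np.array([ca_total_from_free(x) for x in grid])
        assert np.all(np.diff(tot) > 0)
        back = np.array([ca_free_from_total(t) for t in tot])
        assert np.max(np.abs(back - grid)) < 1e-10

    def test_saturation_limit(self):
        big = 1e3
        assert ca_total_from_free(big) == pytest.approx(
            big + cn.CA_BUFFER_TOTAL, rel=1e-3)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            ca_total_from_free(-1e-6)


class TestSynapse:
    def test_peak_equals_weight_at_peak_time(self):
        spec = SynapseSpec(weight=0.0005, events=[0.0])
        tp = 3.0 * math.log(3.0)
        assert syn_conductance(spec, tp) == pytest.approx(0.0005, rel=1e-12)
        grid = np.linspace(0, 40, 4001)
        g = np.array([syn_conductance(spec, t) for t in grid])
        assert g.max() == pytest.approx(0.0005, rel=1e-6)

    def test_zero_before_event_and_superposition(self):
        spec = SynapseSpec(weight=1.0, events=[10.0])
        assert syn_conductance(spec, 5.0) == 0.0
        double = SynapseSpec(weight=1.0, events=[10.0, 10.0])
        assert syn_conductance(double, 14.0) == pytest.approx(
            2 * syn_conductance(spec, 14.0), rel=1e-12)

    def test_invalid_time_constants_raise(self):
        with pytest.raises(ValueError):
            SynapseSpec(weight=1.0, tau_rise=6.0, tau_decay=2.0)


class TestGabaaSplit:
    def test_split_identity(self):
        rev = refresh_reversals()
        for v in np.linspace(-90, 20, 23):
            icl, ihco3 = gabaa_currents(5e-4, v, rev["Cl"], rev["HCO3"])
            total = 5e-4 * (v - rev["GABAa"])
            assert icl + ihco3 == pytest.approx(total, rel=1e-12, abs=1e-15)

    def test_reversal_zero_and_pure_chloride(self):
        rev = refresh_reversals()
        icl, ihco3 = gabaa_currents(1e-3, rev["GABAa"], rev["Cl"], rev["HCO3"])
        assert icl + ihco3 == pytest.approx(0.0, abs=1e-12)
        icl, ihco3 = gabaa_currents(1e-3, -40.0, rev["Cl"], rev["HCO3"], p=0.0)
        assert ihco3 == 0.0


class TestMembraneCurrents:
    def test_chloride_leak_hand_value(self):
        rev = {"Na": 69.4, "K": -84.5, "Cl": -81.8, "Ca": 139.3}
        cur = membrane_currents(PY_SOMA, -61.0, steady_gates(PY_SOMA, -61.0), rev)
        assert cur["Cl_leak"] == pytest.approx(1e-5 * 20.8, rel=1e-10)

    def test_zero_conductance_zero_current(self):
        g = conductance_set(PY_SOMA, {"Na": 0.0, "KM": 0.0})
        rev = refresh_reversals()
        cur = membrane_currents(PY_SOMA, -20.0, steady_gates(PY_SOMA, -20.0),
                                rev, conds=g)
        assert cur["Na"] == 0.0 and cur["KM"] == 0.0

    def test_kc_calcium_saturation_clamps(self):
        gates = steady_gates(PY_SOMA, -30.0, 1.0)
        at_sat = effective_conductances(PY_SOMA, gates, 250.0)
        beyond = effective_conductances(PY_SOMA, gates, 400.0)
        assert at_sat["KC"] == pytest.approx(beyond["KC"], rel=1e-12)

    def test_unknown_conductance_rejected(self):
        with pytest.raises(KeyError):
            conductance_set(PY_SOMA, {"NotACurrent": 1.0})
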