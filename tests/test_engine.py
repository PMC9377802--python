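"""Integrator behaviour: determinism, conservation laws, rest stability."""

import numpy as np
import pytest

from slenet import constants as cn
from slenet.engine import integrate
from slenet.network import NCOMP, RunSpec


def total_moles(state):
    """Moles (conc x volume) of each dynamic ion over all compartments."""
    out = {}
    for sp, name in [(cn.NA, "Na"), (cn.K, "K"), (cn.CL, "Cl")]:
        out[name] = float(np.sum(state.ci[:, sp] * state.v_in
                                 + state.co[:, sp] * state.v_out))
    return out


class TestDeterminism:
    def test_identical_seed_bit_identical(self, model, settled):
        spec = RunSpec(duration=5e3, seed=7, ramp=True, ramp_onset=1e3)
        tr1, st1 = integrate(model, spec, state=settled)
        tr2, st2 = integrate(model, spec, state=settled)
        assert np.array_equal(tr1.v, tr2.v)
        assert np.array_equal(st1.ci, st2.ci)
        for c in range(NCOMP):
            assert np.array_equal(tr1.spike_times[c], tr2.spike_times[c])

    def test_different_seeds_differ(self, model, settled):
        tr1, _ = integrate(model, RunSpec(duration=5e3, seed=1), state=settled)
        tr2, _ = integrate(model, RunSpec(duration=5e3, seed=2), state=settled)
        assert not np.array_equal(tr1.v, tr2.v)


class TestConservation:
    def test_closed_system_conserves_ion_mass(self, model, settled):
        """With bath and glia disabled, total moles of Na/K/Cl stay constant
        during 10 s of stimulated activity."""
        spec = RunSpec(duration=10e3, seed=3, ramp=True, ramp_onset=1e3,
                       bath=False, glia=False)
        before = total_moles(settled)
        _, out = integrate(model, spec, state=settled)
        after = total_moles(out)
        for ion in before:
            assert after[ion] == pytest.approx(before[ion], rel=1e-6), ion

    def test_total_volume_conserved(self, model, settled):
        spec = RunSpec(duration=10e3, seed=3, ramp=True, ramp_onset=1e3)
        _, out = integrate(model, spec, state=settled)
        total0 = settled.v_in + settled.v_out
        total1 = out.v_in + out.v_out
        assert np.allclose(total1, total0, rtol=1e-12)

    def test_ecs_never_below_floor(self, reference_traces):
        vo = reference_traces.slow[:, :, 11]
        vi = reference_traces.slow[:, :, 10]
        assert np.all(vo >= cn.ECS_FRACTION_MIN * vi - 1e-9)

    def test_spiking_without_homeostasis_accumulates_monotonically(
            self, model, settled):
        """With pumps, KCC2, glia, bath and synapses off, sustained firing
        can only raise K+_o and Na+_i (no hidden sources)."""
        dc = np.zeros(NCOMP)
        dc[8] = 0.03
        spec = RunSpec(duration=3e3, poisson=False, synapses=False,
                       pump=False, kcc2=False, glia=False, bath=False,
                       extra_dc=dc, slow_stride=400)
        tr, _ = integrate(model, spec, state=settled)
        assert len(tr.spike_times[8]) > 100
        ko = tr.slow[:, 8, 6]
        nai = tr.slow[:, 8, 0]
        assert np.all(np.diff(ko) >= -1e-12)
        assert np.all(np.diff(nai) >= -1e-12)


class TestRestStability:
    def test_rest_holds_over_60s(self, rest_60s, settled):
        traces, end = rest_60s
        assert np.max(np.abs(traces.v - cn.V_REST)) < 0.5
        for sp in (cn.NA, cn.K, cn.CL):
            assert np.max(np.abs(end.ci[:, sp] / settled.ci[:, sp] - 1)) < 0.01
            assert np.max(np.abs(end.co[:, sp] / settled.co[:, sp] - 1)) < 0.01

    def test_frozen_ions_keep_reversals_constant(self, model, settled):
        spec = RunSpec(duration=5e3, poisson=False, ion_dynamics=False)
        tr, out = integrate(model, spec, state=settled)
        assert np.array_equal(out.ci, settled.ci)
        assert np.array_equal(out.co, settled.co)
        assert np.max(np.abs(tr.v - cn.V_REST)) < 0.5


class TestStimulation:
    def test_interneuron_fi_curve_monotone(self, model, settled):
        rates = []
        for amp in (0.02, 0.03, 0.04, 0.05):
            dc = np.zeros(NCOMP)
            dc[8] = amp
            spec = RunSpec(duration=2e3, poisson=False, synapses=False,
                           ion_dynamics=False, extra_dc=dc)
            tr, _ = integrate(model, spec, state=settled)
            rates.append(len(tr.spike_times[8]))
        assert rates == sorted(rates)
        assert rates[-1] > rates[0] > 0

    def test_clamped_potassium_step_drives_spiking(self, model, settled):
        """Somatic K+_o clamped at 12 mM (rest elsewhere) pushes the
        pyramidal cells out of rest within 5 s."""
        st = settled.copy()
        st.co[[0, 2, 4, 6], cn.K] = 12.0
        spec = RunSpec(duration=5e3, poisson=False, ion_dynamics=False)
        tr, _ = integrate(model, spec, state=st)
        assert len(tr.spikes([0, 2, 4, 6])) > 10

    def test_blowup_reports_time_and_state(self, model):
        """Clamping every pool at the unsettled printed composition leaves
        the strong calcium pump unbalanced; the integrator must fail loudly
        rather than return garbage."""
        spec = RunSpec(duration=2e3, poisson=False, ion_dynamics=False)
        with pytest.raises(RuntimeError, match="blew up at t"):
            integrate(model, spec, state=model.rest_state())


class TestAccuracy:
    def test_halving_dt_changes_subthreshold_vm_little(self, model, settled):
        dc = np.zeros(NCOMP)
        dc[1] = 2e-5  # subthreshold dendritic drive
        specs = [RunSpec(duration=3e3, dt=dtv, poisson=False, extra_dc=dc,
                         fast_stride=stride)
                 for dtv, stride in ((0.05, 20), (0.025, 40))]
        tr1, _ = integrate(model, specs[0], state=settled)
        tr2, _ = integrate(model, specs[1], state=settled)
        rms = np.sqrt(np.mean((tr1.v - tr2.v) ** 2))
        assert rms < 0.5
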