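"""Simulation protocols of the in-silico experiments.

Every protocol starts from a settled state: the calibrated network is run
input-free for a few seconds so that fast gates, the glial buffer and the
calcium subsystem reach their true stationary values (free calcium relaxes
from the nominal initial 5e-5 mM to the pump/I_CaL equilibrium within tens
of milliseconds; everything else stays at the printed composition).
"""

from __future__ import annotations

import numpy as np

from . import constants as cn
from .engine import TraceSet, integrate
from .network import (IN_INDEX, NCOMP, PY_DENDRITES, PY_SOMATA, SOMATA,
                      NetworkModel, NetworkState, RunSpec, Trajectory)

SETTLE_MS = 5e3


def settled_state(model: NetworkModel, duration: float = SETTLE_MS) -> NetworkState:
    """Input-free settling run from the printed composition; returns the state."""
    _, state = integrate(model, RunSpec(duration=duration, poisson=False))
    return state


def run_reference_sle(model: NetworkModel, seed: int = 1,
                      duration: float = 240e3,
                      state: NetworkState | None = None,
                      **kwargs) -> TraceSet:
    """The reference seizure-like event: Poisson background plus the
    0.35 nA -> 0 depolarising ramp injected into the interneuron at 60 s."""
    st = state if state is not None else settled_state(model)
    spec = RunSpec(duration=duration, seed=seed, ramp=True, **kwargs)
    traces, _ = integrate(model, spec, state=st)
    return traces


def run_noise_free_sle(model: NetworkModel, duration: float = 240e3,
                       state: NetworkState | None = None,
                       **kwargs) -> TraceSet:
    """Deterministic variant: background input replaced by the 1.85 pA
    dendritic DC; used for the IBI-scaling and excitability analyses."""
    st = state if state is not None else settled_state(model)
    spec = RunSpec(duration=duration, seed=None, poisson=False, ramp=True,
                   dc_comp=True, **kwargs)
    traces, _ = integrate(model, spec, state=st)
    return traces


def run_chloride_frozen_sle(model: NetworkModel, seed: int = 1,
                            duration: float = 240e3,
                            state: NetworkState | None = None) -> TraceSet:
    """Reference protocol with chloride accumulation removed: [Cl-] is
    clamped on both sides everywhere, so E_Cl and E_GABAa stay fixed while
    GABAa currents keep flowing."""
    st = state if state is not None else settled_state(model)
    spec = RunSpec(duration=duration, seed=seed, ramp=True,
                   clamps=[("in", cn.CL, None), ("out", cn.CL, None)])
    traces, _ = integrate(model, spec, state=st)
    return traces


# ---------------------------------------------------------------------------
# clamped-ion (fast-slow) protocols
# ---------------------------------------------------------------------------

def clamped_run_spec(duration: float, trajectories: list | None = None,
                     **kwargs) -> RunSpec:
    """RunSpec for the fast-slow analyses: Na+, K+, Cl- and A- are clamped
    on both sides, extracellular Ca2+ is clamped, intracellular free Ca2+
    stays dynamic (it is part of the fast burst machinery), and every
    homeostatic/transport pathway acting on clamped pools is disabled."""
    clamps = [(side, sp, None) for side in ("in", "out")
              for sp in (cn.NA, cn.K, cn.CL, cn.A)]
    clamps.append(("out", cn.CA, None))
    return RunSpec(duration=duration, seed=None, poisson=False,
                   clamps=clamps, trajectories=trajectories or [],
                   glia=False, bath=False, volume=False, rad_diffusion=False,
                   **kwargs)


def clamped_state(model: NetworkModel, base: NetworkState,
                  k_soma: float | None = None, k_dend: float | None = None,
                  cl_py: float | None = 7.0,
                  na_soma: float | None = None,
                  na_dend: float | None = None) -> NetworkState:
    """Settled state with the control concentrations imposed.

    ``k_soma``/``na_soma`` apply to every somatic shell/cell (PY and IN);
    ``cl_py`` to the pyramidal compartments only, as in the published
    protocol.
    """
    st = base.copy()
    if k_soma is not None:
        st.co[SOMATA, cn.K] = k_soma
    if k_dend is not None:
        st.co[PY_DENDRITES, cn.K] = k_dend
    if cl_py is not None:
        py = np.concatenate([PY_SOMATA, PY_DENDRITES])
        st.ci[py, cn.CL] = cl_py
    if na_soma is not None:
        st.ci[SOMATA, cn.NA] = na_soma
    if na_dend is not None:
        st.ci[PY_DENDRITES, cn.NA] = na_dend
    return st


#: default four-stage trajectories (s, mM) approximating the slow-variable
#: time courses of the reference event: (I) sharp somatic K+ rise,
#: (II) elevated somatic K+ with a slow dendritic K+ rise and Na+ loading,
#: (III) K+ decline at sustained high Na+ (termination), (IV) recovery.
FAST_SLOW_STAGES = {
    "k_soma": ([0, 10, 13, 45, 75, 90, 150], [3.5, 3.5, 9.5, 9.3, 5.0, 3.5, 3.5]),
    "k_dend": ([0, 13, 45, 75, 90, 150], [3.5, 3.5, 6.0, 4.0, 3.5, 3.5]),
    "na_soma": ([0, 25, 70, 110, 150], [10.0, 10.0, 16.0, 12.0, 10.5]),
    "na_dend": ([0, 25, 70, 110, 150], [10.0, 10.0, 12.5, 11.0, 10.2]),
}


def fast_slow_replay(model: NetworkModel, stages: dict | None = None,
                     duration: float = 150e3,
                     state: NetworkState | None = None) -> TraceSet:
    """Drive the clamped model along staged K+/Na+ trajectories."""
    stages = stages or FAST_SLOW_STAGES
    base = state if state is not None else settled_state(model)
    st = clamped_state(model, base, cl_py=7.0)
    trajs = []
    for key, comps, side, species in [
            ("k_soma", SOMATA, "out", cn.K),
            ("k_dend", PY_DENDRITES, "out", cn.K),
            ("na_soma", SOMATA, "in", cn.NA),
            ("na_dend", PY_DENDRITES, "in", cn.NA)]:
        t, v = stages[key]
        trajs.append(Trajectory(side, species, list(comps),
                                np.asarray(t, float) * 1e3, np.asarray(v, float)))
    spec = clamped_run_spec(duration, trajectories=trajs)
    traces, _ = integrate(model, spec, state=st)
    return traces


#: clamped-model operating point used for the linear-ramp experiments
RAMP_BASE = {"k_soma": 9.5, "k_dend": 6.0, "cl_py": 7.0,
             "na_soma": 10.0, "na_dend": 10.0}


def linear_ramp_run(model: NetworkModel, species: str,
                    duration: float = 260e3, ramp_start: float = 20e3,
                    ramp_end: float = 240e3,
                    state: NetworkState | None = None) -> TraceSet:
    """Bursting clamped model with exactly one species ramped linearly.

    ``species``: 'k_down' (somatic+dendritic K+ toward rest), 'na_up'
    (intracellular Na+ loading) or 'cl_down' (pyramidal Cl- unloading).
    """
    base = state if state is not None else settled_state(model)
    st = clamped_state(model, base, **RAMP_BASE)
    t = np.array([0.0, ramp_start, ramp_end])
    trajs = []
    if species == "k_down":
        trajs.append(Trajectory("out", cn.K, list(SOMATA), t,
                                np.array([9.5, 9.5, 3.5])))
        trajs.append(Trajectory("out", cn.K, list(PY_DENDRITES), t,
                                np.array([6.0, 6.0, 3.5])))
    elif species == "na_up":
        trajs.append(Trajectory("in", cn.NA, list(SOMATA), t,
                                np.array([10.0, 10.0, 22.0])))
        trajs.append(Trajectory("in", cn.NA, list(PY_DENDRITES), t,
                                np.array([10.0, 10.0, 22.0])))
    elif species == "cl_down":
        py = list(PY_SOMATA) + list(PY_DENDRITES)
        trajs.append(Trajectory("in", cn.CL, py, t,
                                np.array([7.0, 7.0, 1.0])))
    else:
        raise ValueError(f"unknown ramp species {species!r}")
    spec = clamped_run_spec(duration, trajectories=trajs)
    traces, _ = integrate(model, spec, state=st)
    return traces


# ---------------------------------------------------------------------------
# periodic-stimulation (postictal excitability) protocol
# ---------------------------------------------------------------------------

def calibrate_probe_weight(model: NetworkModel, state: NetworkState,
                           lo: float = 1e-5, hi: float = 0.02,
                           tol: float = 1e-5, margin: float = 1.05,
                           n_probes: int = 3) -> float:
    """Bisect the EPSC probe weight to just above spike threshold.

    Uses the interictal (noise-free, DC-compensated) model: a weight is
    suprathreshold when every delivered probe evokes a PY somatic spike
    within 50 ms.  Returns ``margin`` times the bisected threshold.
    """
    def responds(w):
        spec = RunSpec(duration=n_probes * 5e3 + 1e3, poisson=False, seed=None,
                       dc_comp=True, probe=True, probe_weight=w,
                       probe_start=1e3)
        tr, _ = integrate(model, spec, state=state)
        probe_times = 1e3 + 5e3 * np.arange(n_probes)
        sp = tr.spikes(PY_SOMATA)
        return all(np.any((sp >= pt) & (sp < pt + 50.0)) for pt in probe_times)

    if responds(lo):
        raise RuntimeError("probe bisection: lower bound already suprathreshold")
    if not responds(hi):
        raise RuntimeError("probe bisection: upper bound subthreshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if responds(mid):
            hi = mid
        else:
            lo = mid
    return hi * margin


def run_probe_protocol(model: NetworkModel, duration: float = 300e3,
                       probe_weight: float | None = None,
                       state: NetworkState | None = None) -> tuple[TraceSet, float]:
    """Noise-free SLE with the calibrated 5 s periodic somatic probe."""
    st = state if state is not None else settled_state(model)
    if probe_weight is None:
        probe_weight = calibrate_probe_weight(model, st)
    spec = RunSpec(duration=duration, seed=None, poisson=False, ramp=True,
                   dc_comp=True, probe=True, probe_weight=probe_weight,
                   probe_start=5e3)
    traces, _ = integrate(model, spec, state=st)
    return traces, probe_weight
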