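"""Assembly of the 4-pyramidal-cell + 1-interneuron network.

The network is a chain PY1-PY2-IN-PY3-PY4.  Each pyramidal cell has a
somatic and a dendritic compartment, the interneuron a soma only, giving
nine compartments.  Every compartment owns an interstitial shell; shells
exchange Na+ and K+ radially with their chain neighbours (somatic with
somatic, dendritic with dendritic) and all shells exchange Na+, K+ and Cl-
with a common bath.

Synaptic wiring (all-to-all, no autapses): every PY excites every other PY
(mid-dendrite, w_ee) and the IN (w_ei); the IN inhibits every PY
(mid-soma, w_ie) through a GABAa synapse carried by Cl- and HCO3-.
Each PY receives an independent 5 Hz Poisson excitatory background input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as cn
from . import geometry as gm
from .biophysics import CURRENTS, _ca_total
from .config import ModelConfig
from .gating import IN_SOMA, NGATES, PY_DEND, PY_SOMA, steady_gates

NCOMP = 9
#: compartment order: (soma, dend) x 4 pyramidal cells, then the interneuron
KIND = np.array([PY_SOMA, PY_DEND, PY_SOMA, PY_DEND,
                 PY_SOMA, PY_DEND, PY_SOMA, PY_DEND, IN_SOMA], dtype=np.int64)
CELL = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4], dtype=np.int64)
PARTNER = np.array([1, 0, 3, 2, 5, 4, 7, 6, -1], dtype=np.int64)
PY_SOMATA = np.array([0, 2, 4, 6], dtype=np.int64)
PY_DENDRITES = np.array([1, 3, 5, 7], dtype=np.int64)
IN_INDEX = 8
SOMATA = np.array([0, 2, 4, 6, 8], dtype=np.int64)

COMP_NAMES = ["py1_soma", "py1_dend", "py2_soma", "py2_dend",
              "py3_soma", "py3_dend", "py4_soma", "py4_dend", "in_soma"]


@dataclass
class NetworkState:
    """Full dynamical state of the nine-compartment network."""

    v: np.ndarray          # (9,) mV
    gates: np.ndarray      # (9, NGATES)
    ci: np.ndarray         # (9, 5) intracellular Na, K, Cl, Ca_total, A (mM)
    co: np.ndarray         # (9, 5) extracellular Na, K, Cl, Ca, A (mM)
    b_glia: np.ndarray     # (9,) free glial buffer (mM)
    v_in: np.ndarray       # (9,) um^3
    v_out: np.ndarray      # (9,) um^3
    syn: np.ndarray        # (4, 9) dual-exp states: exc a, exc b, inh a, inh b
    last_spike: np.ndarray  # (9,) ms

    def copy(self) -> "NetworkState":
        return NetworkState(*(a.copy() for a in (
            self.v, self.gates, self.ci, self.co, self.b_glia,
            self.v_in, self.v_out, self.syn, self.last_spike)))


class NetworkModel:
    """Parameter arrays of the wired network, ready for the integrator."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = (config or ModelConfig()).copy()
        cfg = self.config
        geoms = [gm.PY_SOMA_GEOM, gm.PY_DEND_GEOM] * 4 + [gm.IN_SOMA_GEOM]
        self.geom = geoms
        self.surface = np.array([g.surface for g in geoms])
        self.area_cm2 = self.surface * 1e-8
        self.v_in0 = np.array([g.v_in for g in geoms])
        self.v_out0 = np.array([g.v_out for g in geoms])
        self.bath_surface = np.array([g.shell_surface for g in geoms])
        bath_dr = (cfg.bath_distance_um if cfg.bath_distance_um is not None
                   else gm.BATH_DISTANCE)
        self.bath_dr = np.full(NCOMP, bath_dr)

        # conductance matrix (9 x 10) in CURRENTS order
        self.gcur = np.array([[cfg.conductances[KIND[c]][cur]
                               for cur in CURRENTS] for c in range(NCOMP)])
        self.imax_pump = np.array([cfg.imax_pump[KIND[c]] for c in range(NCOMP)])
        self.u_kcc2 = np.array([cfg.u_kcc2[KIND[c]] for c in range(NCOMP)])
        self.imax_capump = np.array([cfg.imax_capump[KIND[c]] for c in range(NCOMP)])

        # somato-dendritic coupling, as a current density on each side
        gc_total = (cfg.gc_total_us * 1e-6 if cfg.gc_total_us is not None
                    else gm.coupling_conductance())
        self.gc_total = gc_total
        self.gc_density = np.zeros(NCOMP)
        for c in range(NCOMP):
            if PARTNER[c] >= 0:
                self.gc_density[c] = gc_total / self.area_cm2[c]

        # longitudinal diffusion pairs (soma, dend) per PY cell
        self.long_pairs = np.array([[0, 1], [2, 3], [4, 5], [6, 7]], dtype=np.int64)
        # junction areas: the dendritic cross-section bounds the intracellular
        # path, the dendritic shell annulus the extracellular one
        self.long_s_in = np.full(4, gm.PY_DEND_GEOM.cross_section)
        self.long_s_out = np.full(4, gm.PY_DEND_GEOM.shell_cross_section)
        self.long_dist = np.full(4, gm.SOMA_DEND_DISTANCE)

        # radial diffusion between neighbouring shells along the chain
        soma_contact = gm.RADIAL_CONTACT_FRACTION * gm.PY_SOMA_GEOM.shell_surface
        dend_contact = gm.RADIAL_CONTACT_FRACTION * gm.PY_DEND_GEOM.shell_surface
        d = gm.RADIAL_SPACING
        self.rad_pairs = np.array(
            [[0, 2], [2, 8], [8, 4], [4, 6],      # somatic shells
             [1, 3], [3, 5], [5, 7]],             # dendritic shells
            dtype=np.int64)
        self.rad_contact = np.array([soma_contact] * 4 + [dend_contact] * 3)
        self.rad_dist = np.array([d, d, d, d, d, 2 * d, d])

        self.bath_conc = np.array([cfg.bath_na, cfg.bath_k, cfg.bath_cl])

        # synaptic event routing: weight added to the exc/inh channel of
        # column j when the soma in row i spikes
        self.w_exc = np.zeros((NCOMP, NCOMP))
        self.w_inh = np.zeros((NCOMP, NCOMP))
        for s in PY_SOMATA:
            for d_ in PY_DENDRITES:
                if CELL[s] != CELL[d_]:
                    self.w_exc[s, d_] = cfg.w_ee
            self.w_exc[s, IN_INDEX] = cfg.w_ei
        for d_ in PY_SOMATA:
            self.w_inh[IN_INDEX, d_] = cfg.w_ie

        self.syn_norm = cn.dualexp_norm(cfg.tau_rise, cfg.tau_decay)

        # LFP source layout: PY somata on a line 32 um apart, electrode in
        # the somatic layer midway between the two central somata (16 um
        # from each); the IN sits behind the line, 29 um from the electrode
        xs = np.array([0.0, 32.0, 64.0, 96.0])
        positions = np.zeros((NCOMP, 3))
        for k, s in enumerate(PY_SOMATA):
            positions[s] = (xs[k], 0.0, 0.0)
            positions[s + 1] = (xs[k], gm.PY_SOMA_GEOM.length / 2
                                + gm.PY_DEND_GEOM.length / 2, 0.0)
        positions[IN_INDEX] = (48.0, 0.0, 29.0)
        self.positions = positions
        self.electrode = np.array([48.0, 0.0, 0.0])
        self.lfp_source_weight = np.ones(NCOMP)
        self.lfp_source_weight[IN_INDEX] = cn.IN_LFP_WEIGHT

    # ------------------------------------------------------------------
    def rest_state(self) -> NetworkState:
        """State with every compartment at the printed resting composition.

        Voltages at -61 mV, gates at steady state, glial buffer at binding
        equilibrium, calcium stored as total (buffer-mapped) concentration.
        """
        from .biophysics import glia_k2

        cfg = self.config
        v = np.full(NCOMP, cn.V_REST)
        gates = np.vstack([steady_gates(KIND[c], cn.V_REST) for c in range(NCOMP)])
        ci = np.tile(cn.C_IN_REST, (NCOMP, 1))
        co = np.tile(cn.C_OUT_REST, (NCOMP, 1))
        ci[:, cn.CA] = _ca_total(cn.C_IN_REST[cn.CA], cfg.ca_buffer_total, cfg.ca_kd)
        k2 = glia_k2(cn.C_OUT_REST[cn.K], cfg.k1_glia)
        b0 = cfg.b_max / (1.0 + k2 * cn.C_OUT_REST[cn.K] / cfg.k1_glia)
        b_glia = np.full(NCOMP, b0)
        syn = np.zeros((4, NCOMP))
        last = np.full(NCOMP, -1e9)
        return NetworkState(v, gates, ci, co, b_glia,
                            self.v_in0.copy(), self.v_out0.copy(), syn, last)

    def calibrate(self) -> "NetworkModel":
        """Apply the closed-form rest-state calibration in place."""
        from .calibration import calibrate
        calibrate(self)
        return self


@dataclass
class RunSpec:
    """Everything that defines one simulation run besides the model."""

    duration: float                 # ms
    dt: float | None = None         # defaults to config dt
    seed: int | None = None         # Poisson stream seed; None disables noise
    poisson: bool = True
    ramp: bool = False              # IN depolarising ramp
    ramp_onset: float | None = None     # ms
    ramp_amp: float | None = None       # nA
    ramp_duration: float | None = None  # ms
    dc_comp: bool = False           # dendritic DC replacing Poisson drive
    probe: bool = False             # periodic somatic EPSC probe
    probe_weight: float = 0.0       # uS
    probe_start: float = 0.0        # ms
    probe_period: float | None = None   # ms
    synapses: bool = True           # recurrent synaptic routing
    pump: bool = True
    kcc2: bool = True
    glia: bool = True
    bath: bool = True
    volume: bool = True
    long_diffusion: bool = True
    rad_diffusion: bool = True
    gaba_cl_flux: bool = True       # GABAa Cl- contributes to concentrations
    ion_dynamics: bool = True       # False clamps every concentration
    clamps: list = field(default_factory=list)      # (side, species, comps|None)
    trajectories: list = field(default_factory=list)  # Trajectory objects
    extra_dc: np.ndarray | None = None  # per-compartment DC, mA/cm^2
    spike_threshold: float = -10.0  # mV, upward-crossing detector
    fast_stride: int = 20           # V/LFP sampling, steps (1 ms at dt=0.05)
    slow_stride: int = 200          # concentration sampling, steps


@dataclass
class Trajectory:
    """Externally imposed time course of one clamped concentration."""

    side: str                 # "in" or "out"
    species: int              # constants.NA .. constants.A
    comps: list               # compartment indices
    times: np.ndarray         # ms, increasing
    values: np.ndarray        # mM


def build_network(config: ModelConfig | None = None, calibrated: bool = True) -> NetworkModel:
    """Construct (and by default calibrate) the standard 5-cell network."""
    model = NetworkModel(config)
    if calibrated:
        model.calibrate()
    return model
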