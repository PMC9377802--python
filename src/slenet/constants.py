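"""Physical constants, unit conventions and the resting ionic composition.

Unit system used throughout the package (chosen to avoid silent unit bugs;
all conversion factors live here):

================  ==========
quantity          unit
================  ==========
voltage           mV
time              ms
concentration     mM
length            um
surface area      um^2
volume            um^3
current density   mA/cm^2
conductance       S/cm^2 (membrane), uS (synapses)
capacitance       uF/cm^2
diffusion coeff.  um^2/ms
================  ==========

With these units a membrane current density ``I`` (mA/cm^2) crossing a
surface ``S`` (um^2) into a volume ``V`` (um^3) changes the concentration at
a rate ``I*S*JFAC/(z*V)`` mM/ms, where ``JFAC = 1e4/F``.
"""

from __future__ import annotations

import numpy as np

#: Faraday constant, C/mol
FARADAY = 96485.332
#: Gas constant, J/(mol K)
GAS_CONSTANT = 8.314462618
#: Absolute temperature, K (273.16 + 32 degrees C)
TEMPERATURE = 273.16 + 32.0
#: RT/F in mV at TEMPERATURE
RTF = 1e3 * GAS_CONSTANT * TEMPERATURE / FARADAY
#: mA/cm^2 * um^2 / um^3 -> mM/ms  (divide by valence)
JFAC = 1e4 / FARADAY
#: mA/cm^2 / (uF/cm^2) -> mV/ms
VFAC = 1e3

#: Specific membrane capacitance, uF/cm^2
CM = 1.0
#: Specific axial resistance, Ohm*cm
RA = 100.0

# --- species bookkeeping ----------------------------------------------------
SPECIES = ("Na", "K", "Cl", "Ca", "A")
NA, K, CL, CA, A = range(5)
VALENCE = np.array([1.0, 1.0, -1.0, 2.0, -1.0])

#: Longitudinal/radial/bath diffusion coefficients, um^2/ms
DIFF_COEF = np.array([1.33, 1.96, 2.03, 0.6, 0.0])

# --- resting concentrations (mM) -------------------------------------------
#: intracellular: Na, K, Cl, Ca(free), A
C_IN_REST = np.array([10.0, 87.0, 6.0, 5e-5, 187.5])
#: extracellular: Na, K, Cl, Ca, A
C_OUT_REST = np.array([140.0, 3.5, 135.0, 2.0, 0.0])
#: bicarbonate is held fixed on both sides
HCO3_IN = 15.0
HCO3_OUT = 25.0
#: GABAa relative HCO3- permeability
P_HCO3 = 0.18

#: resting membrane potential, mV
V_REST = -61.0

# --- pump / cotransporter / glia / calcium handling -------------------------
KM_K = 2.0      # pump K+ half-saturation, mM
KM_NA = 10.0    # pump Na+ half-saturation, mM
U_KCC2 = 0.002  # cotransporter strength, mA/cm^2 (paper value; recomputed by calibration)

B_MAX = 1100.0  # glial buffer capacity, mM
K1_GLIA = 0.0008  # backward rate, 1/ms

CA_PUMP_IMAX = 2.55    # printed Ca-pump strength, mA/cm^2 (see calibration)
CA_PUMP_KM = 0.0069    # mM
CA_BUFFER_TOTAL = 1.562  # [B]_i at resting volume, mM
CA_KD = 0.008          # buffer dissociation constant, mM

# --- volume dynamics ---------------------------------------------------------
OSMO_TAU = 250.0       # ms
OSMO_C = 1.0           # um^3/mM
ECS_FRACTION_REST = 0.15  # V_o0 = 0.15 * V_i0
ECS_FRACTION_MIN = 0.04   # extracellular floor, fraction of cellular volume
BATH_SCALE = 4.4e4     # bath diffusion scaling constant s

# --- synapses ----------------------------------------------------------------
TAU_RISE = 2.0   # ms
TAU_DECAY = 6.0  # ms
E_EXC = 0.0      # AMPA reversal, mV
W_EE = 0.0002    # uS
W_EI = 0.0017    # uS
W_IE = 0.0005    # uS
W_INPUT = 0.0004  # uS
POISSON_RATE = 5.0e-3  # 1/ms (5 Hz)

# --- stimulation -------------------------------------------------------------
RAMP_AMP = 0.35e-6     # mA (0.35 nA) initial IN ramp amplitude
RAMP_DURATION = 40e3   # ms
RAMP_ONSET = 60e3      # ms
DC_COMP = 1.85e-9      # mA (1.85 pA) dendritic DC replacing Poisson drive

# --- LFP ---------------------------------------------------------------------
SIGMA_EXTRA = 0.3      # S/m
IN_LFP_WEIGHT = 0.2


def dualexp_norm(tau_rise: float = TAU_RISE, tau_decay: float = TAU_DECAY) -> float:
    """Normalisation factor making the dual-exponential peak equal the weight."""
    if tau_decay <= tau_rise:
        raise ValueError("tau_decay must exceed tau_rise")
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    return 1.0 / (np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise))
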