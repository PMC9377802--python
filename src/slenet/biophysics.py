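"""Membrane-localised machinery: currents, pumps, cotransport, buffers, synapses.

All current densities follow one sign convention: **positive = outward
cation flux** (equivalently, outward conventional current).  The membrane
potential equations subtract every current, so a positive current
hyperpolarises.  Densities are mA/cm^2, voltages mV, concentrations mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as cn
from . import gating
from .gating import (
    G_HNA,
    G_HNAP,
    G_MCAL,
    G_MKAHP,
    G_MKC,
    G_MKM,
    G_MNA,
    G_MNAP,
    G_NKDR,
    IN_SOMA,
    PY_DEND,
    PY_SOMA,
)

__all__ = [
    "nernst",
    "gaba_reversal",
    "pump_flux",
    "pump_currents",
    "kcc2_currents",
    "glia_k2",
    "glia_flux",
    "ca_pump_current",
    "ca_total_from_free",
    "ca_free_from_total",
    "syn_conductance",
    "gabaa_currents",
    "membrane_currents",
    "ConductanceSet",
    "PumpSpec",
    "KCC2Spec",
    "GliaBufferState",
    "CaHandling",
    "SynapseSpec",
]


# --------------------------------------------------------------------------
# reversal potentials
# --------------------------------------------------------------------------

@njit(cache=True)
def _nernst(c_out, c_in, z):
    return cn.RTF / z * math.log(c_out / c_in)


def nernst(c_out: float, c_in: float, valence: int, temperature: float = cn.TEMPERATURE) -> float:
    """Nernst reversal potential (mV) of an ion, ``(RT/zF) ln(out/in)``.

    Parameters are the extracellular and intracellular concentrations (mM),
    the ion valence and the absolute temperature (K).
    """
    if c_out <= 0 or c_in <= 0:
        raise ValueError(
            f"non-positive concentration in Nernst equation (out={c_out}, in={c_in})"
        )
    if valence == 0:
        raise ValueError("valence must be nonzero")
    rtf = 1e3 * cn.GAS_CONSTANT * temperature / cn.FARADAY
    return rtf / valence * math.log(c_out / c_in)


def gaba_reversal(e_cl: float, e_hco3: float, p: float = cn.P_HCO3) -> float:
    """GABAa reversal as the permeability-weighted mix of Cl- and HCO3-."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"HCO3 permeability P={p} outside [0, 1]")
    return (1.0 - p) * e_cl + p * e_hco3


# --------------------------------------------------------------------------
# transporters
# --------------------------------------------------------------------------

@njit(cache=True)
def pump_flux(na_in, k_out, km_k, km_na):
    """Saturating Na+/K+-pump activation, dimensionless in (0, 1)."""
    return (1.0 + km_k / k_out) ** -2 * (1.0 + km_na / na_in) ** -3


def pump_currents(na_in: float, k_out: float, imax: float,
                  km_k: float = cn.KM_K, km_na: float = cn.KM_NA) -> tuple[float, float]:
    """Na+ and K+ pump current densities (3 Na+ out : 2 K+ in).

    Returns ``(I_Na_pump, I_K_pump)``; the Na component is outward
    (positive), the K component inward, and their ratio is -3/2 always.
    """
    if na_in <= 0 or k_out <= 0:
        raise ValueError("pump concentrations must be positive")
    f = pump_flux(na_in, k_out, km_k, km_na)
    return 3.0 * imax * f, -2.0 * imax * f


@njit(cache=True)
def _kcc2_k_current(u, k_in, k_out, cl_in, cl_out):
    return u * math.log(k_in * cl_in / (k_out * cl_out))


def kcc2_currents(k_in: float, k_out: float, cl_in: float, cl_out: float,
                  u_kcc2: float = cn.U_KCC2) -> tuple[float, float]:
    """Electroneutral K-Cl cotransport: ``(I_K_KCC2, I_Cl_KCC2)``.

    ``I_K = U ln([K]i[Cl]i / [K]o[Cl]o)`` and ``I_Cl = -I_K`` exactly, so
    the transporter moves mass without net charge.
    """
    if min(k_in, k_out, cl_in, cl_out) <= 0:
        raise ValueError("KCC2 concentrations must be positive")
    ik = _kcc2_k_current(u_kcc2, k_in, k_out, cl_in, cl_out)
    return ik, -ik


@njit(cache=True)
def glia_k2(k_out, k1):
    """Forward binding rate of the glial K+ buffer, 1/ms."""
    return k1 / (1.0 + math.exp((k_out - 16.0) / -1.25))


def glia_flux(k_out: float, b_free: float, kb_bound: float,
              k1: float = cn.K1_GLIA) -> tuple[float, float, float]:
    """Glial potassium uptake: ``(J_glia, dB/dt, dKB/dt)`` in mM/ms.

    ``J_glia`` (the flux added to d[K+]o/dt) equals dB/dt; bound + free
    buffer is conserved exactly.
    """
    k2 = glia_k2(k_out, k1)
    dB = -k2 * k_out * b_free + k1 * kb_bound
    return dB, dB, -dB


@njit(cache=True)
def ca_pump_current(ca_free, imax, km):
    return imax / (1.0 + km / ca_free) if ca_free > 0.0 else 0.0


@njit(cache=True)
def _ca_total(ca, b_i, kd):
    return ca * (b_i + kd + ca) / (kd + ca)


@njit(cache=True)
def _ca_free(total, b_i, kd):
    # invert total = ca (B + Kd + ca)/(Kd + ca):  ca^2 + (B + Kd - tot) ca - Kd tot = 0
    p = b_i + kd - total
    return 0.5 * (-p + math.sqrt(p * p + 4.0 * kd * total))


def ca_total_from_free(ca_free: float, b_i: float = cn.CA_BUFFER_TOTAL,
                       kd: float = cn.CA_KD) -> float:
    """Total intracellular calcium given free calcium, under fast buffering."""
    if ca_free < 0:
        raise ValueError(f"free calcium must be non-negative, got {ca_free}")
    return _ca_total(ca_free, b_i, kd)


def ca_free_from_total(ca_total: float, b_i: float = cn.CA_BUFFER_TOTAL,
                       kd: float = cn.CA_KD) -> float:
    """Free intracellular calcium given total; exact inverse of the buffer map."""
    if ca_total < 0:
        raise ValueError(f"total calcium must be non-negative, got {ca_total}")
    return _ca_free(ca_total, b_i, kd)


# --------------------------------------------------------------------------
# synapses
# --------------------------------------------------------------------------

@dataclass
class SynapseSpec:
    """Dual-exponential conductance synapse (normalised peak = weight)."""

    weight: float           # uS
    tau_rise: float = cn.TAU_RISE
    tau_decay: float = cn.TAU_DECAY
    e_rev: float = cn.E_EXC
    events: list = field(default_factory=list)  # presynaptic spike times, ms

    def __post_init__(self):
        if self.tau_decay <= self.tau_rise or self.tau_rise <= 0:
            raise ValueError("require tau_decay > tau_rise > 0")
        self.norm = cn.dualexp_norm(self.tau_rise, self.tau_decay)


def syn_conductance(spec: SynapseSpec, t: float) -> float:
    """Summed dual-exponential conductance (uS) at time ``t``.

    Each event contributes ``w * norm * (exp(-dt/tau2) - exp(-dt/tau1))``;
    the single-event peak equals ``w``.
    """
    g = 0.0
    for t0 in spec.events:
        dt = t - t0
        if dt >= 0.0:
            g += spec.weight * spec.norm * (
                math.exp(-dt / spec.tau_decay) - math.exp(-dt / spec.tau_rise)
            )
    return g


def gabaa_currents(g: float, v: float, e_cl: float, e_hco3: float,
                   p: float = cn.P_HCO3) -> tuple[float, float]:
    """Split the GABAa current into its Cl- and HCO3- components.

    ``I_Cl = (1-P) g (V - E_Cl)``, ``I_HCO3 = P g (V - E_HCO3)``; the sum
    equals ``g (V - E_GABAa)`` with the convex-combination reversal.
    ``g`` is a conductance density here (any conductance unit works as long
    as the caller is consistent).
    """
    if g < 0:
        raise ValueError("conductance must be non-negative")
    return (1.0 - p) * g * (v - e_cl), p * g * (v - e_hco3)


# --------------------------------------------------------------------------
# maximal conductances (Table-style defaults) and whole-compartment currents
# --------------------------------------------------------------------------

CURRENTS = ("Na", "NaP", "Kdr", "CaL", "KAHP", "KC", "KM",
            "Na_leak", "K_leak", "Cl_leak")

#: default maximal conductances, S/cm^2, keyed by compartment kind
CONDUCTANCES = {
    PY_SOMA: {"Na": 0.014, "NaP": 60e-5, "Kdr": 0.032, "CaL": 15e-5,
              "KAHP": 5e-5, "KC": 0.196e3, "KM": 0.006,
              "Na_leak": 1.5e-5, "K_leak": 3e-5, "Cl_leak": 1e-5},
    PY_DEND: {"Na": 0.0014, "NaP": 0.0, "Kdr": 0.0032, "CaL": 15e-5,
              "KAHP": 5e-5, "KC": 0.196e3, "KM": 0.0,
              "Na_leak": 1.1e-5, "K_leak": 3e-5, "Cl_leak": 1e-5},
    IN_SOMA: {"Na": 0.013, "NaP": 0.0, "Kdr": 0.027, "CaL": 0.0,
              "KAHP": 0.0, "KC": 0.0, "KM": 0.0,
              "Na_leak": 2.9e-5, "K_leak": 6e-5, "Cl_leak": 1e-5},
}

#: gate exponents (activation power; inactivation power is 1 where present)
GATE_EXPONENTS = {
    PY_SOMA: {"Na": 3, "NaP": 2, "Kdr": 4, "CaL": 2, "KAHP": 1, "KC": 1, "KM": 1},
    PY_DEND: {"Na": 2, "NaP": 2, "Kdr": 2, "CaL": 2, "KAHP": 1, "KC": 1, "KM": 1},
    IN_SOMA: {"Na": 3, "NaP": 2, "Kdr": 4, "CaL": 2, "KAHP": 1, "KC": 1, "KM": 1},
}

#: saturation scale of the I_KC calcium factor, in the model's mM-converted units
KC_CA_SCALE = 250.0


def conductance_set(kind: int, overrides: dict | None = None) -> dict:
    """A copy of the default conductances for one compartment kind."""
    g = dict(CONDUCTANCES[kind])
    for name, val in (overrides or {}).items():
        if name not in g:
            raise KeyError(f"unknown current conductance {name!r}")
        if val < 0:
            raise ValueError(f"conductance {name} must be >= 0")
        g[name] = val
    return g


class ConductanceSet(dict):
    """Mapping current-name -> maximal conductance (S/cm^2) for one kind."""

    def __init__(self, kind: int, overrides: dict | None = None):
        super().__init__(conductance_set(kind, overrides))
        self.kind = kind


@dataclass
class PumpSpec:
    imax: float
    km_k: float = cn.KM_K
    km_na: float = cn.KM_NA


@dataclass
class KCC2Spec:
    u: float = cn.U_KCC2


@dataclass
class GliaBufferState:
    b_free: float
    kb_bound: float
    b_max: float = cn.B_MAX
    k1: float = cn.K1_GLIA


@dataclass
class CaHandling:
    pump_imax: float = cn.CA_PUMP_IMAX
    pump_km: float = cn.CA_PUMP_KM
    buffer_total: float = cn.CA_BUFFER_TOTAL
    kd: float = cn.CA_KD


def effective_conductances(kind: int, gates: np.ndarray, ca_free: float,
                           conds: dict | None = None) -> dict:
    """Open-channel conductance (S/cm^2) of every current of a compartment kind.

    Applies the gate exponents and, for I_KC, the ``min([Ca]i/250, 1)``
    saturation factor.
    """
    g = conds or CONDUCTANCES[kind]
    exp = GATE_EXPONENTS[kind]
    sat = min(ca_free / KC_CA_SCALE, 1.0)
    return {
        "Na": g["Na"] * gates[G_MNA] ** exp["Na"] * gates[G_HNA],
        "NaP": g["NaP"] * gates[G_MNAP] ** exp["NaP"] * gates[G_HNAP],
        "Kdr": g["Kdr"] * gates[G_NKDR] ** exp["Kdr"],
        "CaL": g["CaL"] * gates[G_MCAL] ** exp["CaL"],
        "KAHP": g["KAHP"] * gates[G_MKAHP],
        "KC": g["KC"] * sat * gates[G_MKC],
        "KM": g["KM"] * gates[G_MKM],
        "Na_leak": g["Na_leak"],
        "K_leak": g["K_leak"],
        "Cl_leak": g["Cl_leak"],
    }


def membrane_currents(kind: int, v: float, gates: np.ndarray, reversals: dict,
                      ca_free: float = gating.CA_REST,
                      conds: dict | None = None) -> dict:
    """Every membrane current density (mA/cm^2) of one compartment.

    ``reversals`` must map 'Na', 'K', 'Cl', 'Ca' to reversal potentials
    (mV).  Positive values are outward.  Pump/KCC2/Ca-pump and synaptic
    currents are separate mechanisms and not included here.
    """
    ge = effective_conductances(kind, gates, ca_free, conds)
    ena, ek, ecl, eca = (reversals[s] for s in ("Na", "K", "Cl", "Ca"))
    out = {
        "Na": ge["Na"] * (v - ena),
        "NaP": ge["NaP"] * (v - ena),
        "Kdr": ge["Kdr"] * (v - ek),
        "CaL": ge["CaL"] * (v - eca),
        "KAHP": ge["KAHP"] * (v - ek),
        "KC": ge["KC"] * (v - ek),
        "KM": ge["KM"] * (v - ek),
        "Na_leak": ge["Na_leak"] * (v - ena),
        "K_leak": ge["K_leak"] * (v - ek),
        "Cl_leak": ge["Cl_leak"] * (v - ecl),
    }
    return out


def current_totals_by_ion(currents: dict) -> dict:
    """Sum the conductance-based membrane currents per carried ion."""
    return {
        "Na": currents["Na"] + currents["NaP"] + currents["Na_leak"],
        "K": (currents["Kdr"] + currents["KAHP"] + currents["KC"]
              + currents["KM"] + currents["K_leak"]),
        "Cl": currents["Cl_leak"],
        "Ca": currents["CaL"],
    }
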