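"""Voltage- and calcium-dependent gating kinetics of the active currents.

Three compartment kinds exist in the network: pyramidal soma (``PY_SOMA``),
pyramidal dendrite (``PY_DEND``) and the fast-spiking interneuron soma
(``IN_SOMA``).  The interneuron reuses the somatic Na/Kdr kinetics with its
activation curves shifted 3 mV (I_Na) and 19 mV (I_Kdr) toward more negative
potentials, which prevents depolarisation block during strong current
injection.  The delayed-rectifier activation is already shifted +18 mV in
the pyramidal soma and +10 mV in the dendrite relative to its empirical fit
(raising the firing threshold); those shifts are folded into the
half-activation voltages below.

Rates are 1/ms, time constants ms, voltages mV, calcium mM.  Rational rate
forms with ``exp(x)-1`` denominators are evaluated through their removable
singularity by a series expansion near x = 0.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PY_SOMA, PY_DEND, IN_SOMA = 0, 1, 2
KINDS = (PY_SOMA, PY_DEND, IN_SOMA)

# gate slots in the state matrix
G_MNA, G_HNA, G_MNAP, G_HNAP, G_NKDR, G_MCAL, G_MKAHP, G_MKC, G_MKM = range(9)
NGATES = 9

#: gates that are active for each compartment kind
GATES_BY_KIND = {
    PY_SOMA: (G_MNA, G_HNA, G_MNAP, G_HNAP, G_NKDR, G_MCAL, G_MKAHP, G_MKC, G_MKM),
    PY_DEND: (G_MNA, G_HNA, G_NKDR, G_MCAL, G_MKAHP, G_MKC),
    IN_SOMA: (G_MNA, G_HNA, G_NKDR),
}

#: resting free calcium used by the I_KAHP activation rate, mM
CA_REST = 5e-5

_KDR_D = 0.0338338  # beta_n scale; the companion constant C = -exp(-64.9/5)


@njit(cache=True)
def _exprel(x, a):
    """x / (exp(x/a) - 1), continuous through x = 0 (limit a - x/2)."""
    if abs(x) < 1e-7:
        return a - 0.5 * x
    return x / math.expm1(x / a)


@njit(cache=True)
def _linoid(x, a):
    """x / (1 - exp(-x/a)), continuous through x = 0 (limit a + x/2)."""
    if abs(x) < 1e-7:
        return a + 0.5 * x
    return -x / math.expm1(-x / a)


@njit(cache=True)
def na_m_rates(kind, v):
    """(alpha, beta) of the transient-Na activation gate."""
    if kind == 1:  # dendrite
        return 0.32 * _exprel(-v - 48.9, 4.0), 0.28 * _exprel(v + 21.9, 5.0)
    if kind == 2:  # interneuron: soma kinetics shifted -3 mV
        v = v + 3.0
    return 0.8 * _exprel(-v - 39.8, 4.0), 0.7 * _exprel(v + 14.8, 5.0)


@njit(cache=True)
def na_h_rates(kind, v):
    """(alpha, beta) of the transient-Na inactivation gate."""
    if kind == 1:
        a = 0.128 * math.exp((-v - 44.0) / 18.0)
        b = 4.0 / (1.0 + math.exp((-v - 21.0) / 5.0))
    else:
        a = 0.32 * math.exp((-v - 15.0) / 18.0)
        b = 10.0 / (math.exp((-v - 15.0) / 5.0) + 1.0)
    return a, b


@njit(cache=True)
def nap_m_inf_tau(v):
    minf = 1.0 / (1.0 + math.exp((-48.7 - v) / 4.4))
    x = v + 38.0
    denom = 0.091 * _linoid(x, 5.0) - 0.062 * (-_linoid(-x, 5.0))
    return minf, 1.0 / denom


@njit(cache=True)
def nap_h_inf_tau(v):
    hinf = 1.0 / (1.0 + math.exp((48.8 + v) / 9.98))
    if v <= -60.0:
        x = v + 60.0
        base, scale = 3700.0, 2000.0
    else:
        x = v + 74.0
        base, scale = 1200.0, 8000.0
    denom = 0.091 * _linoid(x, 5.0) - 0.062 * (-_linoid(-x, 5.0))
    return hinf, base + scale / denom


@njit(cache=True)
def kdr_n_inf_tau(kind, v):
    # the interneuron reuses the somatic kinetics with its activation curve
    # (steady state only, not the time constant) shifted -19 mV
    if kind == 1:
        vhalf = -14.8
        va = v
    elif kind == 2:
        vhalf = -22.8
        va = v + 19.0
    else:
        vhalf = -22.8
        va = v
    ninf = 1.0 / (1.0 + math.exp((vhalf - va) / 13.6))
    alpha = 0.016 * _linoid(v + 64.9, 5.0)
    beta = _KDR_D * math.exp(-v / 40.0)
    return ninf, 1.6 / (alpha + beta)


@njit(cache=True)
def cal_m_rates(v):
    a = 1.6 / (1.0 + math.exp(-0.072 * (v - 5.0)))
    b = 0.02 * _exprel(v + 8.9, 5.0)
    return a, b


@njit(cache=True)
def kahp_m_rates(ca):
    a = 2000.0 * (ca - CA_REST)
    if a < 0.0:
        a = 0.0
    return a, 0.01


@njit(cache=True)
def kc_m_rates(v):
    if v <= -10.0:
        a = math.exp((v + 50.0) / 11.0 - (v + 53.5) / 27.0) / 18.975
        b = 2.0 * math.exp((-v - 53.5) / 27.0) - a
        if b < 0.0:
            b = 0.0   # the two exponentials cross marginally near the branch point
    else:
        a = 2.0 * math.exp((-v - 53.5) / 27.0)
        b = 0.0
    return a, b


@njit(cache=True)
def km_m_inf_tau(v):
    minf = 1.0 / (1.0 + math.exp(-(v + 33.0) / 5.0))
    tau = 1000.0 / (3.3 * math.exp((v + 35.0) / 40.0) + math.exp((-v - 35.0) / 20.0))
    return minf, tau


@njit(cache=True)
def gate_inf_tau(kind, gate, v, ca):
    """Steady state and time constant of one gate slot.

    Gates that do not exist for ``kind`` still return a harmless value; the
    corresponding conductance is zero so they never influence the dynamics.
    """
    if gate == G_MNA:
        a, b = na_m_rates(kind, v)
    elif gate == G_HNA:
        a, b = na_h_rates(kind, v)
    elif gate == G_MNAP:
        return nap_m_inf_tau(v)
    elif gate == G_HNAP:
        return nap_h_inf_tau(v)
    elif gate == G_NKDR:
        return kdr_n_inf_tau(kind, v)
    elif gate == G_MCAL:
        a, b = cal_m_rates(v)
    elif gate == G_MKAHP:
        a, b = kahp_m_rates(ca)
    elif gate == G_MKC:
        a, b = kc_m_rates(v)
    else:
        return km_m_inf_tau(v)
    s = a + b
    if s <= 0.0:
        return 0.0, 1e12
    return a / s, 1.0 / s


def steady_gates(kind: int, v: float, ca: float = CA_REST) -> np.ndarray:
    """All nine gate variables at their steady state for a fixed voltage."""
    out = np.empty(NGATES)
    for g in range(NGATES):
        out[g] = gate_inf_tau(kind, g, v, ca)[0]
    return out
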