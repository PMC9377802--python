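"""Concentration state and its evolution: flux conversion, diffusion, volumes.

The network tracks six ion species.  Na+, K+, Cl- and Ca2+ are dynamic on
both membrane sides; the impermeant anion A- changes intracellularly only
through volume compensation ([A-]o is fixed at 0) and HCO3- is static on
both sides.  Electrostatic drift in the extracellular space is neglected;
all spatial exchange is Fickian diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as cn
from .biophysics import nernst, gaba_reversal

__all__ = [
    "IonPool",
    "VolumeDynamics",
    "membrane_flux",
    "longitudinal_diffusion",
    "radial_diffusion",
    "bath_flux",
    "volume_step",
    "refresh_reversals",
]


@dataclass
class IonPool:
    """Paired intra/extracellular concentration state of one species."""

    species: str
    conc_in: float    # mM
    conc_out: float   # mM
    valence: int
    diff_coef: float  # um^2/ms
    dynamic: bool = True


def default_pools() -> dict[str, IonPool]:
    """Pools at the printed resting composition (one representative unit)."""
    pools = {}
    for idx, name in enumerate(cn.SPECIES):
        pools[name] = IonPool(
            name, cn.C_IN_REST[idx], cn.C_OUT_REST[idx],
            int(cn.VALENCE[idx]), cn.DIFF_COEF[idx],
            dynamic=name != "A",
        )
    pools["HCO3"] = IonPool("HCO3", cn.HCO3_IN, cn.HCO3_OUT, -1, 0.0, dynamic=False)
    return pools


@dataclass
class VolumeDynamics:
    """Osmotic volume relaxation parameters."""

    tau: float = cn.OSMO_TAU   # ms
    c: float = cn.OSMO_C       # um^3/mM


def membrane_flux(current_sum: float, surface: float, valence: int,
                  v_in: float, v_out: float) -> tuple[float, float]:
    """Convert a net per-ion membrane current into concentration fluxes.

    ``J_in = -I S / (z F V_in)`` and ``J_out = +I S / (z F V_out)`` in
    mM/ms, so the moles leaving one side enter the other exactly
    (``J_in V_in + J_out V_out = 0``).
    """
    if valence == 0:
        raise ValueError("valence must be nonzero for a charge-carrying flux")
    if v_in <= 0 or v_out <= 0:
        raise ValueError("compartment volumes must be positive")
    base = current_sum * surface * cn.JFAC / valence
    return -base / v_in, base / v_out


def longitudinal_diffusion(conc_a: float, conc_b: float, diff_coef: float,
                           cross_section: float, distance: float,
                           vol_a: float, vol_b: float) -> tuple[float, float]:
    """Fickian exchange between two compartments of one cell, mM/ms each.

    Flux into a: ``D ([b]-[a]) S / (L V_a)``; the pair is volume-weighted
    antisymmetric so total mass is conserved.
    """
    drive = diff_coef * (conc_b - conc_a) * cross_section / distance
    return drive / vol_a, -drive / vol_b


def radial_diffusion(conc: np.ndarray, volumes: np.ndarray,
                     pairs: list[tuple[int, int]],
                     contact_area: np.ndarray, spacing: np.ndarray,
                     diff_coef: float) -> np.ndarray:
    """Fickian exchange between adjacent extracellular shells.

    ``pairs[k] = (i, j)`` exchanges through ``contact_area[k]`` over
    ``spacing[k]``; returns d[conc]/dt per shell (mM/ms), summed over all
    adjacent shells.
    """
    out = np.zeros_like(conc)
    for k, (i, j) in enumerate(pairs):
        drive = diff_coef * (conc[j] - conc[i]) * contact_area[k] / spacing[k]
        out[i] += drive / volumes[i]
        out[j] -= drive / volumes[j]
    return out


def bath_flux(conc_out: float, bath_conc: float, diff_coef: float,
              shell_surface: float, bath_distance: float, volume: float,
              scale: float = cn.BATH_SCALE) -> float:
    """Restorative diffusion between a shell and the common bath, mM/ms."""
    return diff_coef * (bath_conc - conc_out) * shell_surface / (
        scale * bath_distance * volume)


def osmolarities(conc_in: np.ndarray, conc_out: np.ndarray) -> tuple[float, float]:
    """Total osmolarity on each side, including the static HCO3-.

    ``conc_in``/``conc_out`` hold the five dynamic species (Na, K, Cl,
    free Ca, A) of one compartment.
    """
    return float(np.sum(conc_in) + cn.HCO3_IN), float(np.sum(conc_out) + cn.HCO3_OUT)


def volume_step(conc_in: np.ndarray, conc_out: np.ndarray,
                v_in: float, v_out: float, dt: float,
                vd: VolumeDynamics | None = None,
                floor_fraction: float = cn.ECS_FRACTION_MIN):
    """One osmotic volume update; returns new concentrations and volumes.

    The rate of intracellular growth is ``Delta = c (pi_i - pi_o)/tau``;
    total volume is conserved exactly and per-species mass
    (concentration x volume) is kept exactly constant by rescaling the
    concentrations.  Shrinkage of the shell stops at the extracellular
    floor (``Delta`` is zeroed rather than reflected).
    """
    vd = vd or VolumeDynamics()
    pi_i, pi_o = osmolarities(conc_in, conc_out)
    delta = vd.c * (pi_i - pi_o) / vd.tau
    vi_new = v_in + delta * dt
    vo_new = v_out - delta * dt
    if delta > 0 and vo_new < floor_fraction * vi_new:
        return conc_in.copy(), conc_out.copy(), v_in, v_out
    return (conc_in * (v_in / vi_new), conc_out * (v_out / vo_new),
            vi_new, vo_new)


def refresh_reversals(conc_in: dict | None = None, conc_out: dict | None = None,
                      temperature: float = cn.TEMPERATURE,
                      p_hco3: float = cn.P_HCO3) -> dict[str, float]:
    """Recompute every reversal potential (mV) from current concentrations.

    Defaults reproduce the printed resting values (E_Na 69.4, E_K -84.5,
    E_Cl -81.8, E_Ca 139.3, E_HCO3 -13.4, E_GABAa -69.5).
    """
    ci = conc_in or {"Na": cn.C_IN_REST[cn.NA], "K": cn.C_IN_REST[cn.K],
                     "Cl": cn.C_IN_REST[cn.CL], "Ca": cn.C_IN_REST[cn.CA],
                     "HCO3": cn.HCO3_IN}
    co = conc_out or {"Na": cn.C_OUT_REST[cn.NA], "K": cn.C_OUT_REST[cn.K],
                      "Cl": cn.C_OUT_REST[cn.CL], "Ca": cn.C_OUT_REST[cn.CA],
                      "HCO3": cn.HCO3_OUT}
    zmap = {"Na": 1, "K": 1, "Cl": -1, "Ca": 2, "HCO3": -1}
    rev = {s: nernst(co[s], ci[s], z, temperature) for s, z in zmap.items()}
    rev["GABAa"] = gaba_reversal(rev["Cl"], rev["HCO3"], p_hco3)
    return rev
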