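"""Point-source local field potential from transmembrane currents.

Every compartment contributes its total transmembrane current (ionic,
pump and synaptic; injected stimulus currents are excluded) as a point
source at its midpoint: ``phi(r) = 1/(4 pi sigma) sum I_n / |r - r_n|``.
Interneuron sources are down-weighted (0.2) as in the reference model.
"""

from __future__ import annotations

import numpy as np

from . import constants as cn


def point_source_potential(current_ma: float, distance_um: float,
                           sigma: float = cn.SIGMA_EXTRA) -> float:
    """Extracellular potential (mV) of one point current source.

    ``current_ma`` is in mA, ``distance_um`` in micrometres and ``sigma``
    in S/m.
    """
    if distance_um <= 0:
        raise ValueError("electrode coincides with a current source")
    return current_ma * 1e3 / (4.0 * np.pi * sigma * distance_um * 1e-6) * 1e-3


def lfp_weights(model, electrode: np.ndarray | None = None,
                sigma: float = cn.SIGMA_EXTRA) -> np.ndarray:
    """Per-compartment weights mapping current density (mA/cm^2) to LFP (mV)."""
    r = electrode if electrode is not None else model.electrode
    dist = np.linalg.norm(model.positions - r[None, :], axis=1)
    if np.any(dist <= 0):
        raise ValueError("electrode coincides with a current source")
    return (model.lfp_source_weight * model.area_cm2 * 1e6
            / (4.0 * np.pi * sigma * dist))


def compute_lfp(imem: np.ndarray, model, electrode: np.ndarray | None = None,
                sigma: float = cn.SIGMA_EXTRA) -> np.ndarray:
    """LFP time series (mV) from per-compartment membrane current densities."""
    return np.asarray(imem) @ lfp_weights(model, electrode, sigma)
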