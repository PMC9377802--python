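"""Cylindrical compartment geometry and the interstitial shells around it.

Each neuronal compartment is an equivalent cylinder surrounded by its own
extracellular shell.  The resting shell volume is 15% of the cellular
volume (matching an extracellular volume fraction alpha = 0.131); shells
may shrink osmotically down to a 4% floor.  All derived areas and the bath
distance are computed here once from the printed cylinder dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as cn


@dataclass
class CompartmentGeometry:
    """Geometry of one cylinder plus its interstitial shell (um, um^2, um^3)."""

    length: float
    diameter: float
    ecs_fraction: float = cn.ECS_FRACTION_REST

    radius: float = field(init=False)
    surface: float = field(init=False)        # lateral membrane area
    cross_section: float = field(init=False)  # intracellular cross-section
    v_in: float = field(init=False)           # resting intracellular volume
    v_out: float = field(init=False)          # resting shell volume
    shell_radius: float = field(init=False)   # outer radius of the shell
    shell_thickness: float = field(init=False)
    shell_surface: float = field(init=False)  # outer lateral area of the shell
    shell_cross_section: float = field(init=False)  # annulus area
    bath_distance: float = field(init=False)  # half the shell thickness

    def __post_init__(self):
        r = self.diameter / 2.0
        self.radius = r
        self.surface = math.pi * self.diameter * self.length
        self.cross_section = math.pi * r * r
        self.v_in = self.cross_section * self.length
        self.v_out = self.ecs_fraction * self.v_in
        ro = math.sqrt(r * r + self.v_out / (math.pi * self.length))
        self.shell_radius = ro
        self.shell_thickness = ro - r
        self.shell_surface = 2.0 * math.pi * ro * self.length
        self.shell_cross_section = math.pi * (ro * ro - r * r)
        self.bath_distance = 0.5 * self.shell_thickness


#: printed cylinder dimensions
PY_SOMA_GEOM = CompartmentGeometry(length=20.0, diameter=15.0)
PY_DEND_GEOM = CompartmentGeometry(length=450.0, diameter=6.88)
IN_SOMA_GEOM = CompartmentGeometry(length=20.0, diameter=15.0)

#: centre-to-centre distance between the somatic and dendritic compartment, um
SOMA_DEND_DISTANCE = (PY_SOMA_GEOM.length + PY_DEND_GEOM.length) / 2.0

#: fraction of the outer shell surface in contact with a neighbouring shell
RADIAL_CONTACT_FRACTION = 0.16

#: centre-to-centre distance between neighbouring cells' shells, um
RADIAL_SPACING = 40.0

#: distance between every interstitial shell and the common bath, um.
#: The bath boundary is placed half a somatic shell radius outside the
#: shells, uniformly for all compartments (derived value: 4.02 um).  The
#: alternative per-compartment reading (half of each shell's ~0.5 um wall
#: thickness) makes the dendritic shell clear toward the bath faster than
#: the somatic one, which suppresses the dendritic K+ accumulation that
#: the model's tonic-to-bursting transition requires.
BATH_DISTANCE = PY_SOMA_GEOM.shell_radius / 2.0


def coupling_conductance(ra: float = cn.RA,
                         soma: CompartmentGeometry = PY_SOMA_GEOM,
                         dend: CompartmentGeometry = PY_DEND_GEOM) -> float:
    """Somato-dendritic coupling conductance (S) from axial resistance.

    Series resistance of the two half-cylinders: R = Ra (L_s/2A_s + L_d/2A_d)
    with lengths in cm and cross-sections in cm^2.
    """
    r_s = ra * (soma.length * 1e-4 / 2.0) / (soma.cross_section * 1e-8)
    r_d = ra * (dend.length * 1e-4 / 2.0) / (dend.cross_section * 1e-8)
    return 1.0 / (r_s + r_d)
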