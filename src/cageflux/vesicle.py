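"""Spherical vesicle geometry and osmolyte bookkeeping.

A stopped-flow shrinkage experiment mixes a liposome suspension with a
hypertonic osmolyte solution.  The vesicle is modelled as a sphere whose
surface area ``S`` and initial volume ``V0`` follow from the mean
hydrodynamic diameter (DLS), and whose osmotic state is described by the
intravesicular concentration at time zero (``c_in0``) and the constant
extravesicular concentration (``c_out``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import BILAYER_THICKNESS_NM


@dataclass(frozen=True)
class VesicleSpec:
    """Spherical vesicle with its osmotic boundary conditions.

    Parameters
    ----------
    diameter_nm
        Outer (hydrodynamic) diameter in nm.  Both ``S`` and ``V0`` are
        computed from this diameter.
    c_in0_osm
        Intravesicular osmolyte concentration at t = 0, Osm L⁻¹.
    c_out_osm
        Extravesicular osmolyte concentration after mixing, Osm L⁻¹.
    bilayer_thickness_nm
        Membrane thickness, nm; used only for geometric sanity checks.
    """

    diameter_nm: float
    c_in0_osm: float
    c_out_osm: float
    bilayer_thickness_nm: float = BILAYER_THICKNESS_NM

    def __post_init__(self) -> None:
        if self.diameter_nm <= 2 * self.bilayer_thickness_nm:
            raise ValueError(
                f"diameter ({self.diameter_nm} nm) must exceed twice the "
                f"bilayer thickness ({self.bilayer_thickness_nm} nm)"
            )
        if self.c_in0_osm < 0 or self.c_out_osm < 0:
            raise ValueError("osmolyte concentrations must be non-negative")
        if self.delta_osm < 0:
            raise ValueError(
                "swelling regime (c_out < c_in0) is not supported; "
                "the shrinkage model requires delta_osm >= 0"
            )

    @property
    def radius_nm(self) -> float:
        return self.diameter_nm / 2.0

    @property
    def surface_area_nm2(self) -> float:
        """Sphere surface area S, nm²."""
        return 4.0 * math.pi * self.radius_nm**2

    @property
    def volume_nm3(self) -> float:
        """Initial volume V0, nm³."""
        return (4.0 / 3.0) * math.pi * self.radius_nm**3

    @property
    def s_over_v0_per_m(self) -> float:
        """Surface-to-volume ratio S/V0 = 3/r, in m⁻¹."""
        return 3.0 / (self.radius_nm * 1e-9)

    @property
    def delta_osm(self) -> float:
        """Osmotic gradient Δosm = c_out − c_in0, Osm L⁻¹."""
        return self.c_out_osm - self.c_in0_osm


def post_mixing_concentrations(
    c_vesicle_osm: float,
    c_hypertonic_osm: float,
    mixing_ratio: float = 1.0,
) -> tuple[float, float]:
    """Osmolyte concentrations after stopped-flow mixing.

    The liposome suspension (internal and external osmolyte at
    ``c_vesicle_osm``) is mixed with a hypertonic solution at
    ``c_hypertonic_osm`` in a volume ratio ``mixing_ratio`` (hypertonic :
    vesicle, default 1:1).  The vesicle interior does not mix, so
    ``c_in0`` stays at the preparation value while ``c_out`` becomes the
    volume-weighted mean of the two solutions.

    Returns
    -------
    (c_in0, c_out) in Osm L⁻¹.

    Examples
    --------
    200 mM sucrose inside, 600 mM hypertonic osmolyte, 1:1 mixing gives
    c_in0 = 0.2 and c_out = 0.4 Osm L⁻¹ (sucrose osmotic coefficient
    taken as 1).
    """
    if c_vesicle_osm < 0 or c_hypertonic_osm < 0:
        raise ValueError("concentrations must be non-negative")
    if mixing_ratio <= 0:
        raise ValueError("mixing_ratio must be positive")
    c_out = (c_vesicle_osm + mixing_ratio * c_hypertonic_osm) / (1.0 + mixing_ratio)
    return c_vesicle_osm, c_out
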