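"""Nanoaggregate counting and single-nanoaggregate permeability.

Membrane-spanning cage nanoaggregates are counted with a unit-area
model: each aggregate of cross-section A_POC shares the membrane with
its stoichiometric allotment of lipids (headgroup area 0.35 nm²), so the
"unit area" is

    A_Unit = A_POC + ((1 − x)/x) · 0.35,

with x the aggregate-per-lipid mole ratio (feed molar channel/lipid
ratio divided by the number of cage molecules per aggregate).  The
number of aggregates per liposome is N = A_Total / A_Unit with

    A_Total = 2πr² + 2π(r − t)²,   t = bilayer thickness (nm),

i.e. half the combined outer- and inner-leaflet sphere areas, and is
halved again when aggregates are counted as membrane-spanning channels.
Dividing the whole-liposome volume flow by N gives the per-aggregate
permeability P_a, reported both as cm³ s⁻¹ and as water molecules per
second (× N_A / 18 cm³ mol⁻¹).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .constants import BILAYER_THICKNESS_NM, LIPID_AREA_NM2, WATERS_PER_CM3

__all__ = [
    "AggregateGeometry",
    "AggregateResult",
    "PRESETS",
    "geometry_for_preset",
    "aggregates_per_liposome",
    "single_aggregate_permeability",
    "volumetric_to_molecules",
]

#: (cross-sectional area nm², cage molecules per nanoaggregate)
PRESETS: dict[str, tuple[float, int]] = {
    "CC3": (22.73, 17),
    "FT-RCC3": (22.73, 17),
    "CC19": (22.73, 17),
    "CC5": (104.04, 75),
}


@dataclass(frozen=True)
class AggregateGeometry:
    """Geometry and stoichiometry of cage nanoaggregates in the bilayer."""

    a_poc_nm2: float
    fmclr: float
    n_per_aggregate: int = 17
    lipid_area_nm2: float = LIPID_AREA_NM2
    bilayer_thickness_nm: float = BILAYER_THICKNESS_NM

    def __post_init__(self) -> None:
        if self.a_poc_nm2 <= 0 or self.lipid_area_nm2 <= 0:
            raise ValueError("areas must be positive")
        if self.n_per_aggregate < 1:
            raise ValueError("n_per_aggregate must be >= 1")
        if not (0.0 < self.x < 1.0):
            raise ValueError(
                f"corrected mole ratio x = fmCLR/n_per_aggregate = {self.x:.3g} "
                "must lie in (0, 1)"
            )

    @property
    def x(self) -> float:
        """Aggregate-per-lipid mole ratio (corrected fmCLR)."""
        return self.fmclr / self.n_per_aggregate

    @property
    def a_unit_nm2(self) -> float:
        """Unit area: one aggregate plus its share of lipids, nm²."""
        return self.a_poc_nm2 + ((1.0 - self.x) / self.x) * self.lipid_area_nm2


def geometry_for_preset(name: str, fmclr: float) -> AggregateGeometry:
    """Geometry for a named cage (CC3, FT-RCC3, CC19, CC5)."""
    try:
        a_poc, n_agg = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return AggregateGeometry(a_poc_nm2=a_poc, fmclr=fmclr, n_per_aggregate=n_agg)


@dataclass(frozen=True)
class AggregateResult:
    """Aggregate count and, when computed, per-aggregate permeability."""

    a_unit_nm2: float
    a_total_nm2: float
    n_raw: float
    n: float
    halving_applied: bool
    radius_nm: float
    area_convention: str | None = None
    pa_volumetric_cm3_s: float | None = None
    pa_molecules_s: float | None = None


def aggregates_per_liposome(
    radius_nm: float,
    geom: AggregateGeometry,
    halving: bool = True,
) -> AggregateResult:
    """Count cage nanoaggregates per liposome by the unit-area model.

    ``halving=True`` (default) halves the raw unit-area count on the
    grounds that a membrane-spanning aggregate occupies both leaflets at
    once.
    """
    t = geom.bilayer_thickness_nm
    if radius_nm <= t:
        raise ValueError(
            f"radius ({radius_nm} nm) must exceed the bilayer thickness ({t} nm)"
        )
    a_total = 2.0 * math.pi * radius_nm**2 + 2.0 * math.pi * (radius_nm - t) ** 2
    a_unit = geom.a_unit_nm2
    n_raw = a_total / a_unit
    n = n_raw / 2.0 if halving else n_raw
    return AggregateResult(
        a_unit_nm2=a_unit,
        a_total_nm2=a_total,
        n_raw=n_raw,
        n=n,
        halving_applied=halving,
        radius_nm=radius_nm,
    )


def single_aggregate_permeability(
    pf_um_s: float,
    agg: AggregateResult,
    area_convention: str = "eq3_total",
) -> AggregateResult:
    """Per-aggregate water permeability P_a = P_f · A / N.

    ``area_convention`` selects the liposome surface area A:
    ``"eq3_total"`` uses the two-leaflet half-sum A_Total of the counting
    model (internally consistent with N); ``"sphere"`` uses the outer
    sphere area 4πr².  Returns a copy of ``agg`` with the volumetric
    (cm³ s⁻¹) and molecular (waters s⁻¹) throughputs filled in.
    """
    if pf_um_s < 0:
        raise ValueError("pf must be non-negative")
    if agg.n <= 0:
        raise ValueError("aggregate count must be positive")
    if area_convention == "eq3_total":
        area_nm2 = agg.a_total_nm2
    elif area_convention == "sphere":
        area_nm2 = 4.0 * math.pi * agg.radius_nm**2
    else:
        raise ValueError(
            f"unknown area_convention {area_convention!r}; "
            "use 'eq3_total' or 'sphere'"
        )
    pf_cm_s = pf_um_s * 1e-4
    area_cm2 = area_nm2 * 1e-14
    pa_vol = pf_cm_s * area_cm2 / agg.n
    return replace(
        agg,
        area_convention=area_convention,
        pa_volumetric_cm3_s=pa_vol,
        pa_molecules_s=volumetric_to_molecules(pa_vol),
    )


def volumetric_to_molecules(q_cm3_s: float) -> float:
    """Convert a volume flow (cm³ s⁻¹) to water molecules per second."""
    if q_cm3_s < 0:
        raise ValueError("flow must be non-negative")
    return q_cm3_s * WATERS_PER_CM3
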