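"""Flow and mass-balance arithmetic for percolated sediment cores.

Back-of-envelope quantities that frame the microsensor results: how fast
seawater infiltrates the core, how much solute that flow imposes on the
sediment per unit area, how deep plug-flow displacement would carry the
water, the stoichiometric ceiling on N2O accumulation, and areal budgets
that convert volumetric uptake rates in a surface zone into areal rates
comparable with the imposed fluxes.

Full precision is kept internally; :func:`display_round` reproduces the
conventional display rounding (one decimal for infiltration rates,
integers for areal fluxes and percentages).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .profiles import SedimentCore
from . import units


@dataclass
class FlowSpec:
    """A constant-rate percolation treatment on one core.

    flow_ml_min : pump or gravity-drain rate, mL min^-1
    core : the sediment core the water passes through
    duration_h : length of the percolation period, h
    solute_conc : concentration of the solute of interest in the
        percolating water, umol L^-1 (None when irrelevant)
    """

    flow_ml_min: float
    core: SedimentCore
    duration_h: float = 8.0
    solute_conc: float | None = None

    def __post_init__(self) -> None:
        if self.flow_ml_min < 0:
            raise DomainError("flow_ml_min must be >= 0")
        if self.duration_h <= 0:
            raise DomainError("duration_h must be > 0")


@dataclass
class ArealBudget:
    """Areal-rate equivalent of a volumetric rate acting over a zone."""

    volumetric_rate: float     # mmol m^-3 h^-1
    zone_thickness_m: float    # m
    areal_rate: float          # umol m^-2 h^-1


def infiltration_rate(flow: FlowSpec) -> float:
    """Vertical seawater infiltration rate, L m^-2 h^-1.

    Flow volume per core cross-sectional area per hour.
    """
    area = flow.core.cross_section_m2
    if area <= 0:
        raise DomainError("core cross-section must be > 0")
    l_per_h = flow.flow_ml_min / units.ML_PER_L * units.MIN_PER_H
    return l_per_h / area


def imposed_flux(flow: FlowSpec) -> float:
    """Solute flux imposed on the sediment surface, umol m^-2 h^-1."""
    if flow.solute_conc is None:
        raise DomainError("FlowSpec.solute_conc is not set")
    return infiltration_rate(flow) * flow.solute_conc


def theoretical_penetration(flow: FlowSpec) -> float:
    """Plug-flow displacement depth of the percolating water, cm.

    depth = volume / (area * porosity): the depth to which the infiltrated
    volume would displace porewater if it moved as an undispersed plug.
    """
    porosity = flow.core.porosity
    if porosity <= 0:
        raise DomainError("porosity must be > 0")
    volume_m3 = (flow.flow_ml_min * units.MIN_PER_H * flow.duration_h
                 / units.ML_PER_L / units.L_PER_M3)
    depth_m = volume_m3 / (flow.core.cross_section_m2 * porosity)
    return depth_m * units.CM_PER_M


def porewater_velocity(flow: FlowSpec) -> float:
    """Mean downward porewater velocity, m h^-1 (infiltration / porosity)."""
    q_m_per_h = infiltration_rate(flow) / units.L_PER_M3  # L m^-2 h^-1 -> m/h
    return q_m_per_h / flow.core.porosity


def stoichiometric_n2o_ceiling(nox_init: float) -> float:
    """Maximum N2O concentration producible from the initial NOx pool.

    Two NOx are reduced per N2O, so the ceiling is nox_init / 2 (umol L^-1).
    """
    if nox_init < 0:
        raise DomainError("nox_init must be >= 0")
    return nox_init / 2.0


def fraction_of_ceiling(n2o: float, nox_init: float) -> float:
    """Accumulated N2O as a percentage of the stoichiometric ceiling."""
    ceiling = stoichiometric_n2o_ceiling(nox_init)
    if ceiling <= 0:
        raise DomainError("ceiling is zero; nox_init must be > 0")
    return 100.0 * n2o / ceiling


def areal_uptake(volumetric_rate: float, zone_thickness_m: float) -> ArealBudget:
    """Areal rate (umol m^-2 h^-1) of a volumetric rate acting over a zone.

    areal = volumetric (mmol m^-3 h^-1) * thickness (m) * 1000.
    """
    if zone_thickness_m <= 0:
        raise DomainError("zone_thickness_m must be > 0")
    areal = volumetric_rate * zone_thickness_m * units.UMOL_PER_MMOL
    return ArealBudget(volumetric_rate=volumetric_rate,
                       zone_thickness_m=zone_thickness_m,
                       areal_rate=areal)


def fraction_of_supply(areal_uptake_flux: float, supply_flux: float) -> float:
    """Uptake as a percentage of the advective supply flux (unrounded)."""
    if supply_flux <= 0:
        raise DomainError("supply_flux must be > 0")
    return 100.0 * areal_uptake_flux / supply_flux


def display_round(value: float, kind: str) -> float:
    """Conventional display rounding: 'infiltration' to 1 decimal,
    'flux'/'percent' to integers, 'depth_cm' to 1 decimal."""
    if kind == "infiltration" or kind == "depth_cm":
        return round(value, 1)
    if kind in ("flux", "percent"):
        return float(round(value))
    raise DomainError(f"unknown display kind {kind!r}")
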