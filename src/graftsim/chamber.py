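"""Capital and electricity cost model of a walk-in low-temperature storage chamber.

The design base is a prefabricated insulated walk-in room (7.6 m x 7.6 m
x 3.7 m, ~214 m^3) holding two 5-layer shelving units lit continuously by
T8 fluorescent luminaires.  Lamp counts follow a lumen-method lighting
design: photons delivered to a shelf layer are the luminaire PAR photon
flux derated by a coefficient of utilization (cavity geometry and surface
reflectances) and a maintenance factor.  The cooling electricity is a
sensible-load model: the compressor removes the lighting heat plus the
envelope conduction gain at the chiller's coefficient of performance
(COP), while the lamps themselves draw their electrical power directly.

Crop set-points differ: tomato seedlings store at 10 degC under
5 umol m-2 s-1 PPF; watermelon at 12 degC under 12 umol m-2 s-1, which
roughly doubles the lighting requirement and dominates both the capital
premium and the electricity gap between the two configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

_WEEK_HOURS = 24 * 7


class ChamberError(ValueError):
    pass


@dataclass(frozen=True)
class ChamberDesign:
    width_m: float = 7.6
    depth_m: float = 7.6
    height_m: float = 3.7
    wall_insulation_m: float = 0.10
    shelf_units: int = 2
    shelf_layers_per_unit: int = 5
    layer_length_m: float = 7.6
    layer_depth_m: float = 3.4
    layer_height_m: float = 0.6
    tray_area_m2: float = 0.23
    max_trays: int = 960
    room_index: float = 3.82
    reflectance_upper: float = 0.70
    reflectance_wall: float = 0.30
    reflectance_lower: float = 0.10
    luminaire_par_flux_umol_s: float = 37.0
    luminaire_power_W: float = 32.0
    cop: float = 2.93
    ambient_C: float = 15.0
    ambient_RH: float = 0.50
    inside_RH: float = 0.60
    lighting_hours_per_day: float = 24.0

    def __post_init__(self) -> None:
        if min(self.width_m, self.depth_m, self.height_m) <= 0:
            raise ChamberError("chamber dimensions must be positive")


@dataclass(frozen=True)
class Geometry:
    footprint_m2: float
    volume_m3: float
    shelf_area_m2: float
    envelope_area_m2: float


@dataclass(frozen=True)
class CapitalUnitCosts:
    """Unit costs behind the capital breakdown (config-supplied defaults)."""

    structure_usd_per_m2: float = 533.47
    shelving_usd_per_m2: float = 84.61
    luminaire_usd_each: float = 23.566
    chiller_usd_per_m2: float = 24.53

    def __post_init__(self) -> None:
        if min(
            self.structure_usd_per_m2,
            self.shelving_usd_per_m2,
            self.luminaire_usd_each,
            self.chiller_usd_per_m2,
        ) < 0:
            raise ChamberError("unit costs must be non-negative")


@dataclass(frozen=True)
class CostBreakdown:
    """Itemized capital and weekly electricity, per m^2 of chamber footprint."""

    structure_usd_per_m2: float
    shelving_usd_per_m2: float
    luminaires_usd_per_m2: float
    chiller_usd_per_m2: float
    total_capital_usd_per_m2: float
    electricity_usd_per_m2_week: float
    electricity_usd_per_plant_week: float
    plants_per_m2_footprint: float
    luminaire_count: int

    @property
    def shares(self) -> dict[str, float]:
        t = self.total_capital_usd_per_m2
        return {
            "structure": self.structure_usd_per_m2 / t,
            "shelving": self.shelving_usd_per_m2 / t,
            "luminaires": self.luminaires_usd_per_m2 / t,
            "chiller": self.chiller_usd_per_m2 / t,
        }


# Storage capacities per m^2 of chamber footprint (960 trays at the two
# crops' tray planting densities); taken as direct design parameters.
PLANTS_PER_M2_FOOTPRINT = {"tomato": 3307.0, "watermelon": 2116.0}
STORAGE_SETPOINTS = {"tomato": (10.0, 5.0), "watermelon": (12.0, 12.0)}  # (temp C, PPF)


def chamber_geometry(design: ChamberDesign = ChamberDesign()) -> Geometry:
    """Footprint, volume, total shelf area and envelope (walls+ceiling+floor)."""
    w, d, h = design.width_m, design.depth_m, design.height_m
    footprint = w * d
    layers = design.shelf_units * design.shelf_layers_per_unit
    return Geometry(
        footprint_m2=footprint,
        volume_m3=footprint * h,
        shelf_area_m2=layers * design.layer_length_m * design.layer_depth_m,
        envelope_area_m2=2 * footprint + 2 * h * (w + d),
    )


def luminaires_required(
    target_ppf: float,
    layer_area_m2: float,
    n_layers: int,
    luminaire_par_flux_umol_s: float = 37.0,
    utilization_factor: float = 0.6,
    maintenance_factor: float = 0.9,
) -> int:
    """Lamps needed to hold ``target_ppf`` on every shelf layer.

    Lumen-method count per layer: ``ceil(PPF * area / (flux * CU * MF))``,
    summed over layers.  The coefficient of utilization stands in for the
    full photometric tables of the cavity method and is configurable.
    """
    if luminaire_par_flux_umol_s <= 0:
        raise ChamberError("luminaire PAR flux must be positive")
    if not (0 < utilization_factor <= 1) or not (0 < maintenance_factor <= 1):
        raise ChamberError("utilization and maintenance factors must be in (0, 1]")
    if target_ppf < 0:
        raise ChamberError("target PPF must be >= 0")
    if target_ppf == 0:
        return 0
    per_layer = math.ceil(
        target_ppf
        * layer_area_m2
        / (luminaire_par_flux_umol_s * utilization_factor * maintenance_factor)
    )
    return per_layer * n_layers


def electricity_cost(
    design: ChamberDesign,
    target_ppf: float,
    inside_temp_C: float,
    plants_per_m2_footprint: float,
    envelope_U_W_m2K: float = 0.25,
    electricity_rate_usd_kWh: float = 0.11,
    utilization_factor: float = 0.6,
    maintenance_factor: float = 0.9,
) -> tuple[float, float, float]:
    """Weekly electricity: (total power W, $/m^2 footprint/week, $/plant/week).

    Total electric power = lighting + (lighting + envelope conduction)/COP.
    Raises if the chamber is warmer inside than outside (no-cooling regime).
    """
    if design.cop <= 0:
        raise ChamberError("COP must be positive")
    if inside_temp_C >= design.ambient_C and target_ppf > 0:
        raise ChamberError("inside temperature must be below ambient (no-cooling regime)")
    geo = chamber_geometry(design)
    n_layers = design.shelf_units * design.shelf_layers_per_unit
    count = luminaires_required(
        target_ppf,
        design.layer_length_m * design.layer_depth_m,
        n_layers,
        design.luminaire_par_flux_umol_s,
        utilization_factor,
        maintenance_factor,
    )
    lighting_W = count * design.luminaire_power_W
    envelope_W = envelope_U_W_m2K * geo.envelope_area_m2 * max(
        0.0, design.ambient_C - inside_temp_C
    )
    total_W = lighting_W + (lighting_W + envelope_W) / design.cop
    weekly_usd = total_W / 1000.0 * _WEEK_HOURS * electricity_rate_usd_kWh
    per_m2 = weekly_usd / geo.footprint_m2
    return total_W, per_m2, per_plant_cost(per_m2, plants_per_m2_footprint)


def per_plant_cost(per_m2_cost: float, plants_per_m2_footprint: float) -> float:
    """Identity converting a per-m^2-footprint cost to a per-plant cost."""
    if plants_per_m2_footprint <= 0:
        raise ChamberError("plant capacity must be positive")
    return per_m2_cost / plants_per_m2_footprint


def capital_breakdown(
    design: ChamberDesign,
    target_ppf: float,
    plants_per_m2_footprint: float,
    unit_costs: CapitalUnitCosts = CapitalUnitCosts(),
    inside_temp_C: float | None = None,
    envelope_U_W_m2K: float = 0.25,
    electricity_rate_usd_kWh: float = 0.11,
    utilization_factor: float = 0.6,
    maintenance_factor: float = 0.9,
) -> CostBreakdown:
    """Itemized capital plus weekly electricity for one storage configuration."""
    geo = chamber_geometry(design)
    n_layers = design.shelf_units * design.shelf_layers_per_unit
    count = luminaires_required(
        target_ppf,
        design.layer_length_m * design.layer_depth_m,
        n_layers,
        design.luminaire_par_flux_umol_s,
        utilization_factor,
        maintenance_factor,
    )
    lum_per_m2 = count * unit_costs.luminaire_usd_each / geo.footprint_m2
    total = (
        unit_costs.structure_usd_per_m2
        + unit_costs.shelving_usd_per_m2
        + lum_per_m2
        + unit_costs.chiller_usd_per_m2
    )
    if inside_temp_C is None:
        per_m2_week, per_plant_week = 0.0, 0.0
    else:
        _, per_m2_week, per_plant_week = electricity_cost(
            design,
            target_ppf,
            inside_temp_C,
            plants_per_m2_footprint,
            envelope_U_W_m2K,
            electricity_rate_usd_kWh,
            utilization_factor,
            maintenance_factor,
        )
    return CostBreakdown(
        structure_usd_per_m2=unit_costs.structure_usd_per_m2,
        shelving_usd_per_m2=unit_costs.shelving_usd_per_m2,
        luminaires_usd_per_m2=lum_per_m2,
        chiller_usd_per_m2=unit_costs.chiller_usd_per_m2,
        total_capital_usd_per_m2=total,
        electricity_usd_per_m2_week=per_m2_week,
        electricity_usd_per_plant_week=per_plant_week,
        plants_per_m2_footprint=plants_per_m2_footprint,
        luminaire_count=count,
    )


def crop_breakdown(crop: str, design: ChamberDesign = ChamberDesign(), **kwargs) -> CostBreakdown:
    """Cost breakdown at a crop's storage set-point (tomato or watermelon)."""
    if crop not in STORAGE_SETPOINTS:
        raise ChamberError(f"no storage set-point for crop {crop!r}")
    temp, ppf = STORAGE_SETPOINTS[crop]
    return capital_breakdown(
        design,
        target_ppf=ppf,
        plants_per_m2_footprint=PLANTS_PER_M2_FOOTPRINT[crop],
        inside_temp_C=temp,
        **kwargs,
    )
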