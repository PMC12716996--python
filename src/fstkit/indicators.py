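"""Outcome indicators: pure functions of a world state.

All computed indicators of the outcome panel — health headcounts, diet-
attributable premature mortality, biodiversity intactness (cropland and
hotspot landscape selections), Shannon crop-area diversity, nitrogen surplus,
environmental-flow violations, CO2-equivalent greenhouse-gas emissions, and
the inclusion/economy block (expenditure, poverty, labour, wages, bioeconomy
supply, production-factor use). Global surface warming requires a climate
emulator and is reported as not computed; ``WARMING_HOOK`` lets users plug an
external emissions-to-temperature mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from . import demand, health, poverty
from .errors import DomainError, ValidationError
from .world import CellState, CountryState, NitrogenBudget, WorldState

INDICATOR_NAMES: tuple[str, ...] = (
    "underweight", "obesity", "premature_mortality",
    "bii_cropland", "bii_hotspot", "crop_diversity",
    "nitrogen_surplus", "efr_violations", "ghg_emissions",
    "global_surface_warming",
    "ag_expenditure", "poverty", "ag_labour", "ag_wages",
    "bioeconomy_supply", "factor_use",
)

#: optional callable WorldState -> degC; None means 'not computed'
WARMING_HOOK = None

CROPLAND_SELECTOR_MIN_HA = 100.0


@dataclass
class EmissionVector:
    """Global emission totals by gas (Mt gas / yr) with CO2e factors."""

    co2: float
    ch4: float
    n2o: float
    gwp_table: dict[str, float] | None = None

    def gwp(self) -> dict[str, float]:
        return self.gwp_table or dict(C.DEFAULT_GWP100)


# ------------------------------------------------------------ biodiversity
def shannon_crop_diversity(shares) -> float:
    """Shannon index H = -sum p_k ln p_k over cropland classes.

    ``0 ln 0`` counts as 0; raises if the shares are not a distribution.
    Natural log, so K equally-shared classes give ln K.
    """
    p = np.asarray(list(shares), dtype=float)
    if np.any(p < -1e-12):
        raise ValidationError("negative crop share")
    total = p.sum()
    if total <= 0:
        raise DomainError("zero total cropland: Shannon index undefined")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def cell_crop_diversity(cell: CellState) -> float:
    return shannon_crop_diversity(
        [cell.area_by_class[c] for c in C.CROPLAND_CLASSES])


def cell_bii(cell: CellState) -> float:
    """Area-weighted mean intactness of a cell's land classes, in [0, 1]."""
    area = cell.total_area()
    if area <= 0:
        raise DomainError("cell has zero land area")
    return float(sum(cell.area_by_class[c] * cell.intactness[c]
                     for c in C.LAND_CLASSES) / area)


def aggregate_bii(world: WorldState, selector: str = "all") -> float:
    """Range-rarity-weighted mean of cell BII over a cell selection.

    ``cropland_landscape`` keeps cells with at least 100 ha of cropland;
    ``hotspot_landscape`` keeps biodiversity-hotspot / intact-forest cells.
    """
    if selector == "all":
        cells = world.cells
    elif selector == "cropland_landscape":
        cells = [c for c in world.cells if c.cropland_area() >= CROPLAND_SELECTOR_MIN_HA]
    elif selector == "hotspot_landscape":
        cells = [c for c in world.cells if c.hotspot_or_intact]
    else:
        raise ValidationError(f"unknown BII selector {selector!r}")
    if not cells:
        raise DomainError(f"BII selector {selector!r} selects no cells")
    w = np.array([c.range_rarity_weight for c in cells])
    b = np.array([cell_bii(c) for c in cells])
    return float((w * b).sum() / w.sum())


def bii_by_biome_region(world: WorldState) -> dict[str, float]:
    """Range-rarity-weighted BII per biome-region label."""
    acc: dict[str, list[float]] = {}
    for cell in world.cells:
        acc.setdefault(cell.biome_region, [0.0, 0.0])
        acc[cell.biome_region][0] += cell.range_rarity_weight * cell_bii(cell)
        acc[cell.biome_region][1] += cell.range_rarity_weight
    return {k: v[0] / v[1] for k, v in acc.items()}


# -------------------------------------------------------------- nitrogen
def nitrogen_surplus(budget: NitrogenBudget) -> dict[str, float]:
    """Surplus per pool (Mt N/yr) and totals.

    Cropland/pasture: inputs minus withdrawals (may be negative: soil
    mining, flagged). AWMS: excretion minus recycled. Natural vegetation is
    in steady state, so its surplus equals fixation. ``agricultural_soils``
    is the reduced cropland+pasture total used for planetary-boundary
    comparisons.
    """
    budget.validate()
    cropland = sum(budget.cropland_inputs.values()) - budget.cropland_withdrawal
    pasture = sum(budget.pasture_inputs.values()) - budget.pasture_withdrawal
    awms = budget.awms_excretion - budget.awms_recycled
    natural = budget.natural_fixation
    return {
        "cropland": cropland, "pasture": pasture, "awms": awms, "natural": natural,
        "agricultural_soils": cropland + pasture,
        "total": cropland + pasture + awms + natural,
        "soil_mining_flag": float(cropland < 0 or pasture < 0),
    }


def world_nitrogen_surplus(world: WorldState) -> float:
    return float(sum(nitrogen_surplus(cell.n_budget)["total"] for cell in world.cells))


# ------------------------------------------------------------------ water
def efr_violations(world: WorldState) -> float:
    """km3/yr of withdrawals exceeding what environmental flows allow."""
    total = 0.0
    for cell in world.cells:
        allowed = max(0.0, cell.water_availability - cell.efr)
        total += max(0.0, cell.water_withdrawal - allowed)
    return total


# -------------------------------------------------------------- emissions
def co2e_total(e: EmissionVector) -> float:
    """Gt CO2e/yr with GWP100 factors (CH4 27, N2O 273)."""
    gwp = e.gwp()
    mt = e.co2 * gwp["co2"] + e.ch4 * gwp["ch4"] + e.n2o * gwp["n2o"]
    return mt / 1000.0


def world_emissions(world: WorldState) -> EmissionVector:
    totals = {g: 0.0 for g in C.GASES}
    for cell in world.cells:
        for key, val in cell.emissions.items():
            gas = key.split(".")[0]
            totals[gas] += val
    return EmissionVector(totals["co2"], totals["ch4"], totals["n2o"],
                          dict(world.gwp_table))


# ---------------------------------------------------------------- economy
def agricultural_expenditure(country: CountryState) -> float:
    """USD/cap/yr on agricultural food commodities at shadow prices.

    Per-capita food use (supply, i.e. intake plus waste) times the shadow
    price per 1000 kcal, times the scenario price index.
    """
    total = 0.0
    for item in C.DIET_ITEMS:
        kcal_yr = country.diet.intake[item] * country.diet.waste_ratio * C.KCAL_PER_DAY_TO_YEAR
        price = country.shadow_prices[item]
        if price < 0 or kcal_yr < 0:
            raise ValidationError("negative price or food use")
        total += kcal_yr / 1000.0 * price
    return total * country.price_index


def labour_demand(country: CountryState) -> float:
    """Workers employed in agriculture.

    labour share x total factor costs / (hourly wage x annual hours).
    """
    if country.hourly_wage <= 0 or country.working_hours <= 0:
        raise DomainError("wage and working hours must be positive")
    total_costs = sum(country.factor_costs.values())
    return country.labour_share * total_costs / (
        country.hourly_wage * country.working_hours)


def wage_index(world: WorldState, base_wages: dict[str, float]) -> float:
    """Global wage index vs 2020, fixed 2010 population weights."""
    num = den = 0.0
    for country in world.countries:
        if country.name not in base_wages:
            raise ValidationError(f"no base-year wage recorded for {country.name}")
        ratio = country.hourly_wage / base_wages[country.name]
        num += ratio * country.population_2010
        den += country.population_2010
    return num / den


def constant_price_value(quantities: dict[str, float],
                         prices_2010: dict[str, float]) -> float:
    """sum quantity x fixed 2010 price; isolates volume effects."""
    if set(quantities) - set(prices_2010):
        raise ValidationError("quantities and prices are misaligned")
    return float(sum(q * prices_2010[k] for k, q in quantities.items()))


def bioeconomy_supply(world: WorldState) -> float:
    """Billion USD/yr of non-food value streams at fixed 2010 prices."""
    return sum(constant_price_value(c.bioeconomy_quantities, c.prices_2010)
               for c in world.countries) / 1e9


def factor_use(world: WorldState) -> float:
    """Billion USD/yr of labour, capital and intermediates at fixed prices."""
    return sum(sum(c.factor_costs.values()) for c in world.countries) / 1e9


# ------------------------------------------------------------------ panel
def crop_diversity_global(world: WorldState) -> float:
    """Cropland-area-weighted mean Shannon index over cells with cropland."""
    num = den = 0.0
    for cell in world.cells:
        area = cell.cropland_area()
        if area <= 0:
            continue
        num += area * cell_crop_diversity(cell)
        den += area
    if den == 0:
        raise DomainError("no cropland anywhere")
    return num / den


def indicator_panel(world: WorldState, base_wages: dict[str, float] | None = None) -> dict:
    """All outcome indicators for one state, in the panel's units.

    Headcounts and YLL in millions; BII and Shannon unitless; nitrogen in
    Mt N/yr; water in km3/yr; GHG in Gt CO2e/yr; expenditure in USD/cap/yr
    (population-weighted); poverty in million people; labour in million
    workers; wages as an index (needs ``base_wages``, else 1.0); bioeconomy
    and factor use in billion USD/yr. Global surface warming is None unless a
    warming hook is installed.
    """
    mort = sum(health.attributable_yll(c, world.risk_model, world.life_table)
               for c in world.countries)
    pop = world.total_population()
    exp_w = sum(agricultural_expenditure(c) * c.population()
                for c in world.countries) / pop
    warming = WARMING_HOOK(world) if WARMING_HOOK is not None else None
    return {
        "underweight": sum(demand.count_underweight(c) for c in world.countries) / 1e6,
        "obesity": sum(demand.count_obese(c) for c in world.countries) / 1e6,
        "premature_mortality": mort / 1e6,
        "bii_cropland": aggregate_bii(world, "cropland_landscape"),
        "bii_hotspot": aggregate_bii(world, "hotspot_landscape"),
        "crop_diversity": crop_diversity_global(world),
        "nitrogen_surplus": world_nitrogen_surplus(world),
        "efr_violations": efr_violations(world),
        "ghg_emissions": co2e_total(world_emissions(world)),
        "global_surface_warming": warming,
        "ag_expenditure": exp_w,
        "poverty": sum(poverty.poverty_headcount(c.income) for c in world.countries) / 1e6,
        "ag_labour": sum(labour_demand(c) for c in world.countries) / 1e6,
        "ag_wages": wage_index(world, base_wages) if base_wages else 1.0,
        "bioeconomy_supply": bioeconomy_supply(world),
        "factor_use": factor_use(world),
    }
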