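"""The measure engine: 23 food-system measures plus 5 cross-sector settings.

Each measure is a deterministic, phase-in-aware transform of a
:class:`~fstkit.world.WorldState`. Measures phase in linearly from 2020 to
their target year (2030 for land conservation, 2050 otherwise). Within a
package, members apply in a fixed canonical order: cross-sector driver swaps,
then intake-level shifts, then composition caps, then floors, then the waste
cap, then wage/capital/trade settings, then land, water, nutrient and
emission transforms. Caps are applied before floors so floors cannot be
undone by a later cap.

Phase-in semantics keep every cap/floor transform idempotent at fixed year:
the *parameter* is interpolated (a floor rises as ``f * floor``, a cap relaxes
as ``cap / f``), never the state, so applying a measure twice at the same year
changes nothing the second time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .config import ALL_MEASURE_NAMES, MEASURE_DEFAULTS, PACKAGES
from .errors import MeasureInfeasibleError, UnknownMeasureError, ValidationError
from .world import (CellState, CohortIntakeTable, CountryState, DietProfile,
                    WorldState)


@dataclass
class MeasureSpec:
    """One measure with its parameter overrides and phase-in window."""

    name: str
    params: dict = field(default_factory=dict)
    start_year: int = 2020

    def __post_init__(self) -> None:
        if self.name not in ALL_MEASURE_NAMES:
            raise UnknownMeasureError(
                f"unknown measure {self.name!r}; valid names: "
                + ", ".join(ALL_MEASURE_NAMES))
        merged = dict(MEASURE_DEFAULTS[self.name])
        merged.update(self.params)
        self.params = merged

    @property
    def full_year(self) -> int:
        return int(self.params["full_year"])


@dataclass
class PackageSpec:
    name: str
    members: list[MeasureSpec]

    @classmethod
    def from_name(cls, name: str, overrides: dict[str, dict] | None = None) -> "PackageSpec":
        if name not in PACKAGES:
            raise UnknownMeasureError(
                f"unknown package {name!r}; valid names: " + ", ".join(PACKAGES))
        overrides = overrides or {}
        return cls(name, [MeasureSpec(m, overrides.get(m, {})) for m in PACKAGES[name]])


# canonical application order within a package
MEASURE_ORDER: tuple[str, ...] = (
    "Population", "HumanDevelop", "EnergyTrans", "Bioplastics", "TimberCities",
    "NoUnderweight", "HalfOverweight",
    "LowRuminants", "LowMonogastrics", "LowProcessed",
    "HighLegumes", "HighVegFruitsNuts",
    "LowFoodWaste",
    "MinWage", "CapitalSubst", "LibTrade",
    "REDD+", "LandConservation", "PeatlandRewetting", "WaterConservation",
    "BiodivOffset",
    "NitrogenEff", "CropRotations", "LandscapeHabitats", "RiceMitigation",
    "LivestockManagement", "ManureManagement", "SoilCarbon",
)


def phase_in_factor(measure: MeasureSpec, year: int) -> float:
    """Linear phase-in: 0 at start_year, 1 at full_year, clamped outside."""
    span = measure.full_year - measure.start_year
    if span <= 0:
        return 1.0 if year >= measure.full_year else 0.0
    return float(np.clip((year - measure.start_year) / span, 0.0, 1.0))


# ------------------------------------------------------------ diet surgery
def apply_cap_with_staple_compensation(diet: DietProfile, items, cap_kcal: float,
                                       f: float = 1.0) -> DietProfile:
    """Cap a (group of) item(s), staples absorbing the cut.

    Total intake is conserved exactly. During phase-in the cap relaxes to
    ``cap / f``. Sub-items scale proportionally to meet a group cap.
    """
    if cap_kcal < 0:
        raise ValidationError("cap must be non-negative")
    if f <= 0:
        return diet.copy()
    items = (items,) if isinstance(items, str) else tuple(items)
    eff_cap = cap_kcal / f
    out = diet.copy()
    group = out.items_total(items)
    if group <= eff_cap:
        return out
    scale = eff_cap / group if group > 0 else 0.0
    for it in items:
        out.intake[it] *= scale
    out.intake[C.STAPLE_ITEM] += group - eff_cap
    return out


def apply_floor_with_staple_compensation(diet: DietProfile, items, floor_kcal: float,
                                         f: float = 1.0) -> DietProfile:
    """Raise a (group of) item(s) to a floor, reducing staples to compensate.

    Raises :class:`MeasureInfeasibleError` if staples would go negative.
    The floor phases in as ``f * floor``.
    """
    if floor_kcal < 0:
        raise ValidationError("floor must be non-negative")
    items = (items,) if isinstance(items, str) else tuple(items)
    eff_floor = floor_kcal * f
    out = diet.copy()
    group = out.items_total(items)
    if group >= eff_floor:
        return out
    deficit = eff_floor - group
    if out.intake[C.STAPLE_ITEM] - deficit < -1e-9:
        raise MeasureInfeasibleError(
            f"raising {items} to {eff_floor:.0f} kcal drives staples negative")
    if group > 0:
        scale = eff_floor / group
        for it in items:
            out.intake[it] *= scale
    else:
        out.intake[items[0]] = eff_floor
    out.intake[C.STAPLE_ITEM] -= deficit
    return out


def converge_item(diet: DietProfile, item: str, target: float,
                  f: float = 1.0) -> DietProfile:
    """Move an item toward a target level (both directions), staples balancing.

    Acts as a phased cap (``target / f``) from above and a phased floor
    (``target * f``) from below, so it is idempotent at fixed phase-in and
    exact at full phase-in.
    """
    if f <= 0:
        return diet.copy()
    x = diet.intake[item]
    if x > target / f:
        return apply_cap_with_staple_compensation(diet, item, target, f)
    if x < target * f:
        return apply_floor_with_staple_compensation(diet, item, target, f)
    return diet.copy()


def cap_waste(diet: DietProfile, max_waste_share: float, f: float = 1.0) -> DietProfile:
    """Cap household-and-retail waste at a share of intake; intake untouched.

    At full phase-in the waste ratio becomes ``min(ratio, 1 + share)``.
    """
    if max_waste_share < 0:
        raise ValidationError("waste share must be non-negative")
    out = diet.copy()
    if f <= 0:
        return out
    eff = 1.0 + max_waste_share / f
    out.waste_ratio = min(out.waste_ratio, eff)
    return out


def shift_bmi_intake(country: CountryState, mode: str,
                     intake_table: CohortIntakeTable | None = None,
                     f: float = 1.0) -> CountryState:
    """Move BMI-class mass to the healthy class, resetting intake to target.

    ``halve_overweight``: at full phase-in, half the mass of the overweight
    and obese classes moves to the healthy class. ``eradicate_underweight``:
    all mass below BMI 20 moves. Relative dietary composition is preserved;
    the per-capita diet is rescaled by the implied change in mean intake.
    """
    if mode not in ("halve_overweight", "eradicate_underweight"):
        raise ValidationError(f"unknown BMI shift mode {mode!r}")
    table = intake_table or country.intake_table
    moved_frac = (0.5 if mode == "halve_overweight" else 1.0) * f
    source_classes = (C.ABOVE_HEALTHY_CLASSES if mode == "halve_overweight"
                      else C.BELOW_HEALTHY_CLASSES)
    out = copy.deepcopy(country)
    healthy_i = C.BMI_CLASSES.index(C.HEALTHY_CLASS)
    old_mean = country.anthropometric_intake()
    for cohort in C.COHORTS:
        key = f"{cohort[0]}|{cohort[1]}"
        shares = np.asarray(out.bmi_distribution[key], dtype=float)
        for cls in source_classes:
            i = C.BMI_CLASSES.index(cls)
            moved = shares[i] * moved_frac
            shares[i] -= moved
            shares[healthy_i] += moved
        total = shares.sum()
        if abs(total - 1.0) > 1e-12:
            shares /= total
        out.bmi_distribution[key] = shares.tolist()
    new_mean = out.anthropometric_intake()
    if old_mean > 0:
        scale = new_mean / old_mean
        for item in out.diet.intake:
            out.diet.intake[item] *= scale
    return out


# --------------------------------------------------------- economy surgery
def apply_min_wage(country: CountryState, floor_final: float, year: int,
                   f: float = 1.0, substitution: float = 0.3,
                   price_passthrough: float = 0.5) -> CountryState:
    """Raise the hourly wage to the phased-in floor.

    Labour costs rise under-proportionally (capital substitutes for labour at
    elasticity ``substitution``), so labour demand falls; the wage premium is
    flagged for distribution-neutral recycling and part of the cost increase
    passes through to food prices.
    """
    out = copy.deepcopy(country)
    floor = f * floor_final
    if out.hourly_wage >= floor:
        return out
    ratio = floor / out.hourly_wage
    old_total = sum(out.factor_costs.values())
    old_labour = out.factor_costs["labour"]
    out.factor_costs["labour"] = old_labour * ratio ** (1.0 - substitution)
    out.hourly_wage = floor
    core = out.factor_costs["labour"] + out.factor_costs["capital"]
    out.labour_share = out.factor_costs["labour"] / core if core > 0 else 0.0
    d_cost = out.factor_costs["labour"] - old_labour
    pop = out.population()
    if pop > 0:
        out.pending_revenue_pc += d_cost / pop
    if old_total > 0:
        out.price_index *= 1.0 + price_passthrough * d_cost / old_total
    return out


def apply_capital_substitution(country: CountryState, target: float = 0.20,
                               gap_closure: float = 0.5, f: float = 1.0,
                               cost_premium: float = 0.05,
                               price_passthrough: float = 0.5) -> CountryState:
    """Substitute capital by labour toward a labour:capital share of 80:20.

    If the capital share exceeds the target, the gap closes by
    ``gap_closure * f``; the reshuffle carries a substitution-cost premium on
    the core factor bill.
    """
    out = copy.deepcopy(country)
    core = out.factor_costs["labour"] + out.factor_costs["capital"]
    if core <= 0:
        return out
    k = out.factor_costs["capital"] / core
    if k <= target:
        return out
    k_new = k - gap_closure * f * (k - target)
    premium = 1.0 + cost_premium * f
    old_total = sum(out.factor_costs.values())
    new_core = core * premium
    out.factor_costs["capital"] = k_new * new_core
    out.factor_costs["labour"] = (1.0 - k_new) * new_core
    out.labour_share = 1.0 - k_new
    d_cost = new_core - core
    if old_total > 0:
        out.price_index *= 1.0 + price_passthrough * d_cost / old_total
    return out


def apply_manure_digesters(r0: float, digester_share: float,
                           digester_recycling: float) -> float:
    """Recycled manure fraction with part of the stream through digesters."""
    if not (0.0 <= r0 <= 1.0):
        raise ValidationError("baseline recycling fraction outside [0, 1]")
    return digester_share * digester_recycling + (1.0 - digester_share) * r0


# ------------------------------------------------------------ land & water
def apply_protection(world: WorldState, target_share: float,
                     baseline_share: float = 0.15, f: float = 1.0) -> WorldState:
    """Expand protected area to the phased-in global share target.

    Priority: unprotected hotspot / intact-forest cells first, then the rest,
    in cell order; the marginal cell is partially protected so the global
    share lands exactly on target. Already-met targets are a no-op.
    """
    out = world.copy()
    target = baseline_share + f * (target_share - baseline_share)
    total = out.total_land_area()
    if total <= 0:
        return out
    current = out.protected_share()
    if current >= target:
        return out
    needed = (target - current) * total
    ranked = sorted(range(len(out.cells)),
                    key=lambda j: (not out.cells[j].hotspot_or_intact, j))
    for j in ranked:
        cell = out.cells[j]
        headroom = cell.total_area() * (1.0 - cell.protected_fraction)
        if headroom <= 0:
            continue
        take = min(headroom, needed)
        cell.protected_fraction += take / cell.total_area()
        cell.protected = cell.protected_fraction > 1e-12
        needed -= take
        if needed <= 1e-9:
            break
    return out


def enforce_efr(cell: CellState, f: float = 1.0) -> CellState:
    """Cap withdrawal so the phased-in environmental flow remains in the river."""
    out = copy.deepcopy(cell)
    limit = max(0.0, out.water_availability - f * out.efr)
    out.water_withdrawal = min(out.water_withdrawal, limit)
    return out


# ------------------------------------------------- per-measure application
def _scale_emissions(world: WorldState, source: str, reduction: float, f: float) -> None:
    for cell in world.cells:
        cell.emissions[source] *= (1.0 - f * reduction)


def _apply_cost_premium(country: CountryState, premium: float, f: float,
                        passthrough: float) -> None:
    core = country.factor_costs["labour"] + country.factor_costs["capital"]
    old_total = sum(country.factor_costs.values())
    scale = 1.0 + premium * f
    country.factor_costs["labour"] *= scale
    country.factor_costs["capital"] *= scale
    if old_total > 0:
        country.price_index *= 1.0 + passthrough * (core * (scale - 1.0)) / old_total


def _apply_revenue_measure(world: WorldState, revenue_pc: float, f: float) -> None:
    """CO2-tax style measure: consumers pay, revenue is recycled neutrally."""
    from .indicators import agricultural_expenditure
    for country in world.countries:
        e = agricultural_expenditure(country)
        if e > 0:
            country.price_index *= 1.0 + f * revenue_pc / e
        country.pending_revenue_pc += f * revenue_pc


def _nitrogen_efficiency(world: WorldState, gain: float, cap: float, f: float) -> None:
    for cell in world.cells:
        nb = cell.n_budget
        inputs = sum(nb.cropland_inputs.values())
        if inputs <= 0:
            continue
        e0 = nb.cropland_withdrawal / inputs
        e1 = min(min(e0 + f * gain, cap) if e0 < cap else e0, 1.0)
        if e1 <= e0:
            continue
        new_inputs = nb.cropland_withdrawal / e1
        cut = inputs - new_inputs
        fert_cut = min(cut, nb.cropland_inputs.get("fertilizer", 0.0))
        nb.cropland_inputs["fertilizer"] = nb.cropland_inputs.get("fertilizer", 0.0) - fert_cut


def _cap_crop_shares(world: WorldState, max_share: float, f: float) -> None:
    """Cap each crop's share of cell cropland, excess parked as fallow."""
    eff = 1.0 - f * (1.0 - max_share)
    for cell in world.cells:
        cropland = cell.cropland_area()
        if cropland <= 0:
            continue
        for crop in C.CROP_CLASSES:
            cap = eff * cropland
            excess = cell.area_by_class[crop] - cap
            if excess > 0:
                cell.area_by_class[crop] -= excess
                cell.area_by_class[C.FALLOW_CLASS] += excess


def _cap_cropland_to_potential(world: WorldState, cap_share: float, f: float) -> None:
    eff = 1.0 - f * (1.0 - cap_share)
    for cell in world.cells:
        cap = eff * cell.potential_cropland
        cropland = cell.cropland_area()
        if cropland <= cap:
            continue
        scale = cap / cropland
        freed = 0.0
        for cls in C.CROPLAND_CLASSES:
            freed += cell.area_by_class[cls] * (1.0 - scale)
            cell.area_by_class[cls] *= scale
        cell.area_by_class["other_natural"] += freed


def _enforce_bii_floor(world: WorldState) -> None:
    """Restore semi-natural land until each biome-region's BII meets its floor."""
    from .indicators import cell_bii
    if not world.bii_floor:
        return
    regions: dict[str, list[int]] = {}
    for j, cell in enumerate(world.cells):
        regions.setdefault(cell.biome_region, []).append(j)
    for region, floor in world.bii_floor.items():
        idx = regions.get(region, [])
        if not idx:
            continue
        wsum = sum(world.cells[j].range_rarity_weight for j in idx)
        current = sum(world.cells[j].range_rarity_weight * cell_bii(world.cells[j])
                      for j in idx) / wsum
        if current >= floor - 1e-12:
            continue
        # marginal BII gain per ha of cropland restored to semi-natural land
        gains, headrooms = [], []
        for j in idx:
            cell = world.cells[j]
            crop = cell.cropland_area()
            area = cell.total_area()
            avg_i = (sum(cell.area_by_class[c] * cell.intactness[c]
                         for c in C.CROPLAND_CLASSES) / crop) if crop > 0 else 0.0
            g = (cell.range_rarity_weight / wsum) * (1.0 - avg_i) / area if area > 0 else 0.0
            gains.append(g)
            headrooms.append(crop)
        capacity = sum(g * h for g, h in zip(gains, headrooms))
        if capacity <= 0:
            continue
        phi = min((floor - current) / capacity, 1.0)
        for j, h in zip(idx, headrooms):
            cell = world.cells[j]
            restore = phi * h
            crop = cell.cropland_area()
            if crop <= 0:
                continue
            for cls in C.CROPLAND_CLASSES:
                cut = cell.area_by_class[cls] * restore / crop
                cell.area_by_class[cls] -= cut
            cell.area_by_class["other_natural"] += restore


def apply_measure(world: WorldState, spec: MeasureSpec, year: int) -> WorldState:
    """Apply one measure at its phase-in for ``year``; returns a new state."""
    f = phase_in_factor(spec, year)
    p = spec.params
    name = spec.name
    out = world.copy()
    if f <= 0.0:
        return out

    if name == "LowFoodWaste":
        for c in out.countries:
            c.diet = cap_waste(c.diet, p["waste_cap"], f)
    elif name == "LowProcessed":
        for c in out.countries:
            d = apply_cap_with_staple_compensation(c.diet, "sugar", p["sugar_cap"], f)
            d = converge_item(d, "oils_fats", p["oils_fats_target"], f)
            alcohol_cap = p["alcohol_cap_share"] * d.total_intake()
            c.diet = apply_cap_with_staple_compensation(d, "alcohol", alcohol_cap, f)
    elif name == "HighLegumes":
        for c in out.countries:
            c.diet = apply_floor_with_staple_compensation(
                c.diet, C.LEGUME_ITEM, p["legumes_floor"], f)
    elif name == "LowMonogastrics":
        for c in out.countries:
            c.diet = apply_cap_with_staple_compensation(
                c.diet, C.MONOGASTRIC_ITEMS, p["cap"], f)
    elif name == "LowRuminants":
        for c in out.countries:
            c.diet = apply_cap_with_staple_compensation(
                c.diet, C.RUMINANT_ITEMS, p["cap"], f)
    elif name == "HighVegFruitsNuts":
        for c in out.countries:
            c.diet = apply_floor_with_staple_compensation(
                c.diet, C.FRUITVEG_ITEM, p["floor"], f)
    elif name == "HalfOverweight":
        out.countries = [shift_bmi_intake(c, "halve_overweight", f=f)
                         for c in out.countries]
    elif name == "NoUnderweight":
        out.countries = [shift_bmi_intake(c, "eradicate_underweight", f=f)
                         for c in out.countries]
    elif name == "MinWage":
        out.countries = [apply_min_wage(c, p["min_wage"], year, f,
                                        price_passthrough=p["price_passthrough"])
                         for c in out.countries]
    elif name == "CapitalSubst":
        out.countries = [apply_capital_substitution(
            c, p["capital_share_target"], p["gap_closure"], f,
            p["cost_premium"], p["price_passthrough"]) for c in out.countries]
    elif name == "LibTrade":
        for pool, target in p["liberal_pool_target"].items():
            cur = out.trade_pools[pool]
            out.trade_pools[pool] = cur + f * (target - cur)
    elif name == "LandConservation":
        out = apply_protection(out, p["protection_target_share"],
                               p["baseline_protected_share"], f)
    elif name == "WaterConservation":
        out.cells = [enforce_efr(cell, f) for cell in out.cells]
    elif name == "BiodivOffset":
        _enforce_bii_floor(out)
    elif name == "REDD+":
        _scale_emissions(out, "co2.luc", p["co2_luc_reduction"], f)
        _apply_revenue_measure(out, p["revenue_pc"], f)
    elif name == "PeatlandRewetting":
        _scale_emissions(out, "co2.peatland", p["co2_peatland_reduction"], f)
        _apply_revenue_measure(out, p["revenue_pc"], f)
    elif name == "SoilCarbon":
        _scale_emissions(out, "co2.soil", p["co2_soil_reduction"], f)
        _apply_revenue_measure(out, p["revenue_pc"], f)
    elif name == "RiceMitigation":
        _scale_emissions(out, "ch4.rice", p["ch4_rice_reduction"], f)
        for c in out.countries:
            _apply_cost_premium(c, p["cost_premium"], f, p["price_passthrough"])
    elif name == "LivestockManagement":
        _scale_emissions(out, "ch4.enteric", p["ch4_enteric_reduction"], f)
        for c in out.countries:
            _apply_cost_premium(c, p["cost_premium"], f, p["price_passthrough"])
    elif name == "ManureManagement":
        share = f * p["digester_share"]
        for cell in out.cells:
            nb = cell.n_budget
            if nb.awms_excretion > 0:
                r0 = nb.awms_recycled / nb.awms_excretion
                r1 = apply_manure_digesters(min(r0, 1.0), share,
                                            p["digester_recycling"])
                nb.awms_recycled = max(r1, r0) * nb.awms_excretion
        _scale_emissions(out, "ch4.awms", p["ch4_awms_reduction"], f)
        for c in out.countries:
            _apply_cost_premium(c, p["cost_premium"], f, p["price_passthrough"])
    elif name == "NitrogenEff":
        _nitrogen_efficiency(out, p["uptake_gain"], p["uptake_cap"], f)
        for c in out.countries:
            _apply_cost_premium(c, p["cost_premium"], f, p["price_passthrough"])
    elif name == "CropRotations":
        _cap_crop_shares(out, p["max_crop_share"], f)
        _apply_revenue_measure(out, p["revenue_pc"], f)
    elif name == "LandscapeHabitats":
        _cap_cropland_to_potential(out, p["potential_cropland_cap"], f)
    elif name == "Population":
        scale = 1.0 + f * (p["pop_scale_2050"] - 1.0)
        for c in out.countries:
            for k in c.population_by_cohort:
                c.population_by_cohort[k] *= scale
            c.income.population *= scale
    elif name == "HumanDevelop":
        from .demand import project_diet_composition
        for c in out.countries:
            c.income.mean_income *= 1.0 + f * p["extra_income_growth"]
            c.income.gini *= 1.0 - f * p["gini_reduction"]
            c.income_pc_usd *= 1.0 + f * p["extra_income_growth"]
            c.hourly_wage *= 1.0 + f * p["labour_productivity_gain"]
            # higher physical activity raises energy requirements
            boost = 1.0 + f * p["activity_intake_shift"]
            for item in c.diet.intake:
                c.diet.intake[item] *= boost
            for row in c.intake_table.recommended.values():
                for cls in row:
                    row[cls] *= boost
        _nitrogen_efficiency(out, p["uptake_gain"], p["uptake_cap"], f)
    elif name == "EnergyTrans":
        for cell in out.cells:
            cell.water_withdrawal *= 1.0 - f * p["nonag_withdrawal_reduction"]
        for c in out.countries:
            c.bioeconomy_quantities["bioenergy"] *= 1.0 + f * p["bioenergy_boost"]
    elif name == "Bioplastics":
        for c in out.countries:
            c.bioeconomy_quantities["bioplastics"] *= 1.0 + f * p["bioplastics_boost"]
    elif name == "TimberCities":
        for c in out.countries:
            c.bioeconomy_quantities["timber"] *= 1.0 + f * p["timber_boost"]
    else:  # pragma: no cover - names are validated in MeasureSpec
        raise UnknownMeasureError(name)
    return out


# measures acting on land, water, nutrients and emissions: the demand
# pass-through runs before these so that e.g. a later environmental-flow
# constraint binds on the post-diet-change withdrawals
LAND_MEASURES: frozenset[str] = frozenset({
    "REDD+", "LandConservation", "PeatlandRewetting", "WaterConservation",
    "BiodivOffset", "NitrogenEff", "CropRotations", "LandscapeHabitats",
    "RiceMitigation", "LivestockManagement", "ManureManagement", "SoilCarbon",
})

# pass-through intensities: how strongly cell-level pressures follow demand
DEMAND_PASSTHROUGH = {
    "feed_cropland_share": 0.3,     # share of cropland pressure driven by feed
    "irrigation_share": 0.5,        # share of withdrawals that follow cropping
    "labour_livestock_share": 0.5,  # share of factor costs tied to livestock
}


def _aggregate_supply(world: WorldState) -> dict[int, tuple[float, float]]:
    """(animal, plant) aggregate calorie supply per country (kcal/day x pop)."""
    out = {}
    for i, c in enumerate(world.countries):
        pop = c.population()
        wr = c.diet.waste_ratio
        animal = c.diet.items_total(C.ANIMAL_ITEMS) * wr * pop
        plant = (c.diet.total_intake() - c.diet.items_total(C.ANIMAL_ITEMS)) * wr * pop
        out[i] = (animal, plant)
    return out


def demand_passthrough(world: WorldState,
                       base_supply: dict[int, tuple[float, float]]) -> None:
    """Scale cell pressures and factor costs with the change in food demand.

    A configured pass-through standing in for the land-use response: livestock
    pressures (enteric/manure methane, excretion) follow animal-calorie
    supply; cropping pressures (fertiliser, harvest, soil gases, land-use-
    change CO2, irrigation) follow plant-calorie supply plus a feed share of
    the animal change; factor costs follow a livestock/cropping blend.
    """
    p = DEMAND_PASSTHROUGH
    new_supply = _aggregate_supply(world)
    ratios = {}
    for i, (a0, v0) in base_supply.items():
        a1, v1 = new_supply[i]
        r_animal = a1 / a0 if a0 > 0 else 1.0
        r_plant = v1 / v0 if v0 > 0 else 1.0
        r_crop = ((1.0 - p["feed_cropland_share"]) * r_plant
                  + p["feed_cropland_share"] * r_animal)
        ratios[i] = (r_animal, r_crop)
    for cell in world.cells:
        r_animal, r_crop = ratios[cell.country]
        for key in ("ch4.enteric", "ch4.awms", "n2o.awms"):
            cell.emissions[key] *= r_animal
        for key in ("ch4.rice", "n2o.soil", "co2.luc", "co2.soil"):
            cell.emissions[key] *= r_crop
        nb = cell.n_budget
        for k in nb.cropland_inputs:
            nb.cropland_inputs[k] *= r_crop
        nb.cropland_withdrawal *= r_crop
        nb.awms_excretion *= r_animal
        nb.awms_recycled *= r_animal
        cell.water_withdrawal *= (1.0 - p["irrigation_share"]
                                  + p["irrigation_share"] * r_crop)
    for i, c in enumerate(world.countries):
        r_animal, r_crop = ratios[i]
        r_prod = (p["labour_livestock_share"] * r_animal
                  + (1.0 - p["labour_livestock_share"]) * r_crop)
        for k in c.factor_costs:
            c.factor_costs[k] *= r_prod


def apply_package(world: WorldState, package: PackageSpec, year: int) -> WorldState:
    """Apply a package's members in the canonical order.

    Between the demand/economy measures and the land/water/nutrient measures
    the demand pass-through rescales cell-level pressures to the changed food
    demand, so environmental constraints bind on post-diet-change pressures.
    """
    order = {name: i for i, name in enumerate(MEASURE_ORDER)}
    members = sorted(package.members, key=lambda m: order[m.name])
    base_supply = _aggregate_supply(world)
    out = world
    passthrough_done = False
    for spec in members:
        if spec.name in LAND_MEASURES and not passthrough_done:
            out = out.copy()
            demand_passthrough(out, base_supply)
            passthrough_done = True
        try:
            out = apply_measure(out, spec, year)
        except MeasureInfeasibleError as err:
            raise MeasureInfeasibleError(f"{spec.name}: {err}") from err
    if not passthrough_done:
        out = out.copy()
        demand_passthrough(out, base_supply)
    return out
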