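"""Seeded synthetic world generator.

Generates :class:`~fstkit.world.WorldState` fixtures with the statistical
structure the downstream stages assume: country demography with five BMI
classes, diets consistent with the demand regressions at each country's
income, a lognormal income distribution, abstract grid cells carrying land,
water, nitrogen and emission accounts, a relative-risk table and a standard
life table. Per-country random streams are derived from (seed, country index),
so the first k countries are identical regardless of ``n_countries``.
"""

from __future__ import annotations

import numpy as np

from . import constants as C
from .config import SynthConfig
from .world import (CellState, CohortIntakeTable, CountryState, DietProfile,
                    IncomeDistribution, LifeTable, NitrogenBudget, RiskModel,
                    WorldState, _cohort_key)
from . import demand

# GBD-style standard remaining life expectancy at the mid-point of each age
# group (years); strictly decreasing by construction.
_STANDARD_LIFE_TABLE = {
    "0-14": 81.2, "15-29": 66.8, "30-44": 52.2,
    "45-59": 37.8, "60-74": 23.8, "75+": 10.8,
}

_AGE_INTAKE_MULT = {"0-14": 0.75, "15-29": 1.05, "30-44": 1.00,
                    "45-59": 0.95, "60-74": 0.85, "75+": 0.75}
_SEX_INTAKE_MULT = {"F": 0.90, "M": 1.10}
_CLASS_INTAKE_MULT = {"underweight": 0.80, "below_healthy": 0.92,
                      "healthy": 1.00, "overweight": 1.15, "obese": 1.30}

_ENDPOINT_BASE_RATE = {"chd": 0.0020, "stroke": 0.0015, "t2dm": 0.0008,
                       "cancer": 0.0020, "respiratory": 0.0010}
_AGE_RATE_MULT = {"0-14": 0.0, "15-29": 0.05, "30-44": 0.2,
                  "45-59": 1.0, "60-74": 4.0, "75+": 12.0}
_AGE_RR_ATTENUATION = {"15-29": 1.0, "30-44": 0.95, "45-59": 0.85,
                       "60-74": 0.72, "75+": 0.60}

# kcal/day exposure-category breakpoints; category 0 is the TMREL side
_CATEGORY_BREAKS = {
    "red_meat_high": [50.0, 150.0, 300.0],     # harmful when high
    "fruits_low": [126.0, 80.0, 40.0],         # harmful when low (descending)
    "vegetables_low": [78.0, 50.0, 25.0],
    "nuts_low": [100.0, 60.0, 30.0],
    "legumes_low": [200.0, 120.0, 60.0],
}
_DIRECTION = {"red_meat_high": "high", "fruits_low": "low",
              "vegetables_low": "low", "nuts_low": "low", "legumes_low": "low"}
_TMREL = {"red_meat_high": 25.0, "fruits_low": 150.0, "vegetables_low": 100.0,
          "nuts_low": 120.0, "legumes_low": 250.0,
          "underweight": 0.0, "overweight": 0.0, "obese": 0.0}


def generate_life_table(config: SynthConfig | None = None) -> LifeTable:
    """Standard abridged life table (deterministic)."""
    return LifeTable(dict(_STANDARD_LIFE_TABLE))


def generate_risk_model(config: SynthConfig) -> RiskModel:
    """Relative-risk table: RR = 1 at the TMREL, monotone in exposure.

    Category RRs interpolate log-linearly from 1 to a drawn maximum; the
    excess risk attenuates with age, as relative risks for chronic disease
    typically do.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 999])
    lo, hi = config.rr_magnitude_range
    n_cat = C.N_EXPOSURE_CATEGORIES
    rr: dict[str, dict[str, np.ndarray]] = {}
    for factor in C.RISK_FACTORS:
        rr[factor] = {}
        for endpoint in C.ENDPOINTS:
            top = rng.uniform(lo, hi)
            cats = top ** (np.arange(n_cat) / (n_cat - 1))  # 1 ... top
            arr = np.empty((len(C.ADULT_AGE_GROUPS), len(C.SEXES), n_cat))
            for ia, age in enumerate(C.ADULT_AGE_GROUPS):
                att = _AGE_RR_ATTENUATION[age]
                arr[ia, :, :] = 1.0 + (cats - 1.0) * att
            rr[factor][endpoint] = arr
    return RiskModel(rr=rr,
                     category_breaks={k: list(v) for k, v in _CATEGORY_BREAKS.items()},
                     direction=dict(_DIRECTION), tmrel=dict(_TMREL))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def _generate_country(config: SynthConfig, index: int) -> CountryState:
    rng = np.random.default_rng([config.seed, 1000 + index])
    lo, hi = config.income_range
    income_pc = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    log_inc = np.log10(income_pc)
    gini = float(rng.uniform(*config.gini_range))

    total_pop = float(10 ** rng.uniform(6.5, 8.3))
    # age pyramid tilts older with income
    base_age = np.array([0.27, 0.23, 0.20, 0.14, 0.11, 0.05])
    tilt = np.array([-1.0, -0.4, 0.0, 0.3, 0.6, 0.9]) * 0.04 * (log_inc - 3.5)
    age_shares = _softmax(np.log(base_age) + tilt + rng.normal(0, 0.02, 6))
    pop_by_cohort: dict[str, float] = {}
    for ia, age in enumerate(C.AGE_GROUPS):
        f_share = float(rng.uniform(0.49, 0.51))
        pop_by_cohort[_cohort_key((age, "F"))] = total_pop * age_shares[ia] * f_share
        pop_by_cohort[_cohort_key((age, "M"))] = total_pop * age_shares[ia] * (1 - f_share)

    # BMI distribution: nutrition transition — richer countries carry more
    # mass in the overweight/obese classes, poorer ones below the threshold
    base_logits = np.array([-2.0, -1.8, 0.9, -0.5, -1.4])
    income_tilt = np.array([-1.2, -0.9, 0.0, 0.55, 0.75]) * (log_inc - 3.6)
    bmi_dist: dict[str, list[float]] = {}
    for age in C.AGE_GROUPS:
        for sex in C.SEXES:
            noise = rng.normal(0, 0.08, 5)
            shares = _softmax(base_logits + income_tilt + noise)
            shares = shares / shares.sum()
            bmi_dist[_cohort_key((age, sex))] = shares.tolist()

    # recommended intake per cohort and BMI class
    base_req = float(rng.uniform(2050, 2150))
    recommended: dict[str, dict[str, float]] = {}
    for age in C.AGE_GROUPS:
        for sex in C.SEXES:
            row = {cls: base_req * _AGE_INTAKE_MULT[age] * _SEX_INTAKE_MULT[sex]
                   * _CLASS_INTAKE_MULT[cls] for cls in C.BMI_CLASSES}
            recommended[_cohort_key((age, sex))] = row
    intake_table = CohortIntakeTable(recommended)

    # diet from the demand regressions at this income
    within = {
        "animal_source": dict(zip(C.ANIMAL_ITEMS,
                                  rng.dirichlet([4.0, 8.0, 3.0, 3.0, 2.0]))),
        "empty_calories": dict(zip(C.EMPTY_CALORIE_ITEMS,
                                   rng.dirichlet([9.0, 9.0, 2.0]))),
        "staples": dict(zip((C.STAPLE_ITEM, C.LEGUME_ITEM),
                            rng.dirichlet([18.0, 2.0]))),
        "fruits_veg_nuts": {C.FRUITVEG_ITEM: 1.0},
    }
    stub = CountryState(
        name=f"C{index:03d}", population_by_cohort=pop_by_cohort,
        bmi_distribution=bmi_dist,
        diet=DietProfile({i: 0.0 for i in C.DIET_ITEMS}, 1.0),
        income=IncomeDistribution(1.0, 0.3, total_pop),
        intake_table=intake_table, hourly_wage=1.0, factor_costs={},
        labour_share=0.5, working_hours=2000.0, shadow_prices={},
        mortality_rates={}, bioeconomy_quantities={}, prices_2010={},
        population_2010=total_pop)
    total_intake = stub.anthropometric_intake()
    diet = demand.build_diet(income_pc, total_intake,
                             config.diet_regression_coeffs,
                             config.waste_regression_coeffs, within)

    wage = max(0.3, income_pc / 2000.0 * 0.45 * float(rng.uniform(0.8, 1.2)))
    ag_share = float(np.clip(0.25 * (income_pc / 1000.0) ** -0.3, 0.02, 0.30))
    total_cost = total_pop * income_pc * ag_share
    labour_share = float(np.clip(0.80 - 0.12 * (log_inc - 3.0)
                                 + rng.normal(0, 0.04), 0.30, 0.85))
    core = 0.8 * total_cost
    factor_costs = {"labour": labour_share * core,
                    "capital": (1.0 - labour_share) * core,
                    "intermediates": 0.2 * total_cost}

    shadow_prices = {item: float(rng.uniform(0.3, 2.0)) for item in C.DIET_ITEMS}
    mortality = {}
    for e in C.ENDPOINTS:
        for age in C.AGE_GROUPS:
            for sex in C.SEXES:
                rate = (_ENDPOINT_BASE_RATE[e] * _AGE_RATE_MULT[age]
                        * float(rng.uniform(0.8, 1.2)))
                mortality[f"{e}|{age}|{sex}"] = rate

    bio_q = {p: total_pop * float(rng.uniform(0.02, 0.2)) for p in C.BIOECONOMY_PRODUCTS}
    prices_2010 = {p: float(rng.uniform(50, 400)) for p in C.BIOECONOMY_PRODUCTS}

    income_growth = float(np.clip(0.055 - 0.012 * (log_inc - 3.0)
                                  + rng.normal(0, 0.004), 0.005, 0.05))
    pop_growth = float(np.clip(0.024 - 0.006 * (log_inc - 3.0)
                               + rng.normal(0, 0.002), 0.0, 0.025))

    return CountryState(
        name=f"C{index:03d}",
        population_by_cohort=pop_by_cohort,
        bmi_distribution=bmi_dist,
        diet=diet,
        income=IncomeDistribution(
            mean_income=income_pc * config.ppp_per_usd_day * float(rng.uniform(1.2, 2.2)),
            gini=gini, population=total_pop,
            food_share=float(np.clip(0.55 - 0.1 * (log_inc - 3.0), 0.10, 0.60))),
        intake_table=intake_table,
        hourly_wage=wage,
        factor_costs=factor_costs,
        labour_share=labour_share,
        working_hours=float(rng.uniform(1800, 2400)),
        shadow_prices=shadow_prices,
        mortality_rates=mortality,
        bioeconomy_quantities=bio_q,
        prices_2010=prices_2010,
        population_2010=total_pop * float(rng.uniform(0.82, 0.95)),
        income_pc_usd=income_pc,
        income_growth=income_growth,
        pop_growth=pop_growth,
        wage_growth=income_growth * float(rng.uniform(0.85, 1.1)),
        gini_drift=float(rng.uniform(-0.0008, 0.0008)),
        cost_growth=pop_growth + 0.4 * income_growth,
    )


def _generate_cells(config: SynthConfig, index: int) -> list[CellState]:
    rng = np.random.default_rng([config.seed, 5000 + index])
    n = config.n_cells_per_country
    alpha = np.array([0.5] * len(C.CROP_CLASSES) + [0.3]      # fallow
                     + [2.0]                                   # pasture
                     + [2.5, 0.8, 2.0]                         # natural classes
                     + [0.2])                                  # built-up
    cells = []
    for _ in range(n):
        area = float(10 ** rng.uniform(5.3, 6.2))
        shares = rng.dirichlet(alpha)
        area_by_class = {cls: area * float(s)
                         for cls, s in zip(C.LAND_CLASSES, shares)}
        cropland = sum(area_by_class[c] for c in C.CROPLAND_CLASSES)
        potential = cropland / float(rng.uniform(0.55, 0.95))
        avail = float(10 ** rng.uniform(-1.5, 0.8))
        efr = avail * float(rng.uniform(0.2, 0.45))
        withdrawal = float(rng.uniform(0.0, 1.15)) * max(avail - efr, 0.0)

        crop_ha = cropland
        past_ha = area_by_class["pasture"]
        nat_ha = sum(area_by_class[c] for c in C.NATURAL_CLASSES)
        kg_to_mt = 1e-9
        fert = crop_ha * float(rng.uniform(40, 120)) * kg_to_mt
        manure_in = crop_ha * float(rng.uniform(10, 40)) * kg_to_mt
        fixation = crop_ha * float(rng.uniform(5, 20)) * kg_to_mt
        deposition = crop_ha * float(rng.uniform(3, 10)) * kg_to_mt
        seed = crop_ha * float(rng.uniform(1, 3)) * kg_to_mt
        inputs_total = fert + manure_in + fixation + deposition + seed
        withdraw_n = inputs_total * float(rng.uniform(0.45, 0.70))
        p_in = past_ha * float(rng.uniform(5, 25)) * kg_to_mt
        p_out = p_in * float(rng.uniform(0.5, 0.9))
        excretion = past_ha * float(rng.uniform(8, 30)) * kg_to_mt
        recycled = excretion * float(rng.uniform(0.40, 0.70))
        nat_fix = nat_ha * float(rng.uniform(3, 8)) * kg_to_mt

        emis = {
            "co2.luc": (crop_ha + past_ha) * float(rng.uniform(0.1, 0.6)) * 1e-6,
            "co2.peatland": area * float(rng.uniform(0.0, 0.05)) * 1e-6,
            "co2.soil": crop_ha * float(rng.uniform(0.02, 0.15)) * 1e-6,
            "ch4.enteric": past_ha * float(rng.uniform(0.01, 0.06)) * 1e-6,
            "ch4.rice": area_by_class["rice"] * float(rng.uniform(0.05, 0.2)) * 1e-6,
            "ch4.awms": excretion * float(rng.uniform(2.0, 6.0)),
            "n2o.soil": (fert + manure_in) * float(rng.uniform(0.01, 0.02)),
            "n2o.awms": excretion * float(rng.uniform(0.005, 0.02)),
        }

        cells.append(CellState(
            country=index,
            area_by_class=area_by_class,
            potential_cropland=potential,
            protected=False,
            hotspot_or_intact=bool(rng.uniform() < 0.35),
            biome_region=f"r{index % 3}_b{int(rng.integers(0, 3))}",
            range_rarity_weight=float(np.exp(rng.normal(0.0, 0.3))),
            intactness=dict(C.DEFAULT_INTACTNESS),
            water_availability=avail,
            water_withdrawal=withdrawal,
            efr=efr,
            n_budget=NitrogenBudget(
                cropland_inputs={"fertilizer": fert, "manure": manure_in,
                                 "fixation": fixation, "deposition": deposition,
                                 "seed_organic": seed},
                cropland_withdrawal=withdraw_n,
                pasture_inputs={"deposition": p_in},
                pasture_withdrawal=p_out,
                awms_excretion=excretion,
                awms_recycled=recycled,
                natural_fixation=nat_fix,
            ),
            emissions=emis,
        ))
    if not any(c.hotspot_or_intact for c in cells):
        cells[0].hotspot_or_intact = True  # hotspot selector must be non-empty
    # baseline protection: exactly 15% of this country's land area, drawn in
    # random order (the marginal cell is partially covered)
    order = rng.permutation(n)
    country_area = sum(c.total_area() for c in cells)
    target = 0.15 * country_area
    acc = 0.0
    for j in order:
        cell = cells[int(j)]
        a = cell.total_area()
        if acc + a <= target:
            cell.protected = True
            cell.protected_fraction = 1.0
            acc += a
        else:
            frac = (target - acc) / a
            if frac > 1e-12:
                cell.protected = True
                cell.protected_fraction = frac
            break
    return cells


def generate_world(config: SynthConfig) -> WorldState:
    """Generate a complete, validated world state for ``config.year0``."""
    config.validate()
    countries = [_generate_country(config, i) for i in range(config.n_countries)]
    cells: list[CellState] = []
    for i in range(config.n_countries):
        cells.extend(_generate_cells(config, i))
    world = WorldState(
        year=config.year0,
        countries=countries,
        cells=cells,
        gwp_table=dict(C.DEFAULT_GWP100),
        life_table=generate_life_table(config),
        risk_model=generate_risk_model(config),
    )
    world.validate()
    return world
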