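"""World-state containers.

A :class:`WorldState` is a full synthetic scenario state for one year:
demography, diets, incomes, wages, grid cells with land/water/nitrogen/emission
accounts, plus the relative-risk table and life table used by the health layer.
Everything is a plain dataclass and round-trips through a single JSON document
(:meth:`WorldState.to_json` / :meth:`WorldState.from_json`) so that fixture
states can be stored and compared byte-for-byte.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import constants as C
from .errors import ValidationError

Cohort = tuple[str, str]  # (age group, sex)


def _cohort_key(cohort: Cohort) -> str:
    return f"{cohort[0]}|{cohort[1]}"


def _parse_cohort(key: str) -> Cohort:
    age, sex = key.split("|")
    return age, sex


# --------------------------------------------------------------------- diet
@dataclass
class DietProfile:
    """Per-capita daily calorie intake by food item plus the waste ratio.

    ``waste_ratio`` is food calorie supply per calorie of intake (>= 1); the
    difference between supply and intake is household and retail food waste.
    """

    intake: dict[str, float]
    waste_ratio: float = 1.0

    def __post_init__(self) -> None:
        for item in C.DIET_ITEMS:
            self.intake.setdefault(item, 0.0)

    def total_intake(self) -> float:
        return float(sum(self.intake.values()))

    def group_intake(self, group: str) -> float:
        return float(sum(self.intake[i] for i in C.GROUP_ITEMS[group]))

    def items_total(self, items) -> float:
        return float(sum(self.intake[i] for i in items))

    def supply(self) -> float:
        """Total calorie supply per capita per day (intake times waste ratio)."""
        return self.total_intake() * self.waste_ratio

    def validate(self) -> None:
        if self.waste_ratio < 1.0 - 1e-12:
            raise ValidationError(f"waste_ratio {self.waste_ratio} < 1")
        for k, v in self.intake.items():
            if v < -1e-9:
                raise ValidationError(f"negative intake for {k}: {v}")

    def copy(self) -> "DietProfile":
        return DietProfile(dict(self.intake), self.waste_ratio)


@dataclass
class CohortIntakeTable:
    """Recommended kcal/day by cohort and BMI class.

    ``recommended[cohort_key][bmi_class]`` holds the class-specific intake;
    the entry for the healthy class doubles as the healthy target used when a
    measure moves people between BMI classes.
    """

    recommended: dict[str, dict[str, float]]

    def intake(self, cohort: Cohort, bmi_class: str) -> float:
        return self.recommended[_cohort_key(cohort)][bmi_class]

    def healthy_target(self, cohort: Cohort) -> float:
        return self.recommended[_cohort_key(cohort)][C.HEALTHY_CLASS]


# ------------------------------------------------------------------- income
@dataclass
class IncomeDistribution:
    """Country income as a lognormal: mean (Int$2011PPP/cap/day) and Gini."""

    mean_income: float
    gini: float
    population: float
    poverty_line: float = 3.20
    food_share: float = 0.30  # mean food-expenditure share of income

    def validate(self) -> None:
        if self.mean_income <= 0:
            raise ValidationError("mean_income must be > 0")
        if not (0.0 <= self.gini < 1.0):
            raise ValidationError(f"gini {self.gini} outside [0, 1)")

    def copy(self) -> "IncomeDistribution":
        return IncomeDistribution(self.mean_income, self.gini, self.population,
                                  self.poverty_line, self.food_share)


# ------------------------------------------------------------------- health
@dataclass
class LifeTable:
    """Standard remaining life expectancy e*_a by age group (years)."""

    remaining: dict[str, float]

    def validate(self) -> None:
        vals = [self.remaining[a] for a in C.AGE_GROUPS]
        if any(v < 0 for v in vals):
            raise ValidationError("life table has negative entries")
        for a, b in zip(vals, vals[1:]):
            if b >= a:
                raise ValidationError("remaining life expectancy must decrease with age")


@dataclass
class RiskModel:
    """Relative-risk table for the comparative risk assessment.

    ``rr[factor][endpoint]`` is an array of shape
    (n adult age groups, n sexes, n categories) with category 0 the TMREL
    (rr exactly 1) and rr non-decreasing in category for harmful exposure.
    ``category_breaks[factor]`` are kcal/day breakpoints mapping a dietary
    intake to a category; ``direction[factor]`` is ``high`` when high intake is
    harmful and ``low`` when low intake is.
    """

    rr: dict[str, dict[str, np.ndarray]]
    category_breaks: dict[str, list[float]]
    direction: dict[str, str]
    tmrel: dict[str, float]
    colorectal_share_of_cancer: float = 0.35

    def validate(self) -> None:
        for f in C.RISK_FACTORS:
            for e in C.ENDPOINTS:
                arr = self.rr[f][e]
                if arr.shape != (len(C.ADULT_AGE_GROUPS), len(C.SEXES), C.N_EXPOSURE_CATEGORIES):
                    raise ValidationError(f"rr[{f}][{e}] has shape {arr.shape}")
                if not np.allclose(arr[..., 0], 1.0):
                    raise ValidationError(f"rr[{f}][{e}] != 1 at TMREL")
                if np.any(arr < 0):
                    raise ValidationError("negative relative risk")
                if np.any(np.diff(arr, axis=-1) < -1e-12):
                    raise ValidationError(f"rr[{f}][{e}] not monotone in exposure")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in C.RISK_FACTORS:
            for e in C.ENDPOINTS:
                for ia, a in enumerate(C.ADULT_AGE_GROUPS):
                    for isx, s in enumerate(C.SEXES):
                        for cat in range(C.N_EXPOSURE_CATEGORIES):
                            rows.append((f, e, a, s, cat, float(self.rr[f][e][ia, isx, cat])))
        return pd.DataFrame(rows, columns=["factor", "endpoint", "age", "sex", "category", "rr"])


# ----------------------------------------------------------------- nitrogen
@dataclass
class NitrogenBudget:
    """Per-cell nitrogen budget terms (Mt N / yr).

    Cropland and pasture surpluses are inputs minus withdrawals; the animal
    waste management (AWMS) surplus is excretion minus recycled manure; natural
    vegetation is assumed in steady state (fixation equals surplus).
    """

    cropland_inputs: dict[str, float] = field(default_factory=dict)
    cropland_withdrawal: float = 0.0
    pasture_inputs: dict[str, float] = field(default_factory=dict)
    pasture_withdrawal: float = 0.0
    awms_excretion: float = 0.0
    awms_recycled: float = 0.0
    natural_fixation: float = 0.0

    def validate(self) -> None:
        for d in (self.cropland_inputs, self.pasture_inputs):
            for k, v in d.items():
                if v < 0:
                    raise ValidationError(f"negative nitrogen input {k}")
        for v in (self.cropland_withdrawal, self.pasture_withdrawal,
                  self.awms_excretion, self.awms_recycled, self.natural_fixation):
            if v < 0:
                raise ValidationError("negative nitrogen term")


# --------------------------------------------------------------------- cell
@dataclass
class CellState:
    """One abstract grid cell: land areas (ha), water (km3/yr), N, emissions."""

    country: int
    area_by_class: dict[str, float]
    potential_cropland: float
    protected: bool
    hotspot_or_intact: bool
    biome_region: str
    range_rarity_weight: float
    intactness: dict[str, float]
    water_availability: float
    water_withdrawal: float
    efr: float
    n_budget: NitrogenBudget
    emissions: dict[str, float]  # "gas.source" -> Mt gas / yr
    # share of the cell's area under protection; the boolean flag is True as
    # soon as any of the cell is protected (the marginal cell of an expansion
    # can be partially covered)
    protected_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.protected_fraction is None:
            self.protected_fraction = 1.0 if self.protected else 0.0

    def total_area(self) -> float:
        return float(sum(self.area_by_class.values()))

    def cropland_area(self) -> float:
        return float(sum(self.area_by_class[c] for c in C.CROPLAND_CLASSES))

    def validate(self) -> None:
        for k, v in self.area_by_class.items():
            if v < -1e-9:
                raise ValidationError(f"negative area for class {k}")
        if min(self.water_availability, self.water_withdrawal, self.efr) < 0:
            raise ValidationError("negative water term")
        for cls in ("forest_old", "other_natural"):
            if abs(self.intactness.get(cls, 1.0) - 1.0) > 1e-12:
                raise ValidationError(f"reference class {cls} must have intactness 1")
        self.n_budget.validate()


# ------------------------------------------------------------------ country
@dataclass
class CountryState:
    name: str
    population_by_cohort: dict[str, float]           # "age|sex" -> persons
    bmi_distribution: dict[str, list[float]]         # "age|sex" -> 5 class shares
    diet: DietProfile
    income: IncomeDistribution
    intake_table: CohortIntakeTable
    hourly_wage: float                                # USD_05MER per hour
    factor_costs: dict[str, float]                    # labour/capital/intermediates, USD/yr
    labour_share: float                               # labour / (labour + capital)
    working_hours: float                              # h per worker per yr
    shadow_prices: dict[str, float]                   # USD per 1000 kcal by item
    mortality_rates: dict[str, float]                 # "endpoint|age|sex" -> deaths/person-yr
    bioeconomy_quantities: dict[str, float]
    prices_2010: dict[str, float]
    population_2010: float
    income_pc_usd: float = 10_000.0   # USD/cap/yr, drives the demand regressions
    # driver trajectory parameters (per-year rates)
    income_growth: float = 0.02
    pop_growth: float = 0.01
    wage_growth: float = 0.02
    gini_drift: float = 0.0
    cost_growth: float = 0.015
    # scratch fields used by the measure/poverty coupling
    pending_revenue_pc: float = 0.0                   # USD/cap/yr to recycle
    price_index: float = 1.0

    def population(self) -> float:
        return float(sum(self.population_by_cohort.values()))

    def cohort_population(self, cohort: Cohort) -> float:
        return self.population_by_cohort[_cohort_key(cohort)]

    def bmi_shares(self, cohort: Cohort) -> np.ndarray:
        return np.asarray(self.bmi_distribution[_cohort_key(cohort)], dtype=float)

    def mortality_rate(self, endpoint: str, age: str, sex: str) -> float:
        return self.mortality_rates[f"{endpoint}|{age}|{sex}"]

    def validate(self) -> None:
        for key, shares in self.bmi_distribution.items():
            if abs(sum(shares) - 1.0) > 1e-9:
                raise ValidationError(f"BMI shares for cohort {key} do not sum to 1")
            if any(s < -1e-12 for s in shares):
                raise ValidationError(f"negative BMI share in cohort {key}")
        if not (0.0 <= self.labour_share <= 1.0):
            raise ValidationError("labour_share outside [0, 1]")
        if self.hourly_wage < 0 or self.working_hours <= 0:
            raise ValidationError("wage/hours must be non-negative/positive")
        for v in self.population_by_cohort.values():
            if v < 0:
                raise ValidationError("negative cohort population")
        self.diet.validate()
        self.income.validate()

    # mean per-capita intake implied by the anthropometric tables -----------
    def anthropometric_intake(self) -> float:
        """Population-mean kcal/cap/day implied by cohort x BMI-class intakes."""
        total_pop = self.population()
        if total_pop == 0:
            return 0.0
        acc = 0.0
        for cohort in C.COHORTS:
            pop = self.cohort_population(cohort)
            shares = self.bmi_shares(cohort)
            for i, cls in enumerate(C.BMI_CLASSES):
                acc += pop * shares[i] * self.intake_table.intake(cohort, cls)
        return acc / total_pop


# -------------------------------------------------------------------- world
@dataclass
class WorldState:
    year: int
    countries: list[CountryState]
    cells: list[CellState]
    gwp_table: dict[str, float]
    life_table: LifeTable
    risk_model: RiskModel
    trade_pools: dict[str, float] = field(
        default_factory=lambda: {"crops": 0.20, "livestock": 0.10})
    bii_floor: dict[str, float] = field(default_factory=dict)  # biome_region -> floor

    def validate(self) -> None:
        n = len(self.countries)
        for cell in self.cells:
            if not (0 <= cell.country < n):
                raise ValidationError(f"cell assigned to unknown country {cell.country}")
            cell.validate()
        for c in self.countries:
            c.validate()
        self.life_table.validate()
        self.risk_model.validate()

    def copy(self) -> "WorldState":
        return copy.deepcopy(self)

    def total_population(self) -> float:
        return float(sum(c.population() for c in self.countries))

    def total_land_area(self) -> float:
        return float(sum(cell.total_area() for cell in self.cells))

    def protected_share(self) -> float:
        total = self.total_land_area()
        prot = sum(c.total_area() * c.protected_fraction for c in self.cells)
        return prot / total if total > 0 else 0.0

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        # numpy arrays in the risk model need explicit conversion
        d["risk_model"]["rr"] = {
            f: {e: self.risk_model.rr[f][e].tolist() for e in C.ENDPOINTS}
            for f in C.RISK_FACTORS
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "WorldState":
        rm = d["risk_model"]
        risk = RiskModel(
            rr={f: {e: np.asarray(rm["rr"][f][e], dtype=float) for e in C.ENDPOINTS}
                for f in C.RISK_FACTORS},
            category_breaks={k: list(v) for k, v in rm["category_breaks"].items()},
            direction=dict(rm["direction"]),
            tmrel=dict(rm["tmrel"]),
            colorectal_share_of_cancer=rm.get("colorectal_share_of_cancer", 0.35),
        )
        countries = []
        for cd in d["countries"]:
            countries.append(CountryState(
                name=cd["name"],
                population_by_cohort=dict(cd["population_by_cohort"]),
                bmi_distribution={k: list(v) for k, v in cd["bmi_distribution"].items()},
                diet=DietProfile(dict(cd["diet"]["intake"]), cd["diet"]["waste_ratio"]),
                income=IncomeDistribution(**cd["income"]),
                intake_table=CohortIntakeTable(
                    {k: dict(v) for k, v in cd["intake_table"]["recommended"].items()}),
                hourly_wage=cd["hourly_wage"],
                factor_costs=dict(cd["factor_costs"]),
                labour_share=cd["labour_share"],
                working_hours=cd["working_hours"],
                shadow_prices=dict(cd["shadow_prices"]),
                mortality_rates=dict(cd["mortality_rates"]),
                bioeconomy_quantities=dict(cd["bioeconomy_quantities"]),
                prices_2010=dict(cd["prices_2010"]),
                population_2010=cd["population_2010"],
                income_pc_usd=cd.get("income_pc_usd", 10_000.0),
                income_growth=cd["income_growth"],
                pop_growth=cd["pop_growth"],
                wage_growth=cd["wage_growth"],
                gini_drift=cd["gini_drift"],
                cost_growth=cd["cost_growth"],
                pending_revenue_pc=cd.get("pending_revenue_pc", 0.0),
                price_index=cd.get("price_index", 1.0),
            ))
        cells = []
        for ce in d["cells"]:
            nb = ce["n_budget"]
            cells.append(CellState(
                country=ce["country"],
                area_by_class=dict(ce["area_by_class"]),
                potential_cropland=ce["potential_cropland"],
                protected=ce["protected"],
                hotspot_or_intact=ce["hotspot_or_intact"],
                biome_region=ce["biome_region"],
                range_rarity_weight=ce["range_rarity_weight"],
                intactness=dict(ce["intactness"]),
                water_availability=ce["water_availability"],
                water_withdrawal=ce["water_withdrawal"],
                efr=ce["efr"],
                n_budget=NitrogenBudget(
                    cropland_inputs=dict(nb["cropland_inputs"]),
                    cropland_withdrawal=nb["cropland_withdrawal"],
                    pasture_inputs=dict(nb["pasture_inputs"]),
                    pasture_withdrawal=nb["pasture_withdrawal"],
                    awms_excretion=nb["awms_excretion"],
                    awms_recycled=nb["awms_recycled"],
                    natural_fixation=nb["natural_fixation"],
                ),
                emissions=dict(ce["emissions"]),
                protected_fraction=ce.get("protected_fraction"),
            ))
        return cls(
            year=d["year"],
            countries=countries,
            cells=cells,
            gwp_table=dict(d["gwp_table"]),
            life_table=LifeTable(dict(d["life_table"]["remaining"])),
            risk_model=risk,
            trade_pools=dict(d["trade_pools"]),
            bii_floor=dict(d.get("bii_floor", {})),
        )

    @classmethod
    def from_json(cls, s: str) -> "WorldState":
        return cls.from_dict(json.loads(s))

    # --------------------------------------------------------- CSV exports
    def countries_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.countries):
            row = {
                "country": c.name, "index": i, "population": c.population(),
                "mean_income": c.income.mean_income, "gini": c.income.gini,
                "hourly_wage": c.hourly_wage, "labour_share": c.labour_share,
                "working_hours": c.working_hours, "waste_ratio": c.diet.waste_ratio,
                "total_intake": c.diet.total_intake(),
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for j, cell in enumerate(self.cells):
            row = {
                "cell": j, "country": cell.country, "total_area": cell.total_area(),
                "cropland": cell.cropland_area(), "protected": cell.protected,
                "hotspot_or_intact": cell.hotspot_or_intact,
                "biome_region": cell.biome_region,
                "range_rarity_weight": cell.range_rarity_weight,
                "water_availability": cell.water_availability,
                "water_withdrawal": cell.water_withdrawal, "efr": cell.efr,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def lifetable_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, self.life_table.remaining[a]) for a in C.AGE_GROUPS],
            columns=["age", "remaining_life_expectancy"])

    def diets_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.countries:
            for item in C.DIET_ITEMS:
                rows.append((c.name, item, c.diet.intake[item], c.diet.waste_ratio))
        return pd.DataFrame(rows, columns=["country", "item", "kcal_per_cap_day", "waste_ratio"])
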