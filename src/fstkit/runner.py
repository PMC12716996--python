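"""Scenario orchestration: BASE vs measures vs packages over 2020-2050.

The runner advances the baseline drivers (population, income, wages, factor
costs, the BMI nutrition transition) to each evaluation year, applies the
scenario's measures at that year's phase-in on top of the baseline state,
couples measure-induced food-price changes and recycled revenues into the
income distributions, and evaluates the indicator panel. It also builds the
measure x indicator delta matrix with a desirability classification and the
package interaction decomposition

    delta(package) = sum delta(members) + interaction,

which is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from . import demand, indicators
from .config import (ALL_MEASURE_NAMES, CLASSIFICATION_EPS, HIGHER_IS_BETTER,
                     LOWER_IS_BETTER, PACKAGES, POVERTY_COUPLING, SynthConfig)
from .errors import ValidationError
from .measures import MeasureSpec, PackageSpec, apply_package
from .poverty import apply_expenditure_shock, recycle_revenue
from .world import WorldState


@dataclass
class ScenarioSpec:
    """A named scenario: no measures (BASE), one measure, or a package."""

    name: str
    package: PackageSpec | None = None
    years: tuple[int, ...] = tuple(range(2020, 2055, 5))

    @classmethod
    def base(cls, years=tuple(range(2020, 2055, 5))) -> "ScenarioSpec":
        return cls("BASE", None, tuple(years))

    @classmethod
    def single(cls, measure: str, years=tuple(range(2020, 2055, 5))) -> "ScenarioSpec":
        return cls(measure, PackageSpec(measure, [MeasureSpec(measure)]), tuple(years))

    def member_names(self) -> tuple[str, ...]:
        if self.package is None:
            return ()
        return tuple(m.name for m in self.package.members)


# ------------------------------------------------------------ driver model
def _shift_mass(shares: np.ndarray, src: int, dst: int, frac: float) -> None:
    moved = shares[src] * frac
    shares[src] -= moved
    shares[dst] += moved


def advance_drivers(world0: WorldState, year: int, config: SynthConfig) -> WorldState:
    """Baseline state at ``year`` from the 2020 state.

    Exponential growth of population, income, wages and factor costs at the
    per-country driver rates; diets re-projected from the demand regressions
    at the new income; a slow BMI-class drift emulates the nutrition
    transition (underweight falls, obesity rises). Cell-level pressures
    (fertiliser, withdrawals, emissions) scale with the country's population.
    """
    t = year - world0.year
    if t < 0:
        raise ValidationError(f"cannot run backwards to {year}")
    world = world0.copy()
    world.year = year
    if t == 0:
        return world
    drift = config.obesity_drift
    for country in world.countries:
        g_pop = (1.0 + country.pop_growth) ** t
        g_inc = (1.0 + country.income_growth) ** t
        g_wage = (1.0 + country.wage_growth) ** t
        g_cost = (1.0 + country.cost_growth) ** t
        for k in country.population_by_cohort:
            country.population_by_cohort[k] *= g_pop
        country.income.population *= g_pop
        country.income.mean_income *= g_inc
        country.income.gini = float(np.clip(
            country.income.gini + country.gini_drift * t, 0.05, 0.95))
        country.income_pc_usd *= g_inc
        country.hourly_wage *= g_wage
        for k in country.factor_costs:
            country.factor_costs[k] *= g_cost
        # nutrition transition: mass drifts out of the thin classes into the
        # healthy class, and from healthy through overweight to obese
        for key, shares in country.bmi_distribution.items():
            s = np.asarray(shares, dtype=float)
            up = min(drift * t, 0.9)
            _shift_mass(s, 0, 2, up)          # underweight -> healthy
            _shift_mass(s, 1, 2, up)          # below-healthy -> healthy
            _shift_mass(s, 3, 4, 0.5 * up)    # overweight -> obese
            _shift_mass(s, 2, 3, 0.8 * up)    # healthy -> overweight
            s /= s.sum()
            country.bmi_distribution[key] = s.tolist()
        # diet re-projected at the new income, same within-group item shares
        within = {}
        for group, items in C.GROUP_ITEMS.items():
            tot = country.diet.items_total(items)
            within[group] = ({i: country.diet.intake[i] / tot for i in items}
                             if tot > 0 else {i: 1.0 / len(items) for i in items})
        total_intake = country.anthropometric_intake()
        country.diet = demand.build_diet(
            country.income_pc_usd, total_intake,
            config.diet_regression_coeffs, config.waste_regression_coeffs, within)
    # environmental pressure scales with population
    pop_scale = {i: (1.0 + c.pop_growth) ** (0.5 * t)
                 for i, c in enumerate(world.countries)}
    for cell in world.cells:
        s = pop_scale[cell.country]
        cell.water_withdrawal *= s
        for k in cell.emissions:
            cell.emissions[k] *= s
        nb = cell.n_budget
        for k in nb.cropland_inputs:
            nb.cropland_inputs[k] *= s
        nb.cropland_withdrawal *= min(s, 1.0 + 0.4 * (s - 1.0))
        nb.awms_excretion *= s
        nb.awms_recycled *= s
    return world


# --------------------------------------------------------------- scenarios
def _couple_income(world: WorldState, config: SynthConfig) -> None:
    """Food-price and revenue effects of measures on income distributions."""
    elasticity = POVERTY_COUPLING["engel_elasticity"]
    for country in world.countries:
        pi = country.price_index - 1.0
        if abs(pi) > 1e-12:
            country.income = apply_expenditure_shock(country.income, pi, elasticity)
        if country.pending_revenue_pc > 0:
            country.income = recycle_revenue(
                country.income, country.pending_revenue_pc * config.ppp_per_usd_day)


def run_scenario(world0: WorldState, spec: ScenarioSpec,
                 config: SynthConfig) -> pd.DataFrame:
    """Indicator panel time series for one scenario.

    Returns a DataFrame indexed by year with one column per indicator;
    'global_surface_warming' is NaN unless a warming hook is installed.
    """
    base_wages = {c.name: c.hourly_wage for c in world0.countries}
    floors = indicators.bii_by_biome_region(world0)
    rows = {}
    for year in spec.years:
        state = advance_drivers(world0, year, config)
        state.bii_floor = dict(floors)
        if spec.package is not None:
            state = apply_package(state, spec.package, year)
            _couple_income(state, config)
        panel = indicators.indicator_panel(state, base_wages)
        rows[year] = {k: (np.nan if v is None else v) for k, v in panel.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "year"
    return df


@dataclass
class EnsembleResult:
    """Panel time series per scenario plus each scenario's member measures."""

    results: dict[str, pd.DataFrame]
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def require(self, name: str) -> pd.DataFrame:
        if name not in self.results:
            raise ValidationError(f"scenario {name!r} missing from ensemble")
        return self.results[name]


def run_ensemble(world0: WorldState, config: SynthConfig,
                 singles: tuple[str, ...] = ALL_MEASURE_NAMES,
                 packages: tuple[str, ...] = ("Diets", "Livelihoods", "Biosphere",
                                              "Agriculture", "CrossSector",
                                              "FST_SSP2", "FST_SDP"),
                 years: tuple[int, ...] = tuple(range(2020, 2055, 5))) -> EnsembleResult:
    """BASE plus single-measure runs plus package runs, all on one baseline."""
    specs = [ScenarioSpec.base(years)]
    specs += [ScenarioSpec.single(m, years) for m in singles]
    specs += [ScenarioSpec(p, PackageSpec.from_name(p), tuple(years)) for p in packages]
    results, members = {}, {}
    for spec in specs:
        results[spec.name] = run_scenario(world0, spec, config)
        members[spec.name] = spec.member_names()
    return EnsembleResult(results, members)


# ------------------------------------------------------------ delta matrix
def _classify(indicator: str, delta: float) -> str:
    eps = CLASSIFICATION_EPS.get(indicator, 1e-9)
    if not np.isfinite(delta) or abs(delta) <= eps:
        return "neutral"
    if indicator in LOWER_IS_BETTER:
        return "improvement" if delta < 0 else "deterioration"
    if indicator in HIGHER_IS_BETTER:
        return "improvement" if delta > 0 else "deterioration"
    # special: agricultural labour demand — falling demand is a welfare
    # trade-off by default; scenarios containing HumanDevelop are evaluated
    # against the HumanDevelop single run by the caller
    return "improvement" if delta > 0 else "deterioration"


def delta_matrix(ensemble: EnsembleResult, year: int = 2050) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(delta, classification) of every non-BASE scenario vs BASE at ``year``.

    The labour-demand column of scenarios that contain the HumanDevelop
    setting is evaluated relative to the HumanDevelop single run (which is
    itself classed neutral there), since wages are the more welfare-relevant
    indicator under that development path.
    """
    base = ensemble.require("BASE")
    if year not in base.index:
        raise ValidationError(f"year {year} not evaluated")
    base_row = base.loc[year]
    hd_row = (ensemble.results["HumanDevelop"].loc[year]
              if "HumanDevelop" in ensemble.results else None)
    deltas, classes = {}, {}
    for name, df in ensemble.results.items():
        if name == "BASE":
            continue
        row = df.loc[year] - base_row
        cls = {}
        for ind in df.columns:
            if ind == "global_surface_warming":
                cls[ind] = "not_computed"
                continue
            d = row[ind]
            if ind == "ag_labour":
                has_hd = "HumanDevelop" in ensemble.members.get(name, ())
                if name == "HumanDevelop":
                    cls[ind] = "neutral"
                    continue
                if has_hd and hd_row is not None:
                    d = df.loc[year, ind] - hd_row[ind]
                    row[ind] = d
            cls[ind] = _classify(ind, d)
        deltas[name] = row
        classes[name] = pd.Series(cls)
    return pd.DataFrame(deltas).T, pd.DataFrame(classes).T


def interaction_effect(ensemble: EnsembleResult, package_name: str,
                       year: int = 2050) -> pd.Series:
    """Per-indicator interaction: delta(package) - sum of member deltas."""
    base = ensemble.require("BASE").loc[year]
    pkg = ensemble.require(package_name).loc[year] - base
    members = ensemble.members.get(package_name) or PACKAGES[package_name]
    member_sum = None
    for m in members:
        d = ensemble.require(m).loc[year] - base
        member_sum = d if member_sum is None else member_sum + d
    if member_sum is None:
        return pkg * 0.0
    return pkg - member_sum


def interactions_frame(ensemble: EnsembleResult,
                       packages: tuple[str, ...] = ("Diets", "Livelihoods",
                                                    "Biosphere", "Agriculture",
                                                    "CrossSector", "FST_SSP2",
                                                    "FST_SDP"),
                       year: int = 2050) -> pd.DataFrame:
    return pd.DataFrame({p: interaction_effect(ensemble, p, year)
                         for p in packages}).T
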