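"""Shared fixtures: a small seeded world and hand-built minimal states."""

from __future__ import annotations

import numpy as np
import pytest

from fstkit import SynthConfig, generate_world
from fstkit import constants as C
from fstkit.world import (CohortIntakeTable, CountryState, DietProfile,
                          IncomeDistribution)


@pytest.fixture(scope="session")
def config() -> SynthConfig:
    return SynthConfig(n_countries=3, n_cells_per_country=4, seed=7)


@pytest.fixture(scope="session")
def world(config):
    return generate_world(config)


@pytest.fixture()
def country(world):
    # mutable copy of the first generated country
    import copy
    return copy.deepcopy(world.countries[0])


def make_simple_country(adult_pop: float = 1000.0,
                        bmi_shares: tuple[float, ...] = (0.0, 0.0, 1.0, 0.0, 0.0),
                        intake: dict | None = None,
                        waste_ratio: float = 1.5) -> CountryState:
    """A one-cohort-per-sex country with uniform BMI shares, for arithmetic tests."""
    pop = {}
    shares = {}
    for age in C.AGE_GROUPS:
        for sex in C.SEXES:
            key = f"{age}|{sex}"
            pop[key] = adult_pop / ((len(C.AGE_GROUPS) - 1) * 2) if age != "0-14" else 0.0
            shares[key] = list(bmi_shares)
    base_intake = {i: 0.0 for i in C.DIET_ITEMS}
    base_intake.update({"staples": 1200.0, "fruits_veg_nuts": 300.0,
                        "ruminant_meat": 200.0, "milk": 200.0, "sugar": 100.0})
    if intake:
        base_intake.update(intake)
    recommended = {}
    for age in C.AGE_GROUPS:
        for sex in C.SEXES:
            recommended[f"{age}|{sex}"] = {
                "underweight": 1700.0, "below_healthy": 1900.0,
                "healthy": 2100.0, "overweight": 2400.0, "obese": 2700.0}
    return CountryState(
        name="T", population_by_cohort=pop, bmi_distribution=shares,
        diet=DietProfile(base_intake, waste_ratio),
        income=IncomeDistribution(10.0, 0.4, adult_pop),
        intake_table=CohortIntakeTable(recommended),
        hourly_wage=2.0,
        factor_costs={"labour": 6e8, "capital": 3e8, "intermediates": 1e8},
        labour_share=6e8 / 9e8, working_hours=2000.0,
        shadow_prices={i: 1.0 for i in C.DIET_ITEMS},
        mortality_rates={f"{e}|{a}|{s}": 0.002
                         for e in C.ENDPOINTS for a in C.AGE_GROUPS for s in C.SEXES},
        bioeconomy_quantities={p: 1.0 for p in C.BIOECONOMY_PRODUCTS},
        prices_2010={p: 100.0 for p in C.BIOECONOMY_PRODUCTS},
        population_2010=adult_pop,
        income_pc_usd=5000.0,
    )


@pytest.fixture()
def simple_country() -> CountryState:
    return make_simple_country()
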