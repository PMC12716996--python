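"""Indicator formulas: Shannon, BII, nitrogen, water, CO2e, economy block."""

import math

import numpy as np
import pytest

from fstkit import MeasureSpec, apply_measure
from fstkit import constants as C
from fstkit.errors import DomainError, ValidationError
from fstkit.indicators import (EmissionVector, aggregate_bii, cell_bii,
                               co2e_total, constant_price_value,
                               agricultural_expenditure, efr_violations,
                               indicator_panel, labour_demand,
                               nitrogen_surplus, shannon_crop_diversity,
                               wage_index, world_nitrogen_surplus)
from fstkit.world import NitrogenBudget

from conftest import make_simple_country


class TestShannon:
    def test_single_crop_is_zero(self):
        assert shannon_crop_diversity([1.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_equal_shares_reach_ln_k(self):
        assert shannon_crop_diversity([0.25] * 4) == pytest.approx(math.log(4))

    def test_two_class_example(self):
        assert shannon_crop_diversity([0.8, 0.2]) == pytest.approx(0.500402, abs=1e-6)

    def test_zero_cropland_undefined(self):
        with pytest.raises(DomainError):
            shannon_crop_diversity([0.0, 0.0])

    @pytest.mark.parametrize("k", [2, 5, 9, 20])
    def test_bounded_by_ln_k(self, k):
        rng = np.random.default_rng(k)
        for _ in range(20):
            shares = rng.dirichlet(np.ones(k))
            h = shannon_crop_diversity(shares)
            assert -1e-12 <= h <= math.log(k) + 1e-12


class TestBII:
    def _cell(self, world, areas):
        cell = world.cells[0].__class__(**{**world.cells[0].__dict__})
        cell.area_by_class = {c: 0.0 for c in C.LAND_CLASSES}
        cell.area_by_class.update(areas)
        return cell

    def test_undisturbed_cell_is_one(self, world):
        cell = self._cell(world, {"forest_old": 500.0, "other_natural": 500.0})
        assert cell_bii(cell) == pytest.approx(1.0)

    def test_single_managed_class_equals_coefficient(self, world):
        cell = self._cell(world, {"pasture": 1000.0})
        assert cell_bii(cell) == pytest.approx(cell.intactness["pasture"])

    def test_5050_mix(self, world):
        cell = self._cell(world, {"forest_old": 500.0, "rice": 500.0})
        cell.intactness = dict(cell.intactness)
        cell.intactness["rice"] = 0.3
        assert cell_bii(cell) == pytest.approx(0.65)

    def test_bii_bounded(self, world):
        for cell in world.cells:
            assert 0.0 <= cell_bii(cell) <= 1.0

    def test_aggregate_uniform_ignores_weights(self, world):
        w = world.copy()
        for cell in w.cells:
            cell.area_by_class = {c: 0.0 for c in C.LAND_CLASSES}
            cell.area_by_class["pasture"] = 100.0
        b = aggregate_bii(w, "all")
        assert b == pytest.approx(w.cells[0].intactness["pasture"])

    def test_small_cropland_cell_excluded_from_cropland_selector(self, world):
        w = world.copy()
        cell = w.cells[0]
        for c in C.CROPLAND_CLASSES:
            cell.area_by_class[c] = 0.0
        cell.area_by_class["temperate_cereals"] = 99.0  # below the 100 ha cut
        included = aggregate_bii(w, "cropland_landscape")
        w2 = world.copy()
        others = [c for i, c in enumerate(w2.cells) if i != 0]
        w2.cells = others
        assert included == pytest.approx(aggregate_bii(w2, "cropland_landscape"))

    def test_weighted_mean_example(self, world):
        w = world.copy()
        w.cells = w.cells[:2]
        for cell, (bii_cls, weight) in zip(w.cells, [("forest_old", 1.0),
                                                     ("pasture", 3.0)]):
            cell.area_by_class = {c: 0.0 for c in C.LAND_CLASSES}
            cell.area_by_class[bii_cls] = 100.0
            cell.range_rarity_weight = weight
            cell.intactness = dict(cell.intactness)
            cell.intactness["pasture"] = 0.5
            cell.hotspot_or_intact = True
        assert aggregate_bii(w, "all") == pytest.approx(0.625)

    def test_empty_selection_raises(self, world):
        w = world.copy()
        for cell in w.cells:
            cell.hotspot_or_intact = False
        with pytest.raises(DomainError):
            aggregate_bii(w, "hotspot_landscape")


class TestNitrogen:
    def test_balanced_budget_zero_surplus(self):
        nb = NitrogenBudget(cropland_inputs={"fertilizer": 5.0},
                            cropland_withdrawal=5.0)
        assert nitrogen_surplus(nb)["cropland"] == pytest.approx(0.0)

    def test_awms_surplus_is_excretion_minus_recycled(self):
        nb = NitrogenBudget(awms_excretion=10.0, awms_recycled=7.5)
        assert nitrogen_surplus(nb)["awms"] == pytest.approx(2.5)

    def test_natural_surplus_equals_fixation(self):
        nb = NitrogenBudget(natural_fixation=3.0)
        s = nitrogen_surplus(nb)
        assert s["natural"] == pytest.approx(3.0)
        assert s["total"] == pytest.approx(3.0)

    def test_agricultural_soils_excludes_awms_and_natural(self):
        nb = NitrogenBudget(cropland_inputs={"fertilizer": 8.0},
                            cropland_withdrawal=5.0, pasture_inputs={"dep": 2.0},
                            pasture_withdrawal=1.0, awms_excretion=4.0,
                            awms_recycled=1.0, natural_fixation=2.0)
        s = nitrogen_surplus(nb)
        assert s["agricultural_soils"] == pytest.approx(4.0)
        assert s["total"] == pytest.approx(9.0)

    def test_pool_additivity(self):
        """The total responds additively to pool-level perturbations."""
        nb = NitrogenBudget(cropland_inputs={"fertilizer": 8.0},
                            cropland_withdrawal=5.0, awms_excretion=4.0,
                            awms_recycled=1.0, natural_fixation=2.0)
        base = nitrogen_surplus(nb)["total"]
        nb.cropland_inputs["fertilizer"] += 1.0
        assert nitrogen_surplus(nb)["total"] == pytest.approx(base + 1.0)
        nb.awms_recycled += 0.5
        assert nitrogen_surplus(nb)["total"] == pytest.approx(base + 0.5)

    def test_nitrogen_eff_lowers_cropland_surplus_only(self, world):
        out = apply_measure(world, MeasureSpec("NitrogenEff",
                                               {"cost_premium": 0.0}), 2050)
        for a, b in zip(world.cells, out.cells):
            sa, sb = nitrogen_surplus(a.n_budget), nitrogen_surplus(b.n_budget)
            assert sb["cropland"] <= sa["cropland"] + 1e-15
            assert sb["pasture"] == pytest.approx(sa["pasture"])
            assert sb["awms"] == pytest.approx(sa["awms"])


class TestWaterAndEmissions:
    def test_compliant_world_zero_violations(self, world):
        w = world.copy()
        for cell in w.cells:
            cell.water_withdrawal = max(0.0, cell.water_availability - cell.efr)
        assert efr_violations(w) == pytest.approx(0.0)

    def test_violation_arithmetic(self, world):
        w = world.copy()
        w.cells = w.cells[:1]
        cell = w.cells[0]
        cell.water_availability, cell.efr, cell.water_withdrawal = 20.0, 15.0, 10.0
        assert efr_violations(w) == pytest.approx(5.0)

    def test_zero_after_enforcement(self, world):
        out = apply_measure(world, MeasureSpec("WaterConservation"), 2050)
        assert efr_violations(out) == pytest.approx(0.0, abs=1e-12)

    def test_co2e_zero_vector(self):
        assert co2e_total(EmissionVector(0, 0, 0)) == 0.0

    def test_gwp_factors(self):
        assert co2e_total(EmissionVector(0, 0, 1.0)) == pytest.approx(0.273)
        assert co2e_total(EmissionVector(0, 1.0, 0)) == pytest.approx(0.027)
        assert co2e_total(EmissionVector(1.0, 0, 0)) == pytest.approx(0.001)


class TestEconomy:
    def test_zero_prices_zero_expenditure(self):
        c = make_simple_country()
        c.shadow_prices = {i: 0.0 for i in C.DIET_ITEMS}
        assert agricultural_expenditure(c) == 0.0

    def test_expenditure_linear_in_prices(self):
        c = make_simple_country()
        e1 = agricultural_expenditure(c)
        c.shadow_prices = {i: 2.0 * p for i, p in c.shadow_prices.items()}
        assert agricultural_expenditure(c) == pytest.approx(2 * e1)

    def test_labour_demand_arithmetic(self):
        c = make_simple_country()
        c.factor_costs = {"labour": 5e8, "capital": 5e8, "intermediates": 0.0}
        c.labour_share, c.hourly_wage, c.working_hours = 0.5, 2.5, 2000.0
        assert labour_demand(c) == pytest.approx(100_000.0)

    def test_labour_falls_when_wage_rises(self):
        c = make_simple_country()
        before = labour_demand(c)
        c.hourly_wage *= 2
        assert labour_demand(c) < before

    def test_wage_index(self, world):
        base = {c.name: c.hourly_wage for c in world.countries}
        assert wage_index(world, base) == pytest.approx(1.0)
        w = world.copy()
        for c in w.countries:
            c.hourly_wage *= 2
        assert wage_index(w, base) == pytest.approx(2.0)

    def test_wage_index_two_country_example(self, world):
        w = world.copy()
        w.countries = w.countries[:2]
        for c, (wage, pop10) in zip(w.countries, [(1.0, 5.0), (3.0, 5.0)]):
            c.hourly_wage, c.population_2010 = wage, pop10
        base = {c.name: 1.0 for c in w.countries}
        assert wage_index(w, base) == pytest.approx(2.0)

    def test_constant_price_value(self):
        assert constant_price_value({}, {}) == 0.0
        assert constant_price_value({"a": 100.0, "b": 2.0},
                                    {"a": 2.0, "b": 50.0}) == pytest.approx(300.0)
        with pytest.raises(ValidationError):
            constant_price_value({"a": 1.0}, {"b": 1.0})


def test_panel_is_pure_function_of_state(world):
    a = indicator_panel(world)
    b = indicator_panel(world)
    assert a == b
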