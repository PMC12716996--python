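"""The measure engine: caps, floors, waste, wages, land, water, packages."""

import pytest

from fstkit import (MeasureSpec, PackageSpec, SynthConfig, apply_measure,
                    apply_package, generate_world, phase_in_factor)
from fstkit import constants as C
from fstkit.config import PACKAGES
from fstkit.errors import MeasureInfeasibleError, UnknownMeasureError
from fstkit.measures import (apply_cap_with_staple_compensation,
                             apply_capital_substitution,
                             apply_floor_with_staple_compensation,
                             apply_manure_digesters, apply_min_wage,
                             apply_protection, cap_waste, enforce_efr,
                             shift_bmi_intake)
from fstkit.world import DietProfile

from conftest import make_simple_country


def diet(**kw):
    base = {i: 0.0 for i in C.DIET_ITEMS}
    base.update(kw)
    return DietProfile(base, kw.pop("waste_ratio", 1.5) if "waste_ratio" in kw else 1.5)


class TestPhaseIn:
    def test_endpoints_and_midpoint(self):
        m = MeasureSpec("LowFoodWaste")  # full in 2050
        assert phase_in_factor(m, 2020) == 0.0
        assert phase_in_factor(m, 2050) == 1.0
        assert phase_in_factor(m, 2035) == pytest.approx(0.5)
        assert phase_in_factor(m, 2010) == 0.0
        assert phase_in_factor(m, 2080) == 1.0

    def test_land_conservation_full_by_2030(self):
        m = MeasureSpec("LandConservation")
        assert phase_in_factor(m, 2030) == 1.0
        assert phase_in_factor(m, 2025) == pytest.approx(0.5)


class TestCapsAndFloors:
    def test_cap_conserves_total(self):
        d = diet(ruminant_meat=500.0, staples=1000.0, sugar=500.0)
        out = apply_cap_with_staple_compensation(d, "ruminant_meat", 200.0)
        assert out.intake["ruminant_meat"] == pytest.approx(200.0)
        assert out.intake["staples"] == pytest.approx(1300.0)
        assert out.intake["sugar"] == pytest.approx(500.0)
        assert out.total_intake() == pytest.approx(2000.0)

    def test_cap_below_is_identity(self):
        d = diet(ruminant_meat=100.0, staples=1000.0)
        out = apply_cap_with_staple_compensation(d, "ruminant_meat", 200.0)
        assert out.intake == d.intake

    def test_cap_idempotent(self):
        d = diet(ruminant_meat=500.0, staples=1000.0)
        once = apply_cap_with_staple_compensation(d, "ruminant_meat", 200.0, f=0.6)
        twice = apply_cap_with_staple_compensation(once, "ruminant_meat", 200.0, f=0.6)
        assert once.intake == twice.intake

    def test_group_cap_scales_subitems_proportionally(self):
        d = diet(pig_meat=200.0, poultry_meat=100.0, eggs=100.0, staples=500.0)
        out = apply_cap_with_staple_compensation(d, C.MONOGASTRIC_ITEMS, 200.0)
        assert out.items_total(C.MONOGASTRIC_ITEMS) == pytest.approx(200.0)
        assert out.intake["pig_meat"] == pytest.approx(100.0)
        assert out.intake["staples"] == pytest.approx(700.0)

    def test_floor_reduces_staples(self):
        d = diet(legumes=50.0, staples=1000.0)
        out = apply_floor_with_staple_compensation(d, "legumes", 100.0)
        assert out.intake["legumes"] == pytest.approx(100.0)
        assert out.intake["staples"] == pytest.approx(950.0)
        assert out.total_intake() == pytest.approx(d.total_intake())

    def test_floor_above_is_identity(self):
        d = diet(legumes=300.0, staples=1000.0)
        out = apply_floor_with_staple_compensation(d, "legumes", 100.0)
        assert out.intake == d.intake

    def test_floor_infeasible_when_staples_exhausted(self):
        d = diet(legumes=0.0, staples=50.0)
        with pytest.raises(MeasureInfeasibleError):
            apply_floor_with_staple_compensation(d, "legumes", 100.0)

    def test_alcohol_capped_at_1_4_percent(self):
        """A diet with alcohol at 5% of a 2000 kcal intake ends at 1.4%."""
        d = diet(alcohol=100.0, staples=1400.0, fruits_veg_nuts=500.0)
        out = apply_measure_diet(d, "LowProcessed")
        assert out.intake["alcohol"] / out.total_intake() == pytest.approx(0.014)
        assert out.total_intake() == pytest.approx(2000.0)


def apply_measure_diet(d, name):
    """Run a diet measure through the engine on a one-country world stub."""
    w = generate_world(SynthConfig(n_countries=1, n_cells_per_country=1, seed=0))
    w.countries[0].diet = d
    out = apply_measure(w, MeasureSpec(name), 2050)
    return out.countries[0].diet


class TestWasteCap:
    def test_waste_capped_at_20_percent_of_intake(self):
        d = diet(staples=2000.0)
        d.waste_ratio = 1.5  # supply 3000
        out = cap_waste(d, 0.20)
        assert out.supply() == pytest.approx(2400.0)
        assert out.total_intake() == pytest.approx(2000.0)

    def test_compliant_ratio_unchanged(self):
        d = diet(staples=2000.0)
        d.waste_ratio = 1.1
        assert cap_waste(d, 0.20).waste_ratio == pytest.approx(1.1)

    def test_idempotent(self):
        d = diet(staples=2000.0)
        d.waste_ratio = 1.5
        once = cap_waste(d, 0.20, f=0.7)
        assert cap_waste(once, 0.20, f=0.7).waste_ratio == once.waste_ratio

    def test_capping_never_increases_supply(self):
        d = diet(staples=1800.0, milk=200.0)
        d.waste_ratio = 1.4
        assert cap_waste(d, 0.20).supply() <= d.supply()


class TestBMIShift:
    def test_halve_overweight_shares(self):
        c = make_simple_country(bmi_shares=(0.0, 0.0, 0.6, 0.30, 0.10))
        out = shift_bmi_intake(c, "halve_overweight", f=1.0)
        shares = out.bmi_shares(("30-44", "F"))
        assert shares[3] == pytest.approx(0.15)
        assert shares[4] == pytest.approx(0.05)
        assert shares[2] == pytest.approx(0.80)

    def test_no_underweight_mass_is_identity(self):
        c = make_simple_country(bmi_shares=(0.0, 0.0, 0.7, 0.2, 0.1))
        out = shift_bmi_intake(c, "eradicate_underweight", f=1.0)
        assert out.bmi_distribution == c.bmi_distribution
        assert out.diet.intake == c.diet.intake

    def test_intake_change_matches_moved_mass_bruteforce(self):
        c = make_simple_country(bmi_shares=(0.1, 0.1, 0.5, 0.2, 0.1))
        out = shift_bmi_intake(c, "halve_overweight", f=1.0)
        # brute force: sum over cohorts and classes of moved mass x intake gap
        expect_delta = 0.0
        pop = c.population()
        for cohort in C.COHORTS:
            cpop = c.cohort_population(cohort)
            healthy = c.intake_table.healthy_target(cohort)
            for cls in ("overweight", "obese"):
                moved = 0.5 * c.bmi_shares(cohort)[C.BMI_CLASSES.index(cls)]
                expect_delta += cpop * moved * (healthy - c.intake_table.intake(cohort, cls))
        got_delta = (out.anthropometric_intake() - c.anthropometric_intake()) * pop
        assert got_delta == pytest.approx(expect_delta, rel=1e-9)
        # relative composition preserved
        base = c.diet.intake
        new = out.diet.intake
        k = new["staples"] / base["staples"]
        for item, v in base.items():
            if v > 0:
                assert new[item] / v == pytest.approx(k, rel=1e-9)


class TestEconomyMeasures:
    def test_min_wage_reaches_3_by_2050(self):
        c = make_simple_country()
        c.hourly_wage = 1.0
        out = apply_min_wage(c, 3.0, 2050, f=1.0)
        assert out.hourly_wage == pytest.approx(3.0)

    def test_high_wage_untouched(self):
        c = make_simple_country()
        c.hourly_wage = 5.0
        for f in (0.0, 0.5, 1.0):
            assert apply_min_wage(c, 3.0, 2050, f=f).hourly_wage == 5.0

    def test_2035_floor_is_midpoint(self):
        c = make_simple_country()
        c.hourly_wage = 0.5
        out = apply_min_wage(c, 3.0, 2035, f=0.5)
        assert out.hourly_wage == pytest.approx(1.5)

    def test_capital_share_halfway_to_target(self):
        c = make_simple_country()
        c.factor_costs = {"labour": 6e8, "capital": 4e8, "intermediates": 0.0}
        out = apply_capital_substitution(c, target=0.20, gap_closure=0.5, f=1.0,
                                         cost_premium=0.0)
        core = out.factor_costs["labour"] + out.factor_costs["capital"]
        assert out.factor_costs["capital"] / core == pytest.approx(0.30)

    def test_capital_share_below_target_unchanged(self):
        c = make_simple_country()
        c.factor_costs = {"labour": 8.5e8, "capital": 1.5e8, "intermediates": 0.0}
        out = apply_capital_substitution(c, f=1.0)
        assert out.factor_costs == c.factor_costs

    def test_fixed_point_is_target_by_bisection(self):
        """Solve update(x) = x independently: the unique fixed point of the
        capped update on (0.2, 1] approached from above is the 0.20 target."""
        def update(x):
            return x - 0.5 * (x - 0.20) if x > 0.20 else x
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if update(mid) < mid:
                hi = mid
            else:
                lo = mid
        assert lo == pytest.approx(0.20, abs=1e-9)

    def test_manure_digesters(self):
        assert apply_manure_digesters(0.6, 0.5, 0.9) == pytest.approx(0.75)
        assert apply_manure_digesters(0.9, 0.5, 0.9) == pytest.approx(0.9)
        assert apply_manure_digesters(0.0, 1.0, 0.9) == pytest.approx(0.9)


class TestLandWater:
    def test_protection_reaches_30_percent(self, world, config):
        out = apply_protection(world, 0.30, 0.15, f=1.0)
        assert out.protected_share() == pytest.approx(0.30, abs=1e-9)

    def test_already_at_target_is_identity(self, world):
        stepped = apply_protection(world, 0.30, 0.15, f=1.0)
        again = apply_protection(stepped, 0.30, 0.15, f=1.0)
        assert again.protected_share() == pytest.approx(stepped.protected_share())

    def test_hotspots_exhausted_first(self, world):
        out = apply_protection(world, 0.30, 0.15, f=1.0)
        # find cells whose protection increased
        newly = [(a, b) for a, b in zip(world.cells, out.cells)
                 if b.protected_fraction > a.protected_fraction + 1e-12]
        hot_with_headroom = [c for c in world.cells
                             if c.hotspot_or_intact and c.protected_fraction < 1]
        n_hot_newly = sum(1 for a, _ in newly if a.hotspot_or_intact)
        # either all hotspot headroom was used, or only hotspot cells were drawn
        assert n_hot_newly == len(hot_with_headroom) or n_hot_newly == len(newly)

    def test_enforce_efr_cap_arithmetic(self, world):
        cell = world.cells[0].__class__(**{**world.cells[0].__dict__})
        cell.water_availability, cell.efr, cell.water_withdrawal = 20.0, 15.0, 10.0
        out = enforce_efr(cell, f=1.0)
        assert out.water_withdrawal == pytest.approx(5.0)

    def test_enforce_efr_boundary_and_identity(self, world):
        cell = world.cells[0].__class__(**{**world.cells[0].__dict__})
        cell.water_availability, cell.efr, cell.water_withdrawal = 10.0, 12.0, 3.0
        assert enforce_efr(cell, f=1.0).water_withdrawal == 0.0
        cell.water_availability, cell.efr, cell.water_withdrawal = 20.0, 5.0, 3.0
        assert enforce_efr(cell, f=1.0).water_withdrawal == 3.0


class TestParameterMeasures:
    def test_libtrade_pool_shares(self, world):
        out = apply_measure(world, MeasureSpec("LibTrade"), 2050)
        assert out.trade_pools["crops"] == pytest.approx(0.30)
        assert out.trade_pools["livestock"] == pytest.approx(0.20)

    def test_cropland_capped_at_80_percent_of_potential(self, world):
        w = world.copy()
        cell = w.cells[0]
        cell.potential_cropland = cell.cropland_area()  # fully used potential
        out = apply_measure(w, MeasureSpec("LandscapeHabitats"), 2050)
        assert out.cells[0].cropland_area() == pytest.approx(
            0.8 * cell.potential_cropland, rel=1e-9)
        # land conserved: freed area went to semi-natural classes
        assert out.cells[0].total_area() == pytest.approx(cell.total_area())

    def test_zero_mitigation_leaves_emissions_unchanged(self, world):
        spec = MeasureSpec("RiceMitigation", {"ch4_rice_reduction": 0.0,
                                              "cost_premium": 0.0})
        out = apply_measure(world, spec, 2050)
        for a, b in zip(world.cells, out.cells):
            assert b.emissions["ch4.rice"] == pytest.approx(a.emissions["ch4.rice"])

    def test_unknown_measure_lists_valid_names(self):
        with pytest.raises(UnknownMeasureError, match="LowFoodWaste"):
            MeasureSpec("NoSuchMeasure")


class TestPackages:
    def test_empty_package_is_identity(self, world):
        out = apply_package(world, PackageSpec("empty", []), 2050)
        assert out.to_json() == world.to_json()

    def test_fst_sdp_has_28_members(self):
        pkg = PackageSpec.from_name("FST_SDP")
        assert len(pkg.members) == 28
        assert set(PACKAGES["FST_SDP"]) == set(PACKAGES["FST_SSP2"]) | set(
            PACKAGES["CrossSector"])

    def test_diets_package_conserves_intake_except_bmi_shifts(self, world, config):
        """Caps/floors/waste leave total intake untouched; only the BMI-shift
        members change it. Audit by running the package without them."""
        members = [MeasureSpec(m) for m in PACKAGES["Diets"]
                   if m not in ("HalfOverweight", "NoUnderweight")]
        out = apply_package(world, PackageSpec("caps_only", members), 2050)
        for a, b in zip(world.countries, out.countries):
            assert b.diet.total_intake() == pytest.approx(
                a.diet.total_intake(), rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_no_negative_state_after_full_package(self, seed):
        cfg = SynthConfig(n_countries=2, n_cells_per_country=3, seed=seed)
        w = generate_world(cfg)
        out = apply_package(w, PackageSpec.from_name("FST_SDP"), 2050)
        for c in out.countries:
            assert min(c.diet.intake.values()) >= -1e-9
            assert c.hourly_wage >= 0
            assert c.diet.waste_ratio >= 1.0 - 1e-12
        for cell in out.cells:
            assert min(cell.area_by_class.values()) >= -1e-9
            assert cell.water_withdrawal >= 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_phase_in(self, seed):
        """The waste-cap effect magnitude is non-decreasing in year."""
        cfg = SynthConfig(n_countries=2, n_cells_per_country=2, seed=seed)
        w = generate_world(cfg)
        prev = None
        for year in (2020, 2030, 2040, 2050):
            out = apply_measure(w, MeasureSpec("LowFoodWaste"), year)
            drop = sum(a.diet.supply() - b.diet.supply()
                       for a, b in zip(w.countries, out.countries))
            if prev is not None:
                assert drop >= prev - 1e-9
            prev = drop
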