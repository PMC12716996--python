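"""Configuration: synthesis parameters, measure constants, packages, desirability.

All Table-style measure constants (caps, floors, targets, shares) live in
``MEASURE_DEFAULTS`` so that users can override any of them; dietary reference
values follow planetary-health-diet style recommendations (kcal/cap/day for a
~2,100 kcal reference diet) and are deliberately configurable rather than
hard-coded into the measure engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError


@dataclass
class SynthConfig:
    """Parameters of the synthetic world generator."""

    n_countries: int = 3
    n_cells_per_country: int = 4
    year0: int = 2020
    horizon: int = 2050
    step: int = 5
    seed: int = 0
    income_range: tuple[float, float] = (800.0, 60_000.0)   # USD/cap/yr
    gini_range: tuple[float, float] = (0.28, 0.58)
    # per-main-group linear predictors in log10 income: (intercept, slope)
    diet_regression_coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "animal_source": (-4.2, 1.0),
            "empty_calories": (-2.8, 0.7),
            "staples": (2.2, -0.45),
            "fruits_veg_nuts": (-1.6, 0.35),
        })
    # waste ratio = 1 + span / (1 + exp(-k (log10 y - x0)))
    waste_regression_coeffs: dict[str, float] = field(
        default_factory=lambda: {"span": 0.65, "k": 2.2, "x0": 4.0})
    rr_magnitude_range: tuple[float, float] = (1.1, 2.2)
    obesity_drift: float = 0.004   # per-year BMI-class mass shift in the baseline
    ppp_per_usd_day: float = 1.0 / 365.0  # converts USD/cap/yr to Int$PPP/cap/day

    def validate(self) -> None:
        if self.year0 >= self.horizon:
            raise ConfigError("year0 must be before horizon")
        if (self.horizon - self.year0) % self.step != 0:
            raise ConfigError("horizon - year0 must be divisible by step")
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        if self.n_cells_per_country < 1:
            raise ConfigError("n_cells_per_country must be >= 1")
        lo, hi = self.income_range
        if not (0 < lo < hi):
            raise ConfigError("income_range must be a non-degenerate positive interval")
        glo, ghi = self.gini_range
        if not (0 <= glo < ghi < 1):
            raise ConfigError("gini_range must be non-degenerate within [0, 1)")
        rlo, rhi = self.rr_magnitude_range
        if not (1.0 <= rlo < rhi <= 5.0):
            raise ConfigError("rr_magnitude_range must be non-degenerate within [1, 5]")


# --------------------------------------------------------------------------
# Measure constants. Dietary reference values (kcal/cap/day) are planetary-
# health-diet style defaults; citation-needed in the sense that users working
# with real data should substitute their preferred reference table.
# --------------------------------------------------------------------------
MEASURE_DEFAULTS: dict[str, dict] = {
    # ---- Diets
    "LowProcessed": {
        "sugar_cap": 120.0, "oils_fats_target": 400.0,
        "alcohol_cap_share": 0.014, "full_year": 2050,
    },
    "HighLegumes": {"legumes_floor": 250.0, "full_year": 2050},
    "LowMonogastrics": {"cap": 150.0, "full_year": 2050},   # pig + poultry + eggs
    "LowRuminants": {"cap": 190.0, "full_year": 2050},      # ruminant meat + milk
    "HighVegFruitsNuts": {"floor": 500.0, "full_year": 2050},
    "HalfOverweight": {"reduction": 0.5, "full_year": 2050},
    "NoUnderweight": {"full_year": 2050},
    "LowFoodWaste": {"waste_cap": 0.20, "full_year": 2050},
    # ---- Livelihoods
    "LibTrade": {
        "liberal_pool_target": {"crops": 0.30, "livestock": 0.20}, "full_year": 2050,
    },
    "MinWage": {"min_wage": 3.0, "price_passthrough": 0.5, "full_year": 2050},
    "CapitalSubst": {
        "capital_share_target": 0.20, "gap_closure": 0.5,
        "cost_premium": 0.05, "price_passthrough": 0.5, "full_year": 2050,
    },
    # ---- Biosphere
    "REDD+": {"co2_luc_reduction": 0.7, "revenue_pc": 4.0, "full_year": 2050},
    "LandConservation": {
        "protection_target_share": 0.30, "baseline_protected_share": 0.15,
        "full_year": 2030,
    },
    "PeatlandRewetting": {"co2_peatland_reduction": 0.6, "revenue_pc": 2.0,
                          "full_year": 2050},
    "WaterConservation": {"full_year": 2050},
    "BiodivOffset": {"full_year": 2050},
    # ---- Agriculture
    "NitrogenEff": {"uptake_gain": 0.10, "uptake_cap": 0.75,
                    "cost_premium": 0.02, "price_passthrough": 0.5, "full_year": 2050},
    "CropRotations": {"max_crop_share": 0.25, "revenue_pc": 1.0, "full_year": 2050},
    "LandscapeHabitats": {"potential_cropland_cap": 0.80, "full_year": 2050},
    "RiceMitigation": {"ch4_rice_reduction": 0.4, "cost_premium": 0.01,
                       "price_passthrough": 0.5, "full_year": 2050},
    "LivestockManagement": {"ch4_enteric_reduction": 0.3, "cost_premium": 0.02,
                            "price_passthrough": 0.5, "full_year": 2050},
    "ManureManagement": {"digester_share": 0.5, "digester_recycling": 0.9,
                         "ch4_awms_reduction": 0.5, "cost_premium": 0.01,
                         "price_passthrough": 0.5, "full_year": 2050},
    "SoilCarbon": {"co2_soil_reduction": 0.5, "revenue_pc": 2.0, "full_year": 2050},
    # ---- CrossSector driver swaps
    "Population": {"pop_scale_2050": 0.947, "full_year": 2050},
    "HumanDevelop": {
        "extra_income_growth": 0.35, "gini_reduction": 0.15,
        "uptake_gain": 0.05, "uptake_cap": 0.75,
        "activity_intake_shift": 0.05, "labour_productivity_gain": 0.25,
        "full_year": 2050,
    },
    "EnergyTrans": {"nonag_withdrawal_reduction": 0.20, "bioenergy_boost": 0.5,
                    "full_year": 2050},
    "Bioplastics": {"bioplastics_boost": 1.5, "full_year": 2050},
    "TimberCities": {"timber_boost": 0.8, "full_year": 2050},
}

FSM_NAMES: tuple[str, ...] = (
    "LowProcessed", "HighLegumes", "LowMonogastrics", "LowRuminants",
    "HighVegFruitsNuts", "HalfOverweight", "NoUnderweight", "LowFoodWaste",
    "LibTrade", "MinWage", "CapitalSubst",
    "REDD+", "LandConservation", "PeatlandRewetting", "WaterConservation",
    "BiodivOffset",
    "NitrogenEff", "CropRotations", "LandscapeHabitats", "RiceMitigation",
    "LivestockManagement", "ManureManagement", "SoilCarbon",
)
CROSS_SECTOR_NAMES: tuple[str, ...] = (
    "Population", "HumanDevelop", "EnergyTrans", "Bioplastics", "TimberCities",
)
ALL_MEASURE_NAMES: tuple[str, ...] = FSM_NAMES + CROSS_SECTOR_NAMES

PACKAGES: dict[str, tuple[str, ...]] = {
    "Diets": ("LowProcessed", "HighLegumes", "LowMonogastrics", "LowRuminants",
              "HighVegFruitsNuts", "HalfOverweight", "NoUnderweight", "LowFoodWaste"),
    "Livelihoods": ("LibTrade", "MinWage", "CapitalSubst"),
    "Biosphere": ("REDD+", "LandConservation", "PeatlandRewetting",
                  "WaterConservation", "BiodivOffset"),
    "Agriculture": ("NitrogenEff", "CropRotations", "LandscapeHabitats",
                    "RiceMitigation", "LivestockManagement", "ManureManagement",
                    "SoilCarbon"),
    "CrossSector": CROSS_SECTOR_NAMES,
}
PACKAGES["FST_SSP2"] = (PACKAGES["Diets"] + PACKAGES["Livelihoods"]
                        + PACKAGES["Biosphere"] + PACKAGES["Agriculture"])
PACKAGES["FST_SDP"] = PACKAGES["FST_SSP2"] + PACKAGES["CrossSector"]

# --------------------------------------------------------------------------
# Desirability of indicator changes: encoded as data so the normative choices
# can be contested. "special" indicators follow dedicated classification rules
# in the scenario runner.
# --------------------------------------------------------------------------
LOWER_IS_BETTER: tuple[str, ...] = (
    "underweight", "obesity", "premature_mortality", "nitrogen_surplus",
    "efr_violations", "ghg_emissions", "ag_expenditure", "poverty", "factor_use",
)
HIGHER_IS_BETTER: tuple[str, ...] = (
    "bii_cropland", "bii_hotspot", "crop_diversity", "ag_wages", "bioeconomy_supply",
)
SPECIAL_INDICATORS: tuple[str, ...] = ("ag_labour",)

# neutral band per indicator: |delta| below this counts as neutral
CLASSIFICATION_EPS: dict[str, float] = {
    "underweight": 0.01, "obesity": 0.01, "premature_mortality": 0.01,
    "bii_cropland": 1e-4, "bii_hotspot": 1e-4, "crop_diversity": 1e-4,
    "nitrogen_surplus": 1e-4, "efr_violations": 1e-6, "ghg_emissions": 1e-4,
    "ag_expenditure": 0.01, "poverty": 0.01, "ag_labour": 0.01,
    "ag_wages": 1e-4, "bioeconomy_supply": 1e-3, "factor_use": 1e-3,
}

# expenditure-shock parameters of the income/poverty coupling
POVERTY_COUPLING: dict[str, float] = {
    "engel_elasticity": 0.8,   # food expenditure-income elasticity in (0, 1]
    "quantile_grid": 1000.0,
}
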