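"""Shared enumerations and physical constants for the food-system toolkit.

Cohorts, BMI classes, food items, land classes, emission sources and the
risk-factor/endpoint sets used throughout the package. These are the fixed
dimensions of the world state; anything tunable lives in :mod:`fstkit.config`.
"""

from __future__ import annotations

# ---------------------------------------------------------------- demography
AGE_GROUPS: tuple[str, ...] = ("0-14", "15-29", "30-44", "45-59", "60-74", "75+")
ADULT_AGE_GROUPS: tuple[str, ...] = AGE_GROUPS[1:]
SEXES: tuple[str, ...] = ("F", "M")
COHORTS: tuple[tuple[str, str], ...] = tuple((a, s) for a in AGE_GROUPS for s in SEXES)

# Five BMI classes; adult boundaries at 18.5 / 20 / 25 / 30. The lowest class
# (< 18.5) is what the underweight headcount indicator counts; the measure that
# eradicates underweight lifts both sub-20 classes. Children use +-1 / +-2 s.d.
# bands in the same five slots.
BMI_CLASSES: tuple[str, ...] = (
    "underweight",      # BMI < 18.5  (children: < -2 s.d.)
    "below_healthy",    # 18.5 <= BMI < 20  (children: -2..-1 s.d.)
    "healthy",          # 20 <= BMI <= 25
    "overweight",       # 25 < BMI <= 30  (children: +1..+2 s.d.)
    "obese",            # BMI > 30  (children: > +2 s.d.)
)
HEALTHY_CLASS = "healthy"
BELOW_HEALTHY_CLASSES: tuple[str, ...] = ("underweight", "below_healthy")
ABOVE_HEALTHY_CLASSES: tuple[str, ...] = ("overweight", "obese")

# ---------------------------------------------------------------- diet items
ANIMAL_ITEMS: tuple[str, ...] = ("ruminant_meat", "milk", "pig_meat", "poultry_meat", "eggs")
EMPTY_CALORIE_ITEMS: tuple[str, ...] = ("sugar", "oils_fats", "alcohol")
STAPLE_ITEM = "staples"           # cereals, roots, tubers: the compensation pool
LEGUME_ITEM = "legumes"
FRUITVEG_ITEM = "fruits_veg_nuts"

DIET_ITEMS: tuple[str, ...] = (
    ANIMAL_ITEMS + EMPTY_CALORIE_ITEMS + (STAPLE_ITEM, LEGUME_ITEM, FRUITVEG_ITEM)
)

# The four main groups of the demand regressions.
MAIN_GROUPS: tuple[str, ...] = ("animal_source", "empty_calories", "staples", "fruits_veg_nuts")
GROUP_ITEMS: dict[str, tuple[str, ...]] = {
    "animal_source": ANIMAL_ITEMS,
    "empty_calories": EMPTY_CALORIE_ITEMS,
    "staples": (STAPLE_ITEM, LEGUME_ITEM),
    "fruits_veg_nuts": (FRUITVEG_ITEM,),
}

RUMINANT_ITEMS: tuple[str, ...] = ("ruminant_meat", "milk")
MONOGASTRIC_ITEMS: tuple[str, ...] = ("pig_meat", "poultry_meat", "eggs")
RED_MEAT_ITEMS: tuple[str, ...] = ("ruminant_meat", "pig_meat")

# ---------------------------------------------------------------- land
CROP_CLASSES: tuple[str, ...] = (
    "temperate_cereals", "tropical_cereals", "rice", "oil_crops",
    "roots_tubers", "sugar_crops", "pulses", "fruit_veg_crops",
)
FALLOW_CLASS = "fallow"
CROPLAND_CLASSES: tuple[str, ...] = CROP_CLASSES + (FALLOW_CLASS,)
NATURAL_CLASSES: tuple[str, ...] = ("forest_old", "forest_young", "other_natural")
LAND_CLASSES: tuple[str, ...] = CROPLAND_CLASSES + ("pasture",) + NATURAL_CLASSES + ("built_up",)

# Intactness of each land class relative to undisturbed vegetation (= 1 for the
# reference classes). Managed classes retain only part of original abundance.
DEFAULT_INTACTNESS: dict[str, float] = {
    **{c: 0.30 for c in CROP_CLASSES},
    FALLOW_CLASS: 0.45,
    "pasture": 0.60,
    "forest_old": 1.0,
    "forest_young": 0.85,
    "other_natural": 1.0,
    "built_up": 0.05,
}

# ---------------------------------------------------------------- emissions
GASES: tuple[str, ...] = ("co2", "ch4", "n2o")
EMISSION_SOURCES: tuple[str, ...] = (
    "co2.luc", "co2.peatland", "co2.soil",
    "ch4.enteric", "ch4.rice", "ch4.awms",
    "n2o.soil", "n2o.awms",
)
# AR6 100-year global warming potentials.
DEFAULT_GWP100: dict[str, float] = {"co2": 1.0, "ch4": 27.0, "n2o": 273.0}

# ---------------------------------------------------------------- health
RISK_FACTORS: tuple[str, ...] = (
    "red_meat_high",
    "fruits_low", "vegetables_low", "nuts_low", "legumes_low",
    "underweight", "overweight", "obese",
)
DIETARY_FACTORS: tuple[str, ...] = RISK_FACTORS[:5]
WEIGHT_FACTORS: tuple[str, ...] = RISK_FACTORS[5:]
ENDPOINTS: tuple[str, ...] = ("chd", "stroke", "t2dm", "cancer", "respiratory")
# Colorectal cancer is reported as a slice of aggregate cancer, not an extra
# endpoint; the share used when reporting it separately is configurable.
N_EXPOSURE_CATEGORIES = 4  # category 0 is the TMREL for every factor

# ---------------------------------------------------------------- bioeconomy
BIOECONOMY_PRODUCTS: tuple[str, ...] = ("bioenergy", "bioplastics", "timber", "material")
FACTOR_KINDS: tuple[str, ...] = ("labour", "capital", "intermediates")

KCAL_PER_DAY_TO_YEAR = 365.0
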