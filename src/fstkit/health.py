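"""Comparative risk assessment: exposure -> impact fractions -> deaths -> YLL.

Eight diet- and weight-related risk factors (high red meat; low fruits,
vegetables, nuts and legumes; underweight, overweight, obese) act on five
disease endpoints (coronary heart disease, stroke, type 2 diabetes, cancer in
aggregate, respiratory disease). A potential impact fraction (PIF) compares a
baseline exposure distribution P with a counterfactual P':

    PIF = (sum P RR - sum P' RR) / (sum P RR)

PIFs combine multiplicatively across risk factors (1 - prod(1 - PIF_i), the
GBD convention); attributable deaths are rate x population x PIF per stratum
and are weighted by standard remaining life expectancy to give years of life
lost (YLL).
"""

from __future__ import annotations

import numpy as np

from . import constants as C
from .errors import ValidationError
from .world import CountryState, LifeTable, RiskModel


# --------------------------------------------------------------- primitives
def potential_impact_fraction(p: np.ndarray, p_cf: np.ndarray,
                              rr: np.ndarray) -> float:
    """PIF of shifting exposure shares from ``p`` to ``p_cf`` given RRs.

    All three arrays run over the same exposure categories (last axis when
    multidimensional). PIF <= 1; negative values mean the counterfactual is
    worse than the baseline.
    """
    p, p_cf, rr = (np.asarray(a, dtype=float) for a in (p, p_cf, rr))
    if not (p.shape == p_cf.shape == rr.shape):
        raise ValidationError(
            f"category sets do not match: {p.shape}, {p_cf.shape}, {rr.shape}")
    base = float(np.sum(p * rr))
    if base <= 0:
        raise ValidationError("baseline exposure-weighted risk must be positive")
    return (base - float(np.sum(p_cf * rr))) / base


def combine_pifs(pifs) -> float:
    """Multiplicative combination across factors: 1 - prod(1 - PIF_i)."""
    out = 1.0
    for p in pifs:
        if p > 1.0 + 1e-12:
            raise ValidationError(f"PIF {p} exceeds 1")
        out *= (1.0 - p)
    return 1.0 - out


def attributable_deaths(rate: float, population: float, pif: float) -> float:
    """Deaths averted (positive PIF) or added in one stratum."""
    if rate < 0 or population < 0:
        raise ValidationError("rates and populations must be non-negative")
    return rate * population * pif


def years_of_life_lost(deaths_by_age: dict[str, float], life_table: LifeTable) -> float:
    """YLL = sum_a deaths_a * e*_a over age groups."""
    total = 0.0
    for age, deaths in deaths_by_age.items():
        if age not in life_table.remaining:
            raise ValidationError(f"age group {age} missing from life table")
        total += deaths * life_table.remaining[age]
    return total


# ---------------------------------------------------- exposure construction
def _dietary_exposure_value(country: CountryState, factor: str) -> float:
    """kcal/cap/day of the item(s) a dietary risk factor is driven by.

    The fruits/vegetables/nuts aggregate is split by fixed shares (0.4 fruits,
    0.4 vegetables, 0.2 nuts), a documented simplification of the synthetic
    diet's granularity.
    """
    diet = country.diet
    if factor == "red_meat_high":
        return diet.items_total(C.RED_MEAT_ITEMS)
    if factor == "legumes_low":
        return diet.intake[C.LEGUME_ITEM]
    fvn = diet.intake[C.FRUITVEG_ITEM]
    return {"fruits_low": 0.4 * fvn, "vegetables_low": 0.4 * fvn,
            "nuts_low": 0.2 * fvn}[factor]


def categorise(value: float, breaks: list[float], direction: str) -> int:
    """Exposure category of a continuous intake. Category 0 is the TMREL.

    For ``high``-harmful factors the category counts ascending breakpoints
    crossed; for ``low``-harmful factors it counts how far intake falls below
    descending breakpoints.
    """
    if direction == "high":
        return int(np.searchsorted(np.asarray(breaks), value, side="right"))
    cat = 0
    for b in breaks:  # descending thresholds
        if value < b:
            cat += 1
    return cat


def exposure_weights(value: float, breaks: list[float], direction: str,
                     tmrel: float) -> np.ndarray:
    """Fractional category weights for a continuous intake.

    The intake is mapped to a continuous coordinate (0 at the TMREL, k at the
    k-th breakpoint) and its mass split between the two neighbouring
    categories, so relative risk responds log-linearly to intake between
    category anchors instead of jumping at breakpoints.
    """
    n_cat = C.N_EXPOSURE_CATEGORIES
    coords = np.arange(n_cat, dtype=float)
    if direction == "high":
        anchors = np.array([tmrel] + list(breaks), dtype=float)
        x = float(np.interp(value, anchors, coords))
    else:
        anchors = -np.array([tmrel] + list(breaks), dtype=float)  # ascending
        x = float(np.interp(-value, anchors, coords))
    lo = int(np.floor(x))
    hi = min(lo + 1, n_cat - 1)
    w = np.zeros(n_cat)
    frac = x - lo
    w[lo] += 1.0 - frac
    w[hi] += frac
    return w


def exposure_from_country(country: CountryState, risk_model: RiskModel) -> dict[str, np.ndarray]:
    """Exposure share arrays (n adult ages, n sexes, n categories) per factor.

    Dietary exposures spread the national intake fractionally across the two
    neighbouring categories (shared across adult cohorts); weight exposures
    put each cohort's BMI-class mass into the exposed category.
    """
    n_age, n_sex, n_cat = (len(C.ADULT_AGE_GROUPS), len(C.SEXES),
                           C.N_EXPOSURE_CATEGORIES)
    out: dict[str, np.ndarray] = {}
    for factor in C.DIETARY_FACTORS:
        val = _dietary_exposure_value(country, factor)
        w = exposure_weights(val, risk_model.category_breaks[factor],
                             risk_model.direction[factor],
                             risk_model.tmrel[factor])
        arr = np.broadcast_to(w, (n_age, n_sex, n_cat)).copy()
        out[factor] = arr
    cls_index = {"underweight": 0, "overweight": 3, "obese": 4}
    for factor in C.WEIGHT_FACTORS:
        arr = np.zeros((n_age, n_sex, n_cat))
        for ia, age in enumerate(C.ADULT_AGE_GROUPS):
            for isx, sex in enumerate(C.SEXES):
                share = float(country.bmi_shares((age, sex))[cls_index[factor]])
                # exposed mass in the top category, the rest at TMREL
                arr[ia, isx, n_cat - 1] = share
                arr[ia, isx, 0] = 1.0 - share
        out[factor] = arr
    return out


def tmrel_exposure() -> np.ndarray:
    """Counterfactual with all mass at the theoretical-minimum-risk category."""
    arr = np.zeros((len(C.ADULT_AGE_GROUPS), len(C.SEXES), C.N_EXPOSURE_CATEGORIES))
    arr[..., 0] = 1.0
    return arr


# ------------------------------------------------------------- aggregation
def attributable_yll(country: CountryState, risk_model: RiskModel,
                     life_table: LifeTable,
                     counterfactual: dict[str, np.ndarray] | None = None) -> float:
    """Years of life lost attributable to the risk factors in one country.

    Compares the country's exposure with the TMREL counterfactual (or a
    supplied one) and sums rate x population x combined-PIF x e* over
    endpoints, adult age groups and sexes. Sign convention: the indicator is
    the burden of current exposure, so the PIF of moving *to* the TMREL is the
    attributable fraction.
    """
    exposure = exposure_from_country(country, risk_model)
    cf = counterfactual if counterfactual is not None else {
        f: tmrel_exposure() for f in C.RISK_FACTORS}
    total = 0.0
    for endpoint in C.ENDPOINTS:
        for ia, age in enumerate(C.ADULT_AGE_GROUPS):
            for isx, sex in enumerate(C.SEXES):
                pifs = []
                for factor in C.RISK_FACTORS:
                    rr = risk_model.rr[factor][endpoint][ia, isx]
                    pifs.append(potential_impact_fraction(
                        exposure[factor][ia, isx], cf[factor][ia, isx], rr))
                pif = combine_pifs(pifs)
                rate = country.mortality_rate(endpoint, age, sex)
                pop = country.cohort_population((age, sex))
                deaths = attributable_deaths(rate, pop, pif)
                total += deaths * life_table.remaining[age]
    return total
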