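"""Food demand and anthropometrics.

Dietary composition and waste regressions, BMI-class intake accounting and the
underweight/obesity headcounts. The demand system is price inelastic: diets
respond to income only, never to prices.

The regression functional forms are saturating in log income: main-group
calorie shares come from a softmax over affine predictors in log10 income
(reproducing the nutrition transition, with the animal-source share rising in
income), and the waste ratio is a scaled logistic with lower asymptote 1.
"""

from __future__ import annotations

import numpy as np

from . import constants as C
from .errors import DomainError, ValidationError
from .world import CountryState, DietProfile


def project_diet_composition(income_pc: float,
                             coeffs: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Main-group calorie shares at a per-capita income (USD/yr).

    Softmax of per-group affine predictors in log10 income; shares are
    non-negative and sum to one by construction.
    """
    if income_pc <= 0:
        raise DomainError("income must be positive")
    x = np.log10(income_pc)
    groups = list(C.MAIN_GROUPS)
    z = np.array([coeffs[g][0] + coeffs[g][1] * x for g in groups])
    z -= z.max()  # numerical stability
    w = np.exp(z)
    shares = w / w.sum()
    return dict(zip(groups, shares.tolist()))


def project_waste_ratio(income_pc: float, coeffs: dict[str, float]) -> float:
    """Food waste ratio (supply per unit intake) at a per-capita income.

    ``1 + span / (1 + exp(-k (log10 y - x0)))``: approaches 1 at minimal
    income and ``1 + span`` at high income, non-decreasing throughout.
    """
    if income_pc <= 0:
        raise DomainError("income must be positive")
    x = np.log10(income_pc)
    return float(1.0 + coeffs["span"] / (1.0 + np.exp(-coeffs["k"] * (x - coeffs["x0"]))))


def _headcount(country: CountryState, classes: tuple[str, ...],
               adults_only: bool = False) -> float:
    total = 0.0
    idx = [C.BMI_CLASSES.index(c) for c in classes]
    for cohort in C.COHORTS:
        if adults_only and cohort[0] == "0-14":
            continue
        shares = country.bmi_shares(cohort)
        if abs(shares.sum() - 1.0) > 1e-9 or (shares < -1e-12).any():
            raise ValidationError(f"malformed BMI distribution for cohort {cohort}")
        pop = country.cohort_population(cohort)
        total += pop * float(shares[idx].sum())
    return total


def count_underweight(country: CountryState) -> float:
    """Persons below the underweight threshold (adults: BMI strictly < 18.5;
    children: 2 s.d. below normal). Only the lowest of the five BMI classes
    counts; someone exactly at the threshold belongs to the class above."""
    return _headcount(country, ("underweight",))


def count_obese(country: CountryState) -> float:
    """Persons above the obesity threshold (adults: BMI strictly > 30;
    children: 2 s.d. above normal)."""
    return _headcount(country, ("obese",))


def supply_from_intake(diet: DietProfile) -> float:
    """Total food calorie supply per capita per day: intake times waste ratio."""
    diet.validate()
    return diet.supply()


def build_diet(income_pc: float, total_intake: float,
               comp_coeffs: dict[str, tuple[float, float]],
               waste_coeffs: dict[str, float],
               within_group_shares: dict[str, dict[str, float]]) -> DietProfile:
    """Assemble a DietProfile from the regressions and within-group item shares."""
    shares = project_diet_composition(income_pc, comp_coeffs)
    intake: dict[str, float] = {}
    for group, items in C.GROUP_ITEMS.items():
        g_total = shares[group] * total_intake
        sub = within_group_shares[group]
        for item in items:
            intake[item] = g_total * sub[item]
    return DietProfile(intake, project_waste_ratio(income_pc, waste_coeffs))
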