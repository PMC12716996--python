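"""Lognormal income-distribution model.

Incomes within a country follow a lognormal distribution parameterised by the
mean income and the Gini coefficient through the standard identity
``G = 2 Phi(sigma / sqrt 2) - 1``. Poverty headcounts are lognormal CDF
evaluations; food-price shocks act quantile-wise through an Engel-curve food
share and the distribution is then re-summarised (mean, Gini) by numerical
Lorenz integration on a quantile grid.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .errors import DomainError, MeasureInfeasibleError
from .world import IncomeDistribution

_SQRT2 = math.sqrt(2.0)


def sigma_from_gini(gini: float) -> float:
    """Lognormal sigma from the Gini coefficient: sigma = sqrt(2) PhiInv((G+1)/2)."""
    if not (0.0 <= gini < 1.0):
        raise DomainError(f"gini {gini} outside [0, 1)")
    return _SQRT2 * float(stats.norm.ppf((gini + 1.0) / 2.0))


def gini_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_gini`: G = 2 Phi(sigma / sqrt 2) - 1."""
    if sigma < 0:
        raise DomainError("sigma must be non-negative")
    return float(2.0 * stats.norm.cdf(sigma / _SQRT2) - 1.0)


def lognormal_params(dist: IncomeDistribution) -> tuple[float, float]:
    """(mu, sigma) with mean = exp(mu + sigma^2 / 2)."""
    sigma = sigma_from_gini(dist.gini)
    mu = math.log(dist.mean_income) - 0.5 * sigma ** 2
    return mu, sigma


def poverty_headcount(dist: IncomeDistribution, line: float | None = None) -> float:
    """Persons with daily income below the poverty line.

    ``population * Phi((ln line - mu) / sigma)``; in the degenerate
    zero-dispersion limit everyone sits at the mean.
    """
    if line is None:
        line = dist.poverty_line
    if line <= 0:
        raise DomainError("poverty line must be positive")
    mu, sigma = lognormal_params(dist)
    if sigma == 0.0:
        return dist.population if line > dist.mean_income else 0.0
    z = (math.log(line) - mu) / sigma
    return dist.population * float(stats.norm.cdf(z))


def _quantile_incomes(dist: IncomeDistribution, n: int) -> np.ndarray:
    """Income at n mid-quantiles of the lognormal."""
    mu, sigma = lognormal_params(dist)
    q = (np.arange(n) + 0.5) / n
    return np.exp(mu + sigma * stats.norm.ppf(q))


def _summarise_quantiles(y: np.ndarray) -> tuple[float, float]:
    """Mean and Gini of an income vector on an equal-mass quantile grid.

    Gini by trapezoidal integration of the Lorenz curve of the sorted incomes.
    """
    y = np.sort(y)
    mean = float(y.mean())
    cum = np.concatenate([[0.0], np.cumsum(y)]) / y.sum()
    p = np.linspace(0.0, 1.0, len(y) + 1)
    lorenz_area = float(np.trapezoid(cum, p))
    return mean, 1.0 - 2.0 * lorenz_area


def apply_expenditure_shock(dist: IncomeDistribution, price_change: float,
                            elasticity: float, n_grid: int = 1000) -> IncomeDistribution:
    """Real-income effect of a relative food-price (expenditure) change.

    Quantile-wise ``y' = y (1 - s(y) pi)`` with the food share following a
    power-law Engel curve ``s(y) = s_bar (y / mean)^(elasticity - 1)`` capped
    at 0.95. With ``elasticity < 1`` the share falls with income, so a price
    increase is regressive: the Gini and the headcount weakly increase.
    """
    if not (0.0 < elasticity <= 1.0):
        raise DomainError("elasticity must be in (0, 1]")
    if price_change == 0.0:
        return dist.copy()
    y = _quantile_incomes(dist, n_grid)
    s = dist.food_share * (y / dist.mean_income) ** (elasticity - 1.0)
    s = np.minimum(s, 0.95)
    y_new = y * (1.0 - s * price_change)
    if np.any(y_new <= 0):
        raise MeasureInfeasibleError("expenditure shock drives incomes non-positive")
    # difference against the unshocked grid so the finite-grid bias of the
    # Lorenz integration cancels: a homothetic shock leaves the Gini exact
    mean0, gini0 = _summarise_quantiles(y)
    mean1, gini1 = _summarise_quantiles(y_new)
    out = dist.copy()
    out.mean_income = dist.mean_income * (mean1 / mean0)
    out.gini = min(max(dist.gini + (gini1 - gini0), 0.0), 0.999)
    return out


def recycle_revenue(dist: IncomeDistribution, revenue_per_capita: float) -> IncomeDistribution:
    """Distributionally neutral recycling of revenue (Int$PPP/cap/day).

    Every quantile is scaled by ``1 + revenue / mean``, so the Gini is exactly
    unchanged and the mean rises by the recycled amount.
    """
    if revenue_per_capita < 0:
        raise DomainError("revenue must be non-negative")
    out = dist.copy()
    out.mean_income = dist.mean_income + revenue_per_capita
    return out
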