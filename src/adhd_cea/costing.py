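"""Severity-based allocation of annual medical costs and drug-cost weighting.

Annual ADHD-management costs are published only as medians/means for
children with and without ADHD, so the model allocates them to the four
severity states:

* Normal   — the non-ADHD median ($245/year in the base case).
* Mild     — the mean of the non-ADHD median and the linearly interpolated
  cost of the patient at the percentile equal to the initial Mild share
  (3.52% → the "3.52th patient" between the $245 minimum and the $322
  ADHD median).
* Severe   — a skewness multiplier (2x) times the ADHD mean ($738/year).
* Moderate — back-solved so the initial-distribution-weighted mean of the
  state costs reproduces the ADHD mean exactly (the Normal initial mass is
  zero in the trial population).

Annual costs divide by 52 to give the weekly cycle costs; the daily drug
cost of the stimulant class is the market-share-weighted average over the
long-acting products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import N_STATES, STATE_NAMES

__all__ = [
    "CostAllocationInputs",
    "interpolate_percentile_cost",
    "derive_annual_state_costs",
    "annual_to_weekly",
    "weighted_daily_drug_cost",
    "productivity_from_ratios",
]

WEEKS_PER_YEAR = 52


class AllocationError(ValueError):
    """The severity allocation is unsolvable for the given inputs."""


@dataclass
class CostAllocationInputs:
    """Inputs for allocating annual medical costs across severity states."""

    nonadhd_median_annual: float = 245.0
    adhd_median_annual: float = 322.0
    adhd_mean_annual: float = 738.0
    severe_multiplier: float = 2.0
    mild_percentile: float | None = None  # defaults to 100 x initial Mild mass
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.adhd_median_annual < self.nonadhd_median_annual:
            raise ValueError("ADHD median cost must be >= the non-ADHD median (minimum) cost")
        if self.adhd_mean_annual <= 0:
            raise ValueError("mean annual cost must be positive")
        if self.severe_multiplier <= 0:
            raise ValueError("severe multiplier must be positive")


def interpolate_percentile_cost(min_cost: float, median_cost: float, percentile: float) -> float:
    """Annual cost of the patient at ``percentile`` (0..50) of a linear cost ramp.

    Linear interpolation between the minimum (percentile 0) and the median
    (percentile 50): ``min + (median - min) * percentile / 50``.
    """
    if not 0 <= percentile <= 50:
        raise ValueError(f"percentile must be in [0, 50], got {percentile}")
    if median_cost < min_cost:
        raise ValueError("median cost must be >= minimum cost")
    return min_cost + (median_cost - min_cost) * percentile / 50.0


def derive_annual_state_costs(inputs: CostAllocationInputs) -> np.ndarray:
    """Allocate annual medical costs to the four severity states.

    Returns the array (Normal, Mild, Moderate, Severe) of annual $CA costs.
    Moderate is back-solved from the weighted-mean identity
    sum_s pi0(s) * cost(s) = adhd_mean_annual.
    """
    pi0 = inputs.initial_distribution
    if pi0 is None:
        raise AllocationError("an initial distribution is required to back-solve the Moderate cost")
    pi0 = np.asarray(pi0, dtype=float)
    if pi0.shape != (N_STATES,):
        raise AllocationError(f"initial distribution must have {N_STATES} entries")
    if pi0[1] <= 0 or pi0[2] <= 0:
        raise AllocationError("Mild and Moderate initial masses must be positive")

    pct = 100.0 * pi0[1] if inputs.mild_percentile is None else inputs.mild_percentile
    normal = inputs.nonadhd_median_annual
    mild = 0.5 * (
        normal + interpolate_percentile_cost(normal, inputs.adhd_median_annual, pct)
    )
    severe = inputs.severe_multiplier * inputs.adhd_mean_annual
    moderate = (
        inputs.adhd_mean_annual - pi0[0] * normal - pi0[1] * mild - pi0[3] * severe
    ) / pi0[2]
    if moderate < 0:
        raise AllocationError(
            f"back-solved Moderate cost is negative ({moderate:.2f}); "
            "the mean is too small for the Mild/Severe allocations"
        )
    return np.array([normal, mild, moderate, severe])


def annual_to_weekly(annual: float | np.ndarray) -> float | np.ndarray:
    """Convert an annual cost to the weekly cycle cost (divide by 52)."""
    annual = np.asarray(annual, dtype=float)
    if np.any(annual < 0):
        raise ValueError("annual cost must be non-negative")
    weekly = annual / WEEKS_PER_YEAR
    return float(weekly) if weekly.ndim == 0 else weekly


def weighted_daily_drug_cost(market: dict[str, dict[str, float]]) -> float:
    """Market-share-weighted average daily drug cost over products.

    ``market`` maps product name to {"daily_cost": $/day, "share": fraction};
    shares are normalized to sum to 1.
    """
    if not market:
        raise ValueError("at least one product is required")
    shares = np.array([p["share"] for p in market.values()], dtype=float)
    costs = np.array([p["daily_cost"] for p in market.values()], dtype=float)
    if np.any(shares < 0) or np.any(costs < 0):
        raise ValueError("shares and costs must be non-negative")
    total = shares.sum()
    if total <= 0:
        raise ValueError("market shares sum to zero; cannot weight costs")
    return float(np.dot(shares / total, costs))


def productivity_from_ratios(annual_state_costs: np.ndarray, base_weekly_productivity: float) -> np.ndarray:
    """Optional helper: scale a base weekly productivity loss by the ratio of
    each state's annual medical cost to the distribution mean of those costs.

    The published weekly productivity values are model inputs; this helper
    only illustrates one ratio-based derivation and is not used by the
    base-case pipeline.
    """
    costs = np.asarray(annual_state_costs, dtype=float)
    return base_weekly_productivity * costs / costs.mean()


def allocation_table(inputs: CostAllocationInputs) -> "list[dict[str, float | str]]":
    """Annual and weekly allocated medical costs as table rows."""
    annual = derive_annual_state_costs(inputs)
    weekly = annual_to_weekly(annual)
    return [
        {"state": STATE_NAMES[i], "annual": float(annual[i]), "weekly": float(weekly[i])}
        for i in range(N_STATES)
    ]
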