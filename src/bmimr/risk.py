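"""Translation between MR odds ratios and relative/absolute risk changes.

Given a diabetes odds ratio beta per 1 kg/m^2 of BMI and a baseline
prevalence P, and making the rare-disease approximation that the odds ratio
approximates the relative risk, a BMI reduction of delta kg/m^2 implies

* relative risk reduction  1 - beta^(-delta),
* prevalence after change  P / beta^delta,
* absolute risk reduction  P - P / beta^delta,

and the inverse problems solve for the BMI (hence weight) change achieving a
target reduction. Confidence intervals are propagated by evaluating at the
odds ratio's CI bounds (all maps are monotone in beta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import math

from ._utils import round_half_away

KG_PER_LB = 0.45359237  # exact by definition


@dataclass(frozen=True)
class WeightChange:
    """A weight change for an individual of given height."""

    kg: float
    height_m: float

    def __post_init__(self) -> None:
        if self.kg < 0:
            raise ValueError("weight change must be nonnegative")
        if not (1.0 < self.height_m < 2.5):
            raise ValueError("height must lie in (1.0, 2.5) meters")

    @classmethod
    def from_lbs(cls, lbs: float, height_m: float) -> "WeightChange":
        return cls(lbs * KG_PER_LB, height_m)

    @property
    def lbs(self) -> float:
        return self.kg / KG_PER_LB

    @property
    def delta_bmi(self) -> float:
        return self.kg / self.height_m**2


def _check(or_per_unit: float, delta_bmi: float) -> None:
    if or_per_unit <= 0:
        raise ValueError("odds ratio must be positive")
    if delta_bmi < 0:
        raise ValueError("BMI reduction must be nonnegative")


def relative_risk_reduction(or_per_unit: float, delta_bmi: float) -> float:
    """Fractional risk reduction from a delta kg/m^2 BMI decrease: 1 - beta^-delta."""
    _check(or_per_unit, delta_bmi)
    return 1.0 - or_per_unit ** (-delta_bmi)


def prevalence_after(prevalence: float, or_per_unit: float, delta_bmi: float) -> float:
    """Prevalence after a delta kg/m^2 BMI decrease: P / beta^delta."""
    _check(or_per_unit, delta_bmi)
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    return prevalence / or_per_unit**delta_bmi


def absolute_risk_reduction(prevalence: float, or_per_unit: float, delta_bmi: float) -> float:
    """Reduction in prevalence (percentage points as a fraction): P - P/beta^delta."""
    return prevalence - prevalence_after(prevalence, or_per_unit, delta_bmi)


def bmi_for_relative_reduction(or_per_unit: float, target: float) -> float:
    """BMI decrease (kg/m^2) achieving a target relative risk reduction."""
    if not (0.0 < target < 1.0):
        raise ValueError("target relative reduction must lie in (0, 1)")
    if or_per_unit <= 1.0:
        raise ValueError("no risk reduction achievable for an odds ratio <= 1")
    return math.log(1.0 / (1.0 - target)) / math.log(or_per_unit)


def weight_for_relative_reduction(
    or_per_unit: float, target: float, height_m: float
) -> Tuple[float, float]:
    """(kg, lbs) of weight loss achieving a target relative risk reduction."""
    delta = bmi_for_relative_reduction(or_per_unit, target)
    kg = delta * height_m**2
    return kg, kg / KG_PER_LB


def weight_for_absolute_reduction(
    prevalence: float, or_per_unit: float, target_pp: float, height_m: float
) -> Tuple[float, float]:
    """(kg, lbs) of weight loss reducing prevalence by target_pp (a fraction)."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    if not (0.0 < target_pp < prevalence):
        raise ValueError("target absolute reduction must lie in (0, prevalence)")
    if or_per_unit <= 1.0:
        raise ValueError("no risk reduction achievable for an odds ratio <= 1")
    delta = math.log(prevalence / (prevalence - target_pp)) / math.log(or_per_unit)
    kg = delta * height_m**2
    return kg, kg / KG_PER_LB


def propagate_ci(op: Callable[[float], object], or_ci: Tuple[float, float]):
    """Evaluate a beta-monotone operation at both CI bounds of the odds ratio.

    Returns the two results ordered low-to-high (bounds invert for the
    weight-needed operations, where a weaker odds ratio implies more weight).
    Scalar results are ordered directly; tuple results (kg, lbs) element-wise.
    """
    lo_b, hi_b = or_ci
    if not (0 < lo_b <= hi_b):
        raise ValueError("invalid odds-ratio confidence interval")
    a, b = op(lo_b), op(hi_b)
    if isinstance(a, tuple):
        pairs = [tuple(sorted(p)) for p in zip(a, b)]
        return tuple(p[0] for p in pairs), tuple(p[1] for p in pairs)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Rendering helpers (table dialects)


def render_percent(x: float, decimals: int = 0) -> str:
    """Render a fraction as a percentage, rounding half away from zero."""
    v = round_half_away(100.0 * x, decimals)
    return f"{v:.{decimals}f}%"


def render_weight(kg: float) -> str:
    """Render a weight as 'L lbs/K kg'.

    Pounds are rounded to integer first and the displayed kilograms derived
    from the *rounded* pounds, which reproduces printed pairings such as
    "14 lbs/6 kg" that direct kg-rounding would not.
    """
    lbs_r = int(round_half_away(kg / KG_PER_LB))
    kg_r = int(round_half_away(lbs_r * KG_PER_LB))
    return f"{lbs_r} lbs/{kg_r} kg"
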