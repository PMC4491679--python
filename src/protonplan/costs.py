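"""Out-of-pocket cost savings from hypofractionated treatment courses.

A patient travelling to a proton centre pays for meals, lodging, and lost
wages for every calendar day of the treatment course.  The calendar model is
deliberately simple: fractions are delivered on consecutive treatment days
starting a Monday, ``fractions_per_week`` per week (default 5, i.e.
weekday-only), with the remaining days of each week counted as non-treatment
days inside the span.  The delivery span for ``n`` fractions is therefore

    span(n) = n + (7 - fractions_per_week) * floor((n - 1) / fractions_per_week)

(with 5 fractions/week: ``n + 2*floor((n-1)/5)``), plus a fixed number of
planning days (CT simulation and treatment planning) for the full course.
Planning days cancel in any between-regimen savings comparison.

Default per-diem rates reflect US government rates near proton centres:
meals and incidentals $51-$71/day, lodging $80-$185/day, and lost wages
$200/day (a $52,100 median household income over ~260.5 working days).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CostParameters",
    "SavingsReport",
    "treatment_calendar_days",
    "savings",
    "annual_wage_to_daily",
]

WORKDAYS_PER_YEAR = 260.5


class CostModelError(ValueError):
    """Raised for invalid cost parameters or degenerate comparisons."""


@dataclass(frozen=True)
class CostParameters:
    """Per-diem rates (USD) and calendar structure of a treatment course."""

    meals_per_day: tuple[float, float] = (51.0, 71.0)
    lodging_per_day: tuple[float, float] = (80.0, 185.0)
    wage_per_day: float = 200.0
    planning_days: int = 5
    fractions_per_week: int = 5

    def __post_init__(self) -> None:
        for name in ("meals_per_day", "lodging_per_day"):
            low, high = getattr(self, name)
            if low < 0 or high < low:
                raise CostModelError(f"{name} must satisfy 0 <= low <= high, got ({low}, {high})")
        if self.wage_per_day < 0:
            raise CostModelError(f"wage_per_day must be non-negative, got {self.wage_per_day}")
        if self.planning_days < 0:
            raise CostModelError(f"planning_days must be non-negative, got {self.planning_days}")
        if not 1 <= self.fractions_per_week <= 7:
            raise CostModelError(
                f"fractions_per_week must be in 1..7, got {self.fractions_per_week}"
            )


def _delivery_span(n_fractions: int, params: CostParameters) -> int:
    rest = 7 - params.fractions_per_week
    return n_fractions + rest * ((n_fractions - 1) // params.fractions_per_week)


def treatment_calendar_days(n_fractions: int, params: CostParameters = CostParameters()) -> int:
    """Total calendar days for a course: delivery span plus planning days.

    The span counts first through last treatment day inclusive, including
    intervening non-treatment days (weekends under the default calendar).
    """
    if int(n_fractions) != n_fractions or n_fractions < 1:
        raise CostModelError(f"n_fractions must be a positive integer, got {n_fractions}")
    return _delivery_span(int(n_fractions), params) + params.planning_days


@dataclass(frozen=True)
class SavingsReport:
    """Unreimbursed-cost savings from shortening a treatment course.

    Monetary fields are ``days_saved`` times the corresponding per-diem
    rate, unrounded; any presentation rounding is a formatting concern.
    """

    days_saved: int
    meals: tuple[float, float]
    lodging: tuple[float, float]
    wages: float

    def describe(self) -> str:
        return (
            f"{self.days_saved} fewer days away: "
            f"meals ${self.meals[0]:.0f}-${self.meals[1]:.0f}, "
            f"lodging ${self.lodging[0]:.0f}-${self.lodging[1]:.0f}, "
            f"lost wages ${self.wages:.0f}"
        )


def savings(
    n_standard: int = 44,
    n_hypo: int = 25,
    params: CostParameters = CostParameters(),
) -> SavingsReport:
    """Savings from delivering ``n_hypo`` instead of ``n_standard`` fractions.

    Days saved is the difference of delivery spans; planning days are common
    to both courses and cancel.  With the defaults (44 -> 25 fractions,
    weekday calendar), 27 days are saved, worth $5400 in lost wages at
    $200/day.
    """
    if int(n_standard) != n_standard or n_standard < 1:
        raise CostModelError(f"n_standard must be a positive integer, got {n_standard}")
    if int(n_hypo) != n_hypo or n_hypo < 1:
        raise CostModelError(f"n_hypo must be a positive integer, got {n_hypo}")
    if n_hypo >= n_standard:
        raise CostModelError(
            f"hypofractionated count ({n_hypo}) must be below the standard count ({n_standard})"
        )
    days = _delivery_span(int(n_standard), params) - _delivery_span(int(n_hypo), params)
    return SavingsReport(
        days_saved=days,
        meals=(days * params.meals_per_day[0], days * params.meals_per_day[1]),
        lodging=(days * params.lodging_per_day[0], days * params.lodging_per_day[1]),
        wages=days * params.wage_per_day,
    )


def annual_wage_to_daily(annual: float, convention: str = "workday") -> float:
    """Convert an annual income to a daily rate.

    ``"workday"`` divides by 260.5 working days/year (a $52,100 median
    household income gives ~$200/day); ``"calendar"`` divides by 365.
    """
    if annual < 0:
        raise CostModelError(f"annual income must be non-negative, got {annual}")
    if convention == "workday":
        return annual / WORKDAYS_PER_YEAR
    if convention == "calendar":
        return annual / 365.0
    raise CostModelError(f"unknown convention {convention!r}; use 'workday' or 'calendar'")
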