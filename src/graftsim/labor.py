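"""Grafting labor: learning curve, workforce sizing and weekly costs.

Unskilled workers speed up with practice following a power-law learning
curve ``T(P) = X + N * P**c`` — ``T`` seconds per grafted plant after
``P`` days of practice, ``X`` the expert asymptote, ``X + N`` the
first-day time, ``c < 0``.  The exponent is calibrated so that after the
nursery's learning period (default 21 days) only 5 % of the learnable
amplitude ``N`` remains, which gives the closed form
``c = log(0.05) / log(21)``.

Workforce rules:

* a constant crew of skilled workers (wage premium 50 %) is sized from
  the *minimum* weekly grafting quantity — the base load that is always
  present;
* each week's residual demand is covered by unskilled workers at their
  current learning-curve speed: up to ``seasonal_weekly_cap`` (50) local
  seasonal hires at minimum wage + 25 % fringe, and beyond the cap,
  migrant workers who additionally incur daily housing/expenses and a
  one-time transportation cost;
* practice accrues only on employed workdays; a released worker who is
  later rehired starts the curve from scratch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np


class LaborError(ValueError):
    pass


@dataclass(frozen=True)
class LearningCurve:
    """Power-law speed-up ``T(P) = X + N * P**c`` (seconds per plant)."""

    X: float  # expert asymptote, s/plant
    N: float  # learnable amplitude, s/plant; T(1) = X + N
    c: float  # exponent, < 0

    def __post_init__(self) -> None:
        if self.X <= 0 or self.N < 0 or self.c >= 0:
            raise LaborError("need X > 0, N >= 0, c < 0")

    @classmethod
    def from_endpoints(
        cls,
        initial_s_per_plant: float,
        expert_s_per_plant: float,
        learning_period_days: int = 21,
        residual_frac: float = 0.05,
    ) -> "LearningCurve":
        """Calibrate so T(1) = initial and T(period) = X + residual_frac*N."""
        if initial_s_per_plant <= expert_s_per_plant:
            raise LaborError("initial time must exceed expert time")
        c = math.log(residual_frac) / math.log(learning_period_days)
        return cls(X=expert_s_per_plant, N=initial_s_per_plant - expert_s_per_plant, c=c)


def graft_time(curve: LearningCurve, practice_days: int) -> float:
    """Seconds per plant after ``practice_days`` (>= 1) of practice."""
    if practice_days < 1:
        raise LaborError("practice_days must be >= 1")
    return max(curve.X, curve.X + curve.N * practice_days**curve.c)


def plants_per_hour(seconds_per_plant: float) -> int:
    """Throughput rounded to whole plants per hour (e.g. 64 s -> 56)."""
    return int(round(3600.0 / seconds_per_plant))


@dataclass(frozen=True)
class LaborPolicy:
    unskilled_wage_usd_per_h: float = 7.80
    skilled_premium: float = 1.5
    seasonal_fringe_frac: float = 0.25
    seasonal_weekly_cap: int = 50
    migrant_daily_expense_usd: float = 17.50
    migrant_billed_days_per_week: int = 7
    migrant_transport_usd_once: float = 500.0
    hours_per_week: float = 40.0
    workdays_per_week: int = 5

    def __post_init__(self) -> None:
        numeric = (
            self.unskilled_wage_usd_per_h,
            self.seasonal_fringe_frac,
            self.migrant_daily_expense_usd,
            self.migrant_transport_usd_once,
            self.hours_per_week,
        )
        if any(v < 0 for v in numeric) or self.seasonal_weekly_cap < 0:
            raise LaborError("monetary values and the seasonal cap must be >= 0")


@dataclass
class WeekLabor:
    """Per-week workforce and cost record."""

    week: int
    plants: int
    skilled: int
    seasonal: int
    migrant: int
    new_migrants: int
    labor_cost_usd: float
    cost_per_plant_usd: float | None
    capacity_plants: float


@dataclass
class _Worker:
    practice_days: int = 0
    transport_paid: bool = False


def _weekly_capacity(worker: _Worker, curve: LearningCurve, policy: LaborPolicy) -> float:
    """Plants an unskilled worker grafts in one week, day by day."""
    hours_per_day = policy.hours_per_week / policy.workdays_per_week
    return sum(
        hours_per_day * 3600.0 / graft_time(curve, worker.practice_days + d)
        for d in range(1, policy.workdays_per_week + 1)
    )


def weekly_labor_cost(
    skilled: int,
    seasonal: int,
    migrant: int,
    new_migrants: int,
    policy: LaborPolicy,
) -> float:
    """Total wages and expenses for one week's crew."""
    w, h = policy.unskilled_wage_usd_per_h, policy.hours_per_week
    cost = skilled * policy.skilled_premium * w * h
    cost += seasonal * w * h * (1.0 + policy.seasonal_fringe_frac)
    cost += migrant * (w * h + policy.migrant_billed_days_per_week * policy.migrant_daily_expense_usd)
    cost += new_migrants * policy.migrant_transport_usd_once
    return cost


def size_workforce(
    weekly_plants: list[int] | np.ndarray,
    curve: LearningCurve,
    expert_time_s: float,
    policy: LaborPolicy | None = None,
    speed_multipliers: list[float] | np.ndarray | None = None,
    base_min_plants: int | None = None,
) -> list[WeekLabor]:
    """Size and cost the weekly crews for a sequence of grafting quantities.

    ``speed_multipliers`` (default all 1.0) scales every worker's
    throughput that week, modelling week-to-week grafting-speed
    variability.  The skilled crew is sized once from the minimum weekly
    quantity (``base_min_plants`` overrides it, e.g. the planned rather
    than realized minimum).  Returns one :class:`WeekLabor` per week.
    """
    policy = policy or LaborPolicy()
    plants = [int(p) for p in weekly_plants]
    if any(p < 0 for p in plants):
        raise LaborError("plant quantities must be non-negative")
    mults = [1.0] * len(plants) if speed_multipliers is None else list(speed_multipliers)
    if len(mults) != len(plants):
        raise LaborError("speed_multipliers length must match the horizon")

    weekly_seconds = policy.hours_per_week * 3600.0
    min_plants = min(plants) if base_min_plants is None else base_min_plants
    skilled = math.ceil(min_plants * expert_time_s / weekly_seconds) if plants else 0

    pool: list[_Worker] = []
    out: list[WeekLabor] = []
    for t, (p, mult) in enumerate(zip(plants, mults), start=1):
        skilled_cap = skilled * weekly_seconds / expert_time_s * mult
        residual = max(0.0, p - skilled_cap)

        pool.sort(key=lambda w: -w.practice_days)
        staff: list[_Worker] = []
        cap = 0.0
        for worker in pool:
            if cap >= residual:
                break
            staff.append(worker)
            cap += _weekly_capacity(worker, curve, policy) * mult
        while cap < residual:
            worker = _Worker()
            staff.append(worker)
            cap += _weekly_capacity(worker, curve, policy) * mult

        n = len(staff)
        seasonal = min(n, policy.seasonal_weekly_cap)
        migrant = n - seasonal
        new_migrants = 0
        for worker in staff[seasonal:]:
            if not worker.transport_paid:
                worker.transport_paid = True
                new_migrants += 1

        cost = weekly_labor_cost(skilled, seasonal, migrant, new_migrants, policy)
        out.append(
            WeekLabor(
                week=t,
                plants=p,
                skilled=skilled,
                seasonal=seasonal,
                migrant=migrant,
                new_migrants=new_migrants,
                labor_cost_usd=cost,
                cost_per_plant_usd=(cost / p) if p > 0 else None,
                capacity_plants=skilled_cap + cap,
            )
        )

        for worker in staff:  # practice accrues only while employed
            worker.practice_days += policy.workdays_per_week
        pool = staff  # released workers lose their practice

    return out


def reduction_report(
    with_metrics: dict[str, float], without_metrics: dict[str, float]
) -> dict[str, int]:
    """Percent reduction (without - with)/without per metric, whole percent."""
    out: dict[str, int] = {}
    for key, wo in without_metrics.items():
        if key not in with_metrics:
            continue
        if wo == 0:
            raise LaborError(f"metric {key!r}: zero denominator in reduction")
        out[key] = int(round(100.0 * (wo - with_metrics[key]) / wo))
    return out
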