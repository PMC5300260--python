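"""Stochastic weekly simulation of a grafting nursery executing a schedule.

The production line is seeding -> germination/growth -> sorting ->
pre-grafting growth -> grafting -> healing (~1 week) -> optional
low-temperature storage -> finishing (~2 weeks) -> shipment.  Time
advances in whole weeks and all reporting is weekly.  The ledger's week
axis is shipment-aligned: the constant seeding-to-grafting and
finishing leads are normalized out, so a batch grafted "in week g" for
shipment week s spends exactly ``s - g`` weeks in storage and, with zero
noise, ships exactly in week ``s``.

Stochasticity (per weekly batch, truncated normal at +/-3 sd):

* stage durations (seeding-to-grafting, healing, finishing) with sd a
  fraction of the nominal duration (~22 %, greenhouse climate events),
* seedling survival (sd 5 % around a configurable mean loss; lost trays
  are not re-sown),
* grafting speed, as a weekly throughput multiplier (sd 10 %).

Each noise source draws from its own independent substream, so switching
one source on or off leaves the others' draws unchanged, and a fixed
seed reproduces the ledger bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import chamber
from .labor import LaborPolicy, LearningCurve, size_workforce
from .scenarios import ShipmentScenario
from .schedule import GraftingSchedule, storage_occupancy


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CropProfile:
    """Crop-specific horticultural, storage, speed and density parameters."""

    name: str
    seed_to_graft_weeks: int
    healing_weeks: int = 1
    finishing_weeks: int = 2
    duration_sd_frac: float = 0.22
    loss_sd_frac: float = 0.05
    speed_sd_frac: float = 0.10
    max_storage_weeks: int = 0
    graft_time_initial_s: float = 36.0
    graft_time_expert_s: float = 12.0
    learning_period_days: int = 21
    plant_density_per_m2_tray: float = 882.0
    tray_area_m2: float = 0.23
    storage_temp_C: float = 10.0
    storage_ppf: float = 5.0

    def __post_init__(self) -> None:
        if self.graft_time_expert_s >= self.graft_time_initial_s:
            raise SimulationError("expert grafting must be faster than initial")
        if min(self.seed_to_graft_weeks, self.healing_weeks, self.finishing_weeks) < 1:
            raise SimulationError("stage durations must be >= 1 week")
        for f in (self.duration_sd_frac, self.loss_sd_frac, self.speed_sd_frac):
            if not (0 <= f < 1):
                raise SimulationError("sd fractions must lie in [0, 1)")

    @property
    def plants_per_tray(self) -> int:
        return int(round(self.plant_density_per_m2_tray * self.tray_area_m2))

    @property
    def learning_curve(self) -> LearningCurve:
        return LearningCurve.from_endpoints(
            self.graft_time_initial_s, self.graft_time_expert_s, self.learning_period_days
        )


TOMATO = CropProfile(
    name="tomato",
    seed_to_graft_weeks=3,
    max_storage_weeks=4,
    graft_time_initial_s=36.0,
    graft_time_expert_s=12.0,
    plant_density_per_m2_tray=882.0,
    storage_temp_C=10.0,
    storage_ppf=5.0,
)

WATERMELON = CropProfile(
    name="watermelon",
    seed_to_graft_weeks=2,
    max_storage_weeks=2,
    graft_time_initial_s=64.0,
    graft_time_expert_s=24.0,
    plant_density_per_m2_tray=565.0,
    storage_temp_C=12.0,
    storage_ppf=12.0,
)

CROPS = {"tomato": TOMATO, "watermelon": WATERMELON}


def get_crop(name: str) -> CropProfile:
    try:
        return CROPS[name]
    except KeyError:
        raise SimulationError(f"unknown crop {name!r}; known: {sorted(CROPS)}") from None


@dataclass
class WeeklyLedger:
    """One simulated week of nursery state and money."""

    week: int
    trays_grafted: int
    trays_in_storage: int
    trays_shipped: int
    skilled_workers: int
    seasonal_workers: int
    migrant_workers: int
    labor_cost_usd: float
    storage_electricity_usd: float

    @property
    def total_workers(self) -> int:
        return self.skilled_workers + self.seasonal_workers + self.migrant_workers


def ledger_frame(ledgers: list[WeeklyLedger]) -> pd.DataFrame:
    df = pd.DataFrame([vars(l) for l in ledgers])
    df["total_workers"] = (
        df.skilled_workers + df.seasonal_workers + df.migrant_workers
    )
    return df


def _tnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Symmetric truncated normal at +/-3 sd (unbiased around the mean)."""
    if sd <= 0:
        return mean
    return float(stats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, random_state=rng))


def run_simulation(
    scenario: ShipmentScenario,
    schedule: GraftingSchedule,
    crop: CropProfile,
    policy: LaborPolicy | None = None,
    seed: int | None = None,
    deterministic: bool = False,
    mean_loss_frac: float = 0.0,
    storage_cost_per_plant_week: float | None = None,
) -> list[WeeklyLedger]:
    """Execute a grafting schedule through the weekly nursery flow.

    In deterministic mode every sd is forced to zero: each demanded tray
    ships in its demand week and totals conserve exactly.  Stochastic
    draws are per batch (one batch per schedule assignment).
    """
    if schedule.max_storage_weeks > crop.max_storage_weeks:
        raise SimulationError(
            f"schedule allows {schedule.max_storage_weeks} storage weeks but "
            f"{crop.name} tolerates only {crop.max_storage_weeks}"
        )
    if mean_loss_frac < 0 or mean_loss_frac >= 1:
        raise SimulationError("mean_loss_frac must lie in [0, 1)")
    policy = policy or LaborPolicy()

    dur_sd = 0.0 if deterministic else crop.duration_sd_frac
    loss_sd = 0.0 if deterministic else crop.loss_sd_frac
    speed_sd = 0.0 if deterministic else crop.speed_sd_frac

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_dur, rng_loss, rng_speed = (np.random.default_rng(s) for s in ss.spawn(3))

    horizon = scenario.horizon_weeks
    slack = crop.healing_weeks + crop.finishing_weeks + 2
    n_weeks = horizon + slack

    grafted = np.zeros(n_weeks, dtype=int)
    in_storage = np.zeros(n_weeks, dtype=int)
    shipped = np.zeros(n_weeks, dtype=int)

    for ship_week, graft_week, trays in schedule.assignments:
        shift = ship_week - graft_week
        # seeding week back-computed so growth meets the graft week in expectation
        _ = graft_week - _tnorm(rng_dur, crop.seed_to_graft_weeks, dur_sd * crop.seed_to_graft_weeks)
        h_dur = max(1, int(round(_tnorm(rng_dur, crop.healing_weeks, dur_sd * crop.healing_weeks))))
        f_dur = max(
            1, int(round(_tnorm(rng_dur, crop.finishing_weeks, dur_sd * crop.finishing_weeks)))
        )
        # not clipped at 1: symmetric variability keeps shipping unbiased
        survival = max(0.0, _tnorm(rng_loss, 1.0 - mean_loss_frac, loss_sd))
        batch = int(round(trays * survival))

        grafted[graft_week - 1] += batch
        start = graft_week + h_dur
        stop = min(start + shift, n_weeks + 1)
        in_storage[start - 1 : stop - 1] += batch
        ship = ship_week + (h_dur - crop.healing_weeks) + (f_dur - crop.finishing_weeks)
        ship = min(max(1, ship), n_weeks)
        shipped[ship - 1] += batch

    # labor: grafting only happens inside the demand horizon
    plants = grafted[:horizon] * crop.plants_per_tray
    mults = [
        min(1.3, max(0.7, _tnorm(rng_speed, 1.0, speed_sd))) for _ in range(horizon)
    ]
    base_min_plants = min(schedule.weekly_graft) * crop.plants_per_tray
    labor = size_workforce(
        plants.tolist(),
        crop.learning_curve,
        crop.graft_time_expert_s,
        policy,
        speed_multipliers=mults,
        base_min_plants=base_min_plants,
    )

    if storage_cost_per_plant_week is None:
        if crop.name in chamber.PLANTS_PER_M2_FOOTPRINT:
            storage_cost_per_plant_week = chamber.crop_breakdown(
                crop.name
            ).electricity_usd_per_plant_week
        else:
            storage_cost_per_plant_week = 0.0

    ledgers = []
    for t in range(n_weeks):
        wl = labor[t] if t < horizon else None
        ledgers.append(
            WeeklyLedger(
                week=t + 1,
                trays_grafted=int(grafted[t]),
                trays_in_storage=int(in_storage[t]),
                trays_shipped=int(shipped[t]),
                skilled_workers=wl.skilled if wl else 0,
                seasonal_workers=wl.seasonal if wl else 0,
                migrant_workers=wl.migrant if wl else 0,
                labor_cost_usd=wl.labor_cost_usd if wl else 0.0,
                storage_electricity_usd=float(in_storage[t])
                * crop.plants_per_tray
                * storage_cost_per_plant_week,
            )
        )
    return ledgers


def summarize_ledger(
    ledgers: list[WeeklyLedger], horizon: int, plants_per_tray: int = 1
) -> dict[str, float]:
    """Scalar metrics of one simulated run over the demand horizon.

    Per-plant costs use ``plants_per_tray`` (e.g. ``crop.plants_per_tray``)
    to convert the ledger's tray counts into grafted plants.
    """
    h = ledgers[:horizon]
    workers = [l.total_workers for l in h]
    grafted = [l.trays_grafted for l in h]
    costs = [l.labor_cost_usd for l in h]
    total_plants = sum(grafted) * plants_per_tray
    peak_week = int(np.argmax(grafted))
    peak_plants = grafted[peak_week] * plants_per_tray
    return {
        "peak_graft_trays": float(max(grafted)),
        "max_workers": float(max(workers)),
        "min_workers": float(min(workers)),
        "mean_workers": float(np.mean(workers)),
        "peak_week_cost_per_plant": (
            costs[peak_week] / peak_plants if peak_plants > 0 else math.nan
        ),
        "overall_cost_per_plant": (
            sum(costs) / total_plants if total_plants > 0 else math.nan
        ),
        "total_trays_shipped": float(sum(l.trays_shipped for l in ledgers)),
        "peak_storage_trays": float(max(l.trays_in_storage for l in ledgers)),
        "total_labor_cost": float(sum(costs)),
        "total_storage_electricity": float(
            sum(l.storage_electricity_usd for l in ledgers)
        ),
    }


def margin_of_error(values, alpha: float = 0.05) -> float:
    """Half-width of the t confidence interval across replicate runs."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise SimulationError("margin of error needs >= 2 replicates")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(tcrit * v.std(ddof=1) / math.sqrt(n))


def welch_ttest(a, b) -> tuple[float, float] | None:
    """Two-sided Welch t-test; None when both samples are degenerate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return None  # not testable: zero variance in both arms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class ReplicateSummary:
    """Means and margins of error across replicated simulation runs."""

    n_reps: int
    alpha: float
    per_week: pd.DataFrame  # mean and ME per ledger column per week
    metrics: pd.DataFrame  # scalar metrics: mean, sd, ME
    raw_metrics: dict[str, list[float]]
    ledgers: list[list[WeeklyLedger]]


def replicate_and_summarize(
    scenario: ShipmentScenario,
    schedule: GraftingSchedule,
    crop: CropProfile,
    n_reps: int = 5,
    alpha: float = 0.05,
    seed: int | None = None,
    **run_kwargs,
) -> ReplicateSummary:
    """Run ``n_reps`` replicate simulations and report mean +/- ME per week."""
    if n_reps < 2:
        raise SimulationError("need at least 2 replicates")
    rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    ledgers, metric_rows = [], []
    for s in rep_seeds:
        led = run_simulation(scenario, schedule, crop, seed=s, **run_kwargs)
        ledgers.append(led)
        metric_rows.append(
            summarize_ledger(led, scenario.horizon_weeks, crop.plants_per_tray)
        )

    frames = [ledger_frame(l).set_index("week") for l in ledgers]
    stacked = pd.concat(frames, keys=range(n_reps))
    mean = stacked.groupby(level=1).mean()
    me = stacked.groupby(level=1).agg(lambda v: margin_of_error(v, alpha))
    per_week = mean.join(me, lsuffix="_mean", rsuffix="_me")

    raw = {k: [m[k] for m in metric_rows] for k in metric_rows[0]}
    metrics = pd.DataFrame(
        {
            "mean": {k: float(np.mean(v)) for k, v in raw.items()},
            "sd": {k: float(np.std(v, ddof=1)) for k, v in raw.items()},
            "me": {k: margin_of_error(v, alpha) for k, v in raw.items()},
        }
    )
    return ReplicateSummary(
        n_reps=n_reps,
        alpha=alpha,
        per_week=per_week,
        metrics=metrics,
        raw_metrics=raw,
        ledgers=ledgers,
    )
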